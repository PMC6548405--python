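"""ChIP-qPCR quantification: native ratios, % Input, replicate aggregation.

Native (MNase) ChIP plates are quantified as the bound/unbound ratio
2^(unbound CT - bound CT), with the matched IgG ratio subtracted per target
and replicate. Cross-linked plates are quantified as % Input with the
input CT adjusted for the fraction of chromatin set aside as input
(ct_input - log2(1/input_fraction)). Sequential ChIP (re-ChIP) plates use
the % Input form against the first-round input, with a no-antibody control
subtracted like IgG. Amplification efficiency 2 is assumed throughout, as
implied by the delta-CT forms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QpcrResult:
    target: str
    enrichment: float  # mean across replicates
    sem: float
    n_replicates: int
    igg_subtracted: bool = False
    single_replicate: bool = False


def bound_unbound_ratio(ct_bound: float, ct_unbound: float) -> float:
    """Ratio Bound/Unbound = 1 / 2^(bound CT - unbound CT)."""
    if not (math.isfinite(ct_bound) and math.isfinite(ct_unbound)):
        raise ValueError("missing or non-finite CT value")
    return 2.0 ** (ct_unbound - ct_bound)


def subtract_igg(specific: float, igg: float) -> float:
    """Subtract the IgG background ratio, clamping at zero with a warning."""
    diff = specific - igg
    if diff < 0:
        logger.warning(
            "IgG ratio %.4g exceeds specific ratio %.4g; clamping enrichment to 0",
            igg,
            specific,
        )
        return 0.0
    return diff


def percent_input(ct_ip: float, ct_input: float, input_fraction: float = 0.10) -> float:
    """ChIP recovery as a percentage of the dilution-adjusted input.

    100 * 2^((ct_input - log2(1/input_fraction)) - ct_ip): when only 10% of
    chromatin was kept as input, its CT is shifted by log2(10) before
    comparison.
    """
    if input_fraction <= 0 or input_fraction > 1:
        raise ValueError("input_fraction must lie in (0, 1]")
    if not (math.isfinite(ct_ip) and math.isfinite(ct_input)):
        raise ValueError("missing or non-finite CT value")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def aggregate_replicates(
    values: Sequence[float],
    target: str = "",
    igg_subtracted: bool = False,
) -> QpcrResult:
    """Mean and SEM (sd/sqrt(n), sample sd) across replicates.

    A single replicate yields SEM 0 and is flagged.
    """
    if len(values) == 0:
        raise ValueError("no replicates to aggregate")
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    if n == 1:
        logger.warning("single replicate for %s; SEM reported as 0", target or "target")
        return QpcrResult(target, float(arr[0]), 0.0, 1, igg_subtracted, single_replicate=True)
    sem = float(arr.std(ddof=1) / math.sqrt(n))
    return QpcrResult(target, float(arr.mean()), sem, n, igg_subtracted)


def analyze_native_plate(
    plate: pd.DataFrame, igg_antibody: str = "IgG"
) -> pd.DataFrame:
    """Quantify a native ChIP-qPCR plate.

    Expects columns target, antibody, replicate, ct_bound, ct_unbound.
    Per replicate and target, the bound/unbound ratio of each specific
    antibody has the matched IgG ratio subtracted; replicates are then
    averaged. Returns target, antibody, enrichment, sem, n_replicates.
    """
    required = {"target", "antibody", "replicate", "ct_bound", "ct_unbound"}
    if not required.issubset(plate.columns):
        raise ValueError(f"native plate needs columns {sorted(required)}")
    plate = plate.copy()
    plate["ratio"] = [
        bound_unbound_ratio(b, u) for b, u in zip(plate["ct_bound"], plate["ct_unbound"])
    ]
    igg = plate[plate["antibody"] == igg_antibody].set_index(["target", "replicate"])["ratio"]
    rows = []
    for (target, antibody), grp in plate[plate["antibody"] != igg_antibody].groupby(
        ["target", "antibody"], sort=True
    ):
        corrected = []
        for rep, ratio in zip(grp["replicate"], grp["ratio"]):
            background = igg.get((target, rep), 0.0)
            corrected.append(subtract_igg(ratio, background))
        res = aggregate_replicates(corrected, target=target, igg_subtracted=True)
        rows.append(
            {
                "target": target,
                "antibody": antibody,
                "enrichment": res.enrichment,
                "sem": res.sem,
                "n_replicates": res.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def analyze_percent_input_plate(
    plate: pd.DataFrame, control_antibody: str | None = None
) -> pd.DataFrame:
    """Quantify a cross-linked (or re-ChIP) plate as % Input.

    Expects columns target, antibody, replicate, ct_ip, ct_input,
    input_fraction. When ``control_antibody`` is given (e.g. a no-antibody
    re-ChIP control), its per-replicate % Input is subtracted from each
    specific antibody before averaging.
    """
    required = {"target", "antibody", "replicate", "ct_ip", "ct_input", "input_fraction"}
    if not required.issubset(plate.columns):
        raise ValueError(f"% Input plate needs columns {sorted(required)}")
    plate = plate.copy()
    plate["pct"] = [
        percent_input(ip, inp, f)
        for ip, inp, f in zip(plate["ct_ip"], plate["ct_input"], plate["input_fraction"])
    ]
    control = None
    if control_antibody is not None:
        control = plate[plate["antibody"] == control_antibody].set_index(
            ["target", "replicate"]
        )["pct"]
        plate = plate[plate["antibody"] != control_antibody]
    rows = []
    for (target, antibody), grp in plate.groupby(["target", "antibody"], sort=True):
        vals = []
        for rep, pct in zip(grp["replicate"], grp["pct"]):
            if control is not None:
                pct = subtract_igg(pct, control.get((target, rep), 0.0))
            vals.append(pct)
        res = aggregate_replicates(vals, target=target, igg_subtracted=control is not None)
        rows.append(
            {
                "target": target,
                "antibody": antibody,
                "enrichment": res.enrichment,
                "sem": res.sem,
                "n_replicates": res.n_replicates,
            }
        )
    return pd.DataFrame(rows)
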