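"""Chromatin-state assignment and censuses.

Each promoter falls into one of four states per condition: marked by
H3K4me3 only, H3K27me3 only, both (bivalent) or neither. Two operational
definitions are supported:

* threshold mode — a mark is "high" when its H3-normalized log2 enrichment
  strictly exceeds a cut (2.5 by default, matching the scatter analyses);
* peak-overlap mode — a mark is "present" when any called domain of that
  mark overlaps the 4 kb promoter window by at least 1 bp (matching the
  intersect-based Venn analyses).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import pandas as pd

from bivalency.domains import PeakDomain
from bivalency.quantify import PromoterWindow


class ChromatinState(str, Enum):
    K4_ONLY = "K4_ONLY"
    K27_ONLY = "K27_ONLY"
    BIVALENT = "BIVALENT"
    NEITHER = "NEITHER"


#: canonical ordering used for censuses and transition matrices
STATE_ORDER: Tuple[ChromatinState, ...] = (
    ChromatinState.K4_ONLY,
    ChromatinState.K27_ONLY,
    ChromatinState.BIVALENT,
    ChromatinState.NEITHER,
)


@dataclass(frozen=True)
class StateThresholds:
    """Enrichment cuts for threshold-mode classification.

    A value exactly equal to high_cut is NOT high (strict exceedance).
    """

    high_cut: float = 2.5
    present_cut: float = 0.0

    def __post_init__(self) -> None:
        if self.high_cut <= self.present_cut:
            raise ValueError("high_cut must exceed present_cut")


@dataclass
class StateTable:
    """Per-gene chromatin states for one condition."""

    condition: str
    states: Dict[str, ChromatinState]
    mode: str  # "threshold" or "peak_overlap"

    def genes(self) -> set:
        return set(self.states)

    def genes_in_state(self, state: ChromatinState) -> set:
        return {g for g, s in self.states.items() if s is state}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.states),
                "condition": self.condition,
                "state": [s.value for s in self.states.values()],
                "mode": self.mode,
            }
        )


def _state_from_presence(k4: bool, k27: bool) -> ChromatinState:
    if k4 and k27:
        return ChromatinState.BIVALENT
    if k4:
        return ChromatinState.K4_ONLY
    if k27:
        return ChromatinState.K27_ONLY
    return ChromatinState.NEITHER


def classify_threshold(
    e_k4: float, e_k27: float, thresholds: StateThresholds = StateThresholds()
) -> ChromatinState:
    """Classify one promoter from its two enrichment values."""
    return _state_from_presence(e_k4 > thresholds.high_cut, e_k27 > thresholds.high_cut)


def classify_threshold_table(
    quant: pd.DataFrame,
    condition: str,
    thresholds: StateThresholds = StateThresholds(),
) -> StateTable:
    """Vectorized threshold classification of a promoter_quant table."""
    states = {
        row.gene_id: _state_from_presence(
            row.E_k4 > thresholds.high_cut, row.E_k27 > thresholds.high_cut
        )
        for row in quant.itertuples(index=False)
    }
    return StateTable(condition=condition, states=states, mode="threshold")


def classify_peak_overlap(
    domains_k4: Sequence[PeakDomain],
    domains_k27: Sequence[PeakDomain],
    windows: Sequence[PromoterWindow],
    condition: str,
) -> StateTable:
    """Classify promoters by >= 1 bp domain overlap with their 4 kb window."""
    k4_hit = _overlap_flags(domains_k4, windows)
    k27_hit = _overlap_flags(domains_k27, windows)
    states = {
        w.gene_id: _state_from_presence(k4_hit[w.gene_id], k27_hit[w.gene_id])
        for w in windows
    }
    return StateTable(condition=condition, states=states, mode="peak_overlap")


def _overlap_flags(
    domains: Sequence[PeakDomain], windows: Sequence[PromoterWindow]
) -> Dict[str, bool]:
    by_chrom: Dict[str, list] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    for intervals in by_chrom.values():
        intervals.sort()
    flags: Dict[str, bool] = {}
    for w in windows:
        hit = False
        for start, end in by_chrom.get(w.chrom, ()):
            if start >= w.end:
                break
            if end > w.start:  # half-open overlap of >= 1 bp
                hit = True
                break
        flags[w.gene_id] = hit
    return flags


def state_census(
    table: StateTable, universe: Iterable[str] | None = None
) -> Dict[ChromatinState, float]:
    """Fraction of genes in each of the four states.

    ``universe`` restricts (and validates) the genes considered; genes in
    the universe but absent from the table raise.
    """
    if universe is None:
        genes = list(table.states)
    else:
        genes = list(universe)
        missing = set(genes) - set(table.states)
        if missing:
            raise ValueError(f"genes missing from state table: {sorted(missing)[:5]}")
    if not genes:
        raise ValueError("empty gene universe")
    n = len(genes)
    census = {state: 0 for state in STATE_ORDER}
    for g in genes:
        census[table.states[g]] += 1
    return {state: count / n for state, count in census.items()}


def merge_replicate_states(
    a: StateTable, b: StateTable, how: str = "union"
) -> StateTable:
    """Combine two replicate state tables at the per-mark presence level.

    Each state implies presence/absence of each mark; 'union' calls a mark
    present when either replicate has it, 'intersection' when both do.
    """
    if how not in ("union", "intersection"):
        raise ValueError("how must be 'union' or 'intersection'")
    if a.genes() != b.genes():
        raise ValueError("replicate tables cover different gene universes")
    combine = (lambda x, y: x or y) if how == "union" else (lambda x, y: x and y)
    states: Dict[str, ChromatinState] = {}
    for gene in a.states:
        sa, sb = a.states[gene], b.states[gene]
        k4 = combine(sa in (ChromatinState.K4_ONLY, ChromatinState.BIVALENT),
                     sb in (ChromatinState.K4_ONLY, ChromatinState.BIVALENT))
        k27 = combine(sa in (ChromatinState.K27_ONLY, ChromatinState.BIVALENT),
                      sb in (ChromatinState.K27_ONLY, ChromatinState.BIVALENT))
        states[gene] = _state_from_presence(k4, k27)
    return StateTable(condition=f"{a.condition}|{b.condition}:{how}", states=states, mode=a.mode)
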