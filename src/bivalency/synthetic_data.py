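"""Synthetic genomes with known chromatin-state truth.

Generates a single-chromosome annotation of well-separated promoters, draws
a true chromatin state per gene (and a second-timepoint state through a
known transition matrix), and emits tag libraries for H3, H3K4me3 and
H3K27me3 in which promoter-window counts are Poisson with state-dependent
rates over a uniform genomic background. Expression values and qPCR plates
with known truth complete the inputs needed to exercise every pipeline
stage.

The default parameters emulate the statistical structure of promoter
bivalency data in differentiating cell populations: 16% of promoters
bivalent and 5% H3K27me3-only at the progenitor timepoint, IP tag rates
12x the H3 baseline at marked promoters and 0.5x elsewhere (true log2
ratios around +3.5 and -1, straddling the 2.5 classification cut), and a
genome large enough that background tags dominate library totals — as in
real ChIP-seq, where promoters are a small fraction of the genome — so
that depth scaling preserves the in-window rate contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from bivalency.genome_io import ChromSizes, GeneSet, TagLibrary, TssRecord, make_tag_library
from bivalency.states import STATE_ORDER, ChromatinState

_STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}

_DEFAULT_PROPORTIONS = {
    ChromatinState.K4_ONLY: 0.45,
    ChromatinState.K27_ONLY: 0.05,
    ChromatinState.BIVALENT: 0.16,
    ChromatinState.NEITHER: 0.34,
}

# rows/columns in STATE_ORDER (K4_ONLY, K27_ONLY, BIVALENT, NEITHER):
# non-bivalent states mostly persist; bivalent promoters preferentially
# resolve toward the active H3K4me3-only state upon differentiation.
_DEFAULT_TRANSITIONS = np.array(
    [
        [0.92, 0.01, 0.05, 0.02],
        [0.02, 0.90, 0.05, 0.03],
        [0.45, 0.10, 0.40, 0.05],
        [0.03, 0.02, 0.02, 0.93],
    ]
)

_DEFAULT_EXPRESSION_MEANS = {
    ChromatinState.K4_ONLY: 8.0,
    ChromatinState.BIVALENT: 5.0,
    ChromatinState.K27_ONLY: 4.8,
    ChromatinState.NEITHER: 4.5,
}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults define the standard conditions.

    lambda_h3 is the mean H3 tag count per 4 kb promoter window; IP rates
    are multipliers of it (ip_high at states carrying the mark, ip_low
    elsewhere). background_rate is tags/bp outside promoter windows.
    overdispersion, when set, switches window counts from Poisson to a
    negative binomial with that shape parameter.
    """

    n_genes: int = 400
    chrom: str = "chrS"
    chrom_len: int = 100_000_000
    flank: int = 2000
    min_spacing: int = 8000
    state_proportions: Dict[ChromatinState, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    lambda_h3: float = 30.0
    ip_high: float = 12.0
    ip_low: float = 0.5
    background_rate: float = 0.002
    overdispersion: float | None = None
    transition_matrix: np.ndarray = field(
        default_factory=lambda: _DEFAULT_TRANSITIONS.copy()
    )
    expression_means: Dict[ChromatinState, float] = field(
        default_factory=lambda: dict(_DEFAULT_EXPRESSION_MEANS)
    )
    expression_sd: float = 1.0
    gene_set_size: int = 50
    timepoints: Tuple[str, str] = ("E10.5", "E13.5")
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.array([self.state_proportions[s] for s in STATE_ORDER])
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("state proportions must sum to 1")
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (4, 4) or not np.allclose(tm.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be 4x4 row-stochastic")
        if min(self.lambda_h3, self.ip_high, self.ip_low, self.background_rate) < 0:
            raise ValueError("rates must be non-negative")

    def window_rates(self, mark: str, state: ChromatinState) -> float:
        """Mean tag count for one mark in one promoter window."""
        if mark == "H3":
            return self.lambda_h3
        carries = {
            "H3K4me3": state in (ChromatinState.K4_ONLY, ChromatinState.BIVALENT),
            "H3K27me3": state in (ChromatinState.K27_ONLY, ChromatinState.BIVALENT),
        }[mark]
        return self.lambda_h3 * (self.ip_high if carries else self.ip_low)


@dataclass
class SyntheticTruth:
    """Ground-truth states per gene at each timepoint."""

    genes: List[str]
    state_t0: Dict[str, ChromatinState]
    state_t1: Dict[str, ChromatinState]
    seed: int


@dataclass
class SimulatedDataset:
    """Everything one run of the generator produces."""

    config: SyntheticConfig
    tss: List[TssRecord]
    chrom_sizes: ChromSizes
    gene_sets: Dict[str, GeneSet]
    truth: SyntheticTruth
    libraries: Dict[Tuple[str, str], TagLibrary]  # (timepoint, mark) -> library
    expression: pd.DataFrame


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_annotation(
    config: SyntheticConfig,
) -> Tuple[List[TssRecord], ChromSizes, Dict[str, GeneSet]]:
    """Place non-overlapping promoters and sample two disjoint gene sets.

    TSSs keep a pairwise spacing of at least ``min_spacing`` (8 kb default,
    so 4 kb windows cannot overlap) and stay ``flank`` bp clear of the
    chromosome ends. Deterministic under a fixed config seed.
    """
    rng = _rng(config, 1)
    usable = config.chrom_len - 2 * config.flank - (config.n_genes - 1) * config.min_spacing
    if config.n_genes < 1 or usable <= 0:
        raise ValueError(
            f"cannot pack {config.n_genes} promoters with {config.min_spacing} bp "
            f"spacing into {config.chrom_len} bp"
        )
    jitter = np.sort(rng.random(config.n_genes)) * usable
    tss_pos = (
        config.flank
        + np.floor(jitter).astype(np.int64)
        + np.arange(config.n_genes, dtype=np.int64) * config.min_spacing
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)
    width = len(str(max(config.n_genes - 1, 1)))
    records = [
        TssRecord(gene_id=f"g{i:0{width}d}", chrom=config.chrom, tss=int(t), strand=s)
        for i, (t, s) in enumerate(zip(tss_pos, strands))
    ]
    chrom_sizes: ChromSizes = {config.chrom: config.chrom_len}

    n_set = min(config.gene_set_size, config.n_genes // 2)
    picked = rng.choice(config.n_genes, size=2 * n_set, replace=False)
    gene_ids = [r.gene_id for r in records]
    gene_sets = {
        "testis_specific": GeneSet(
            "testis_specific", frozenset(gene_ids[i] for i in picked[:n_set])
        ),
        "ovary_specific": GeneSet(
            "ovary_specific", frozenset(gene_ids[i] for i in picked[n_set:])
        ),
    }
    return records, chrom_sizes, gene_sets


def simulate_truth(config: SyntheticConfig, genes: Sequence[str]) -> SyntheticTruth:
    """Draw t0 states from the state proportions and t1 states through the
    transition matrix."""
    rng = _rng(config, 2)
    props = np.array([config.state_proportions[s] for s in STATE_ORDER])
    idx_t0 = rng.choice(4, size=len(genes), p=props)
    tm = np.asarray(config.transition_matrix, dtype=float)
    idx_t1 = np.array([rng.choice(4, p=tm[i]) for i in idx_t0])
    return SyntheticTruth(
        genes=list(genes),
        state_t0={g: STATE_ORDER[i] for g, i in zip(genes, idx_t0)},
        state_t1={g: STATE_ORDER[i] for g, i in zip(genes, idx_t1)},
        seed=config.seed,
    )


def _background_positions(
    rng: np.random.Generator,
    windows: Sequence[Tuple[int, int]],
    chrom_len: int,
    rate: float,
) -> np.ndarray:
    """Uniform background tags over the complement of the promoter windows."""
    gaps: List[Tuple[int, int]] = []
    cursor = 0
    for start, end in windows:
        if start > cursor:
            gaps.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < chrom_len:
        gaps.append((cursor, chrom_len))
    gap_lens = np.array([e - s for s, e in gaps], dtype=np.int64)
    total_bg = int(gap_lens.sum())
    n_bg = rng.poisson(rate * total_bg)
    if n_bg == 0:
        return np.empty(0, dtype=np.int64)
    u = rng.integers(0, total_bg, size=n_bg)
    gap_offsets = np.concatenate([[0], np.cumsum(gap_lens)])
    gap_idx = np.searchsorted(gap_offsets, u, side="right") - 1
    gap_starts = np.array([s for s, _e in gaps], dtype=np.int64)
    return gap_starts[gap_idx] + (u - gap_offsets[gap_idx])


def _window_counts(
    rng: np.random.Generator, rates: np.ndarray, overdispersion: float | None
) -> np.ndarray:
    if overdispersion is None:
        return rng.poisson(rates)
    # NB with mean = rate, shape = overdispersion (variance = m + m^2/shape)
    r = overdispersion
    p = r / (r + rates)
    return rng.negative_binomial(r, p)


def simulate_tags(
    truth: SyntheticTruth,
    tss: Sequence[TssRecord],
    config: SyntheticConfig,
    timepoint: str | None = None,
) -> Dict[str, TagLibrary]:
    """Emit H3/H3K4me3/H3K27me3 tag libraries for one timepoint.

    Promoter-window counts are Poisson (or negative-binomial) with the
    state-dependent rates of ``config``; tags are uniform within their
    window, and the rest of the chromosome carries uniform background.
    """
    timepoint = timepoint or config.timepoints[0]
    if timepoint == config.timepoints[0]:
        states, stream = truth.state_t0, 3
    elif timepoint == config.timepoints[1]:
        states, stream = truth.state_t1, 4
    else:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    rng = _rng(config, stream)

    order = sorted(tss, key=lambda r: r.tss)
    windows = [(r.tss - config.flank, r.tss + config.flank) for r in order]
    libraries: Dict[str, TagLibrary] = {}
    for mark in ("H3", "H3K4me3", "H3K27me3"):
        rates = np.array([config.window_rates(mark, states[r.gene_id]) for r in order])
        counts = _window_counts(rng, rates, config.overdispersion)
        parts = [
            rng.integers(start, end, size=c)
            for (start, end), c in zip(windows, counts)
        ]
        parts.append(
            _background_positions(rng, windows, config.chrom_len, config.background_rate)
        )
        positions = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        libraries[mark] = make_tag_library(
            sample_id=f"{mark}_{timepoint}",
            mark=mark,
            condition=timepoint,
            chroms=[config.chrom] * len(positions),
            positions=positions,
        )
    return libraries


def simulate_expression(
    truth: SyntheticTruth, config: SyntheticConfig, timepoint: str | None = None
) -> pd.DataFrame:
    """Per-gene log-intensity values, Normal(mean_state, sd)."""
    timepoint = timepoint or config.timepoints[0]
    if timepoint == config.timepoints[0]:
        states, stream = truth.state_t0, 5
    elif timepoint == config.timepoints[1]:
        states, stream = truth.state_t1, 6
    else:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    rng = _rng(config, stream)
    means = np.array([config.expression_means[states[g]] for g in truth.genes])
    values = rng.normal(means, config.expression_sd)
    return pd.DataFrame(
        {"gene_id": truth.genes, "condition": timepoint, "value": values}
    )


def simulate_qpcr(
    true_ratios: Mapping[str, float],
    noise_sd_ct: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    antibody: str = "specific",
    ct_unbound: float = 24.0,
) -> pd.DataFrame:
    """Native-protocol qPCR plate whose noiseless ratios equal the truth.

    For each target the bound CT is set to ct_unbound - log2(true ratio),
    then independent Gaussian CT noise is added to bound and unbound wells.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    rows = []
    for target in sorted(true_ratios):
        ratio = true_ratios[target]
        if ratio <= 0:
            raise ValueError(f"true ratio for {target!r} must be positive")
        base_bound = ct_unbound - np.log2(ratio)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "target": target,
                    "antibody": antibody,
                    "replicate": rep,
                    "ct_bound": base_bound + rng.normal(0.0, noise_sd_ct)
                    if noise_sd_ct > 0
                    else base_bound,
                    "ct_unbound": ct_unbound + rng.normal(0.0, noise_sd_ct)
                    if noise_sd_ct > 0
                    else ct_unbound,
                }
            )
    return pd.DataFrame(rows)


def uniform_library(
    n_tags: int,
    chrom_len: int,
    seed: int,
    mark: str = "H3K27me3",
    chrom: str = "chrS",
    condition: str = "uniform",
) -> TagLibrary:
    """A library of tags placed uniformly at random — the null for the
    domain caller's calibration."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 8]))
    positions = rng.integers(0, chrom_len, size=n_tags)
    return make_tag_library(
        sample_id=f"uniform_{mark}_{seed}",
        mark=mark,
        condition=condition,
        chroms=[chrom] * n_tags,
        positions=positions,
    )


def simulate_dataset(config: SyntheticConfig | None = None) -> SimulatedDataset:
    """One full two-timepoint dataset: annotation, truth, six tag
    libraries, and expression at both timepoints."""
    config = config or SyntheticConfig()
    tss, chrom_sizes, gene_sets = generate_annotation(config)
    truth = simulate_truth(config, [r.gene_id for r in tss])
    libraries: Dict[Tuple[str, str], TagLibrary] = {}
    for tp in config.timepoints:
        libs = simulate_tags(truth, tss, config, timepoint=tp)
        for mark, lib in libs.items():
            libraries[(tp, mark)] = lib
    expression = pd.concat(
        [simulate_expression(truth, config, tp) for tp in config.timepoints],
        ignore_index=True,
    )
    return SimulatedDataset(
        config=config,
        tss=tss,
        chrom_sizes=chrom_sizes,
        gene_sets=gene_sets,
        truth=truth,
        libraries=libraries,
        expression=expression,
    )
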