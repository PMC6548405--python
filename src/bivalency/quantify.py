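"""Promoter-window tag counting and H3-normalized log2 enrichment.

Each TSS gets a symmetric window of ``flank`` bp on each side (4 kb total by
default). IP tag counts in the window are divided by the total-H3 count in
the same window, after optional library-depth scaling and with a pseudocount
keeping log ratios finite:

    E = log2( ((c_ip + p) / N_ip) / ((c_h3 + p) / N_h3) )

Normalizing to total H3 controls for nucleosome occupancy and recovery, so E
measures the density of the modification per nucleosome rather than raw
coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from bivalency.genome_io import ChromSizes, TagLibrary, TssRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PromoterWindow:
    """A half-open quantification window around one TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: empty window [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NormalizationConfig:
    """Constants behind the H3 normalization.

    pseudocount is added to both IP and H3 window counts; depth_scale
    divides each count by its library total before forming the ratio.
    """

    pseudocount: float = 1.0
    depth_scale: bool = True

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def make_promoter_windows(
    tss_list: Sequence[TssRecord],
    flank: int = 2000,
    chrom_sizes: ChromSizes | None = None,
) -> List[PromoterWindow]:
    """Build [tss - flank, tss + flank) windows, clipped at chromosome edges.

    Windows are strand-independent (symmetric about the TSS). Clipped
    windows are flagged but kept; their counts are not rescaled.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    windows: List[PromoterWindow] = []
    for rec in tss_list:
        start = rec.tss - flank
        end = rec.tss + flank
        clipped = False
        if start < 0:
            start, clipped = 0, True
        if chrom_sizes is not None and rec.chrom in chrom_sizes:
            length = chrom_sizes[rec.chrom]
            if end > length:
                end, clipped = length, True
        windows.append(
            PromoterWindow(gene_id=rec.gene_id, chrom=rec.chrom, start=start, end=end, clipped=clipped)
        )
    return windows


def count_tags_in_windows(
    library: TagLibrary, windows: Sequence[PromoterWindow]
) -> Dict[str, int]:
    """Count tags whose position falls in [start, end) of each window.

    Overlapping windows each count shared tags. Uses a sorted-position
    binary search per chromosome.
    """
    counts: Dict[str, int] = {}
    for window in windows:
        pos = library.positions(window.chrom)
        lo = np.searchsorted(pos, window.start, side="left")
        hi = np.searchsorted(pos, window.end, side="left")
        counts[window.gene_id] = int(hi - lo)
    return counts


def log2_enrichment(
    c_ip: float | np.ndarray,
    c_h3: float | np.ndarray,
    n_ip: int,
    n_h3: int,
    config: NormalizationConfig = NormalizationConfig(),
) -> float | np.ndarray:
    """H3-normalized log2 enrichment of one window (vectorized)."""
    if n_ip <= 0 or n_h3 <= 0:
        raise ValueError("empty library: totals must be positive")
    p = config.pseudocount
    num = np.asarray(c_ip, dtype=float) + p
    den = np.asarray(c_h3, dtype=float) + p
    ratio = num / den
    if config.depth_scale:
        ratio = ratio * (n_h3 / n_ip)
    result = np.log2(ratio)
    return float(result) if np.ndim(result) == 0 else result


def enrichment_table(
    counts_k4: Mapping[str, int],
    counts_k27: Mapping[str, int],
    counts_h3: Mapping[str, int],
    totals: Mapping[str, int],
    config: NormalizationConfig = NormalizationConfig(),
) -> pd.DataFrame:
    """Per-gene quantification table.

    ``totals`` maps mark name ('H3K4me3', 'H3K27me3', 'H3') to library size.
    Returns columns gene_id, c_k4, c_k27, c_h3, E_k4, E_k27.
    """
    genes = sorted(counts_h3)
    if set(counts_k4) != set(genes) or set(counts_k27) != set(genes):
        raise ValueError("count mappings cover different gene universes")
    c_k4 = np.array([counts_k4[g] for g in genes], dtype=np.int64)
    c_k27 = np.array([counts_k27[g] for g in genes], dtype=np.int64)
    c_h3 = np.array([counts_h3[g] for g in genes], dtype=np.int64)
    if (c_k4 < 0).any() or (c_k27 < 0).any() or (c_h3 < 0).any():
        raise ValueError("negative tag counts")
    e_k4 = log2_enrichment(c_k4, c_h3, totals["H3K4me3"], totals["H3"], config)
    e_k27 = log2_enrichment(c_k27, c_h3, totals["H3K27me3"], totals["H3"], config)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "c_k4": c_k4,
            "c_k27": c_k27,
            "c_h3": c_h3,
            "E_k4": e_k4,
            "E_k27": e_k27,
        }
    )


def promoter_quant(
    tss_list: Sequence[TssRecord],
    k4: TagLibrary,
    k27: TagLibrary,
    h3: TagLibrary,
    flank: int = 2000,
    chrom_sizes: ChromSizes | None = None,
    config: NormalizationConfig = NormalizationConfig(),
) -> pd.DataFrame:
    """End-to-end promoter quantification: windows, counts, enrichment."""
    windows = make_promoter_windows(tss_list, flank=flank, chrom_sizes=chrom_sizes)
    totals = {"H3K4me3": k4.total_tags, "H3K27me3": k27.total_tags, "H3": h3.total_tags}
    return enrichment_table(
        count_tags_in_windows(k4, windows),
        count_tags_in_windows(k27, windows),
        count_tags_in_windows(h3, windows),
        totals,
        config,
    )
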