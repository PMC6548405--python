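"""Readers and writers for annotations, tag libraries and tabular inputs.

All genomic coordinates are 0-based, half-open throughout the package.
Aligned ChIP reads are reduced to single 5' tag positions on read
(start for +, end-1 for -); no fragment extension is applied, which is
adequate for MNase mononucleosome libraries. An optional fixed shift is
exposed for other protocols.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_MARKS = ("H3", "H3K4me3", "H3K27me3")

#: chromosome name -> length in bp
ChromSizes = Dict[str, int]


class ParseError(ValueError):
    """Malformed input row; message names the offending line."""


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicates, out-of-range)."""


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site anchor.

    ``tss`` is the 0-based coordinate of the start site itself; for a
    minus-strand gene annotated as a half-open interval this is ``end - 1``.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"{self.gene_id}: negative TSS {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class TagLibrary:
    """One sample's aligned ChIP tags, reduced to 5' positions.

    ``tags`` holds (chrom, position) pairs as a DataFrame with columns
    ``chrom`` and ``pos``. Duplicate tags are retained.
    """

    sample_id: str
    mark: str
    condition: str
    tags: pd.DataFrame
    _index: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.mark not in VALID_MARKS:
            raise ValidationError(f"unknown mark {self.mark!r}; expected one of {VALID_MARKS}")
        if list(self.tags.columns[:2]) != ["chrom", "pos"]:
            raise ValidationError("tags frame must have columns (chrom, pos)")

    @property
    def total_tags(self) -> int:
        return len(self.tags)

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted tag positions on one chromosome (cached)."""
        if chrom not in self._index:
            sel = self.tags.loc[self.tags["chrom"] == chrom, "pos"]
            self._index[chrom] = np.sort(sel.to_numpy(dtype=np.int64))
        return self._index[chrom]

    def chromosomes(self) -> List[str]:
        return sorted(self.tags["chrom"].unique())


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: FrozenSet[str]

    def __len__(self) -> int:
        return len(self.members)


def make_tag_library(
    sample_id: str,
    mark: str,
    condition: str,
    chroms: Sequence[str],
    positions: Sequence[int],
) -> TagLibrary:
    """Assemble a TagLibrary from parallel chrom/position sequences."""
    frame = pd.DataFrame(
        {"chrom": pd.Series(chroms, dtype=str), "pos": pd.Series(positions, dtype=np.int64)}
    )
    return TagLibrary(sample_id=sample_id, mark=mark, condition=condition, tags=frame)


# ---------------------------------------------------------------------------
# annotation


def read_tss(path: str | Path) -> List[TssRecord]:
    """Read a TSS annotation from a BED-like file.

    Accepts BED6 rows (chrom start end name score strand), where the TSS is
    ``start`` on + and ``end - 1`` on -, or 4-column rows
    (chrom pos name strand) giving the TSS directly. gene_id must be unique.
    """
    records: List[TssRecord] = []
    seen: Dict[str, int] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                if len(fields) >= 6:
                    chrom, start, end, name, _score, strand = fields[:6]
                    start_i, end_i = int(start), int(end)
                    if end_i <= start_i:
                        raise ValueError("empty interval")
                    tss = start_i if strand == "+" else end_i - 1
                elif len(fields) == 4:
                    chrom, pos, name, strand = fields
                    tss = int(pos)
                else:
                    raise ValueError(f"expected 4 or >=6 columns, got {len(fields)}")
                rec = TssRecord(gene_id=name, chrom=chrom, tss=tss, strand=strand)
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if name in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate gene_id {name!r} (first seen line {seen[name]})"
                )
            seen[name] = lineno
            records.append(rec)
    return records


def write_tss(records: Iterable[TssRecord], path: str | Path) -> None:
    """Write a TSS annotation as BED6 single-base intervals."""
    with Path(path).open("w") as fh:
        for r in records:
            start = r.tss if r.strand == "+" else r.tss
            # single-base interval [tss, tss+1); read_tss recovers tss on both strands
            fh.write(f"{r.chrom}\t{start}\t{start + 1}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# tags


def read_tags(
    path: str | Path,
    sample_id: str,
    mark: str,
    condition: str,
    chrom_sizes: ChromSizes | None = None,
    fmt: str = "bed",
    shift: int = 0,
) -> TagLibrary:
    """Read aligned tags from BED (default) or SAM (``fmt='sam'``).

    Each record contributes one tag at the 5' position of the read
    (``start`` for +, ``end - 1`` for -), optionally shifted downstream by
    ``shift`` bp in the read's orientation. Tags beyond their chromosome end
    raise; an empty file yields an empty library with a logged warning.
    """
    if fmt == "bed":
        chroms, positions = _read_tags_bed(Path(path), shift)
    elif fmt == "sam":
        chroms, positions = _read_tags_sam(Path(path), shift)
    else:
        raise ValueError(f"unknown tag format {fmt!r}")

    if chrom_sizes is not None:
        for chrom, pos in zip(chroms, positions):
            if chrom not in chrom_sizes:
                raise ValidationError(f"tag on unknown chromosome {chrom!r}")
            if not (0 <= pos < chrom_sizes[chrom]):
                raise ValidationError(
                    f"tag at {chrom}:{pos} outside chromosome of length {chrom_sizes[chrom]}"
                )
    if not positions:
        logger.warning("tag file %s is empty; library %s has 0 tags", path, sample_id)
    return make_tag_library(sample_id, mark, condition, chroms, positions)


def _read_tags_bed(path: Path, shift: int) -> Tuple[List[str], List[int]]:
    chroms: List[str] = []
    positions: List[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            strand = fields[5] if len(fields) >= 6 else "+"
            pos = start + shift if strand != "-" else end - 1 - shift
            chroms.append(chrom)
            positions.append(pos)
    return chroms, positions


def _read_tags_sam(path: Path, shift: int) -> Tuple[List[str], List[int]]:
    import pysam

    chroms: List[str] = []
    positions: List[int] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        for read in af:
            if read.is_unmapped:
                continue
            if read.is_reverse:
                pos = read.reference_end - 1 - shift
            else:
                pos = read.reference_start + shift
            chroms.append(read.reference_name)
            positions.append(pos)
    return chroms, positions


def write_tags(library: TagLibrary, path: str | Path) -> None:
    """Write a tag library as single-base plus-strand BED6 records.

    Round-trips exactly through :func:`read_tags`.
    """
    with Path(path).open("w") as fh:
        for chrom, pos in library.tags.itertuples(index=False):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t0\t+\n")


# ---------------------------------------------------------------------------
# bedGraph and chrom sizes


def write_bedgraph(
    values: Sequence[Tuple[str, int, int, float]], path: str | Path
) -> None:
    """Write sorted, non-overlapping half-open intervals as 4-column bedGraph."""
    prev: Dict[str, Tuple[int, int]] = {}
    last_chrom = None
    seen_chroms = set()
    for chrom, start, end, _score in values:
        if start < 0 or end <= start:
            raise ValidationError(f"bad interval {chrom}:{start}-{end}")
        if chrom != last_chrom:
            if chrom in seen_chroms:
                raise ValidationError(f"input not sorted: chromosome {chrom} recurs")
            seen_chroms.add(chrom)
            last_chrom = chrom
        if chrom in prev:
            _p_start, p_end = prev[chrom]
            if start < p_end:
                raise ValidationError(
                    f"intervals unsorted or overlapping at {chrom}:{start}-{end}"
                )
        prev[chrom] = (start, end)
    with Path(path).open("w") as fh:
        for chrom, start, end, score in values:
            fh.write(f"{chrom}\t{start}\t{end}\t{score:g}\n")


def read_bedgraph(path: str | Path) -> List[Tuple[str, int, int, float]]:
    out: List[Tuple[str, int, int, float]] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            out.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return out


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column chrom.sizes table."""
    sizes: ChromSizes = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            length = int(fields[1])
            if length <= 0:
                raise ValidationError(f"{path}:{lineno}: non-positive length {length}")
            sizes[fields[0]] = length
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# gene sets, expression, qPCR plates


def read_gene_set(
    path: str | Path,
    name: str | None = None,
    annotation: Sequence[TssRecord] | None = None,
) -> GeneSet:
    """Read a gene set from a one-column CSV (optional ``gene_id`` header).

    When ``annotation`` is given, membership is validated against its gene
    universe.
    """
    path = Path(path)
    members: List[str] = []
    with path.open() as fh:
        for line in fh:
            token = line.strip().split(",")[0].strip()
            if not token or token == "gene_id":
                continue
            members.append(token)
    gene_set = GeneSet(name=name or path.stem, members=frozenset(members))
    if annotation is not None:
        universe = {r.gene_id for r in annotation}
        missing = gene_set.members - universe
        if missing:
            raise ValidationError(
                f"gene set {gene_set.name!r} has members outside the annotation: "
                f"{sorted(missing)[:5]}..."
            )
    return gene_set


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\n")
        for gene in sorted(gene_set.members):
            fh.write(f"{gene}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read per-gene expression log-intensities.

    CSV with columns ``gene_id, condition, value``; returns a validated
    DataFrame with finite values.
    """
    frame = pd.read_csv(path)
    required = {"gene_id", "condition", "value"}
    if not required.issubset(frame.columns):
        raise ParseError(f"expression table must have columns {sorted(required)}")
    if not np.isfinite(frame["value"]).all():
        raise ValidationError("expression table contains non-finite values")
    return frame


def read_qpcr_plate(path: str | Path) -> pd.DataFrame:
    """Read a qPCR plate CSV.

    Expected columns: ``target, antibody, replicate`` plus the CT columns of
    the protocol in use (``ct_bound``/``ct_unbound`` for native ChIP,
    ``ct_ip``/``ct_input`` and ``input_fraction`` for cross-linked).
    CT values must lie in (0, 45).
    """
    frame = pd.read_csv(path)
    required = {"target", "antibody", "replicate"}
    if not required.issubset(frame.columns):
        raise ParseError(f"qPCR plate must have columns {sorted(required)}")
    ct_cols = [c for c in frame.columns if c.startswith("ct_")]
    if not ct_cols:
        raise ParseError("qPCR plate has no CT columns")
    for col in ct_cols:
        vals = frame[col].dropna()
        if ((vals <= 0) | (vals >= 45)).any():
            raise ValidationError(f"CT values in {col} outside (0, 45)")
    if "input_fraction" in frame.columns:
        frac = frame["input_fraction"].dropna()
        if ((frac <= 0) | (frac > 1)).any():
            raise ValidationError("input_fraction outside (0, 1]")
    return frame
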