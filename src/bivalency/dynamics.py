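"""Cross-condition comparison of chromatin-state tables.

Transition matrices between two timepoints, bivalency-resolution fractions
within gene sets, shared-state overlaps between samples, and the
association between chromatin state and expression level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from bivalency.genome_io import GeneSet
from bivalency.states import STATE_ORDER, ChromatinState, StateTable

logger = logging.getLogger(__name__)


@dataclass
class TransitionSummary:
    """4x4 state-transition counts between two conditions.

    ``counts`` is a DataFrame indexed by from-state with to-state columns,
    both in canonical state order. Counts sum to the size of the compared
    universe (or gene set).
    """

    condition_pair: Tuple[str, str]
    counts: pd.DataFrame
    restricted_to: str | None = None

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class ResolutionFraction:
    numerator: int
    denominator: int
    percent: float
    percent_rounded: int


@dataclass(frozen=True)
class OverlapSummary:
    state: ChromatinState
    size_a: int
    size_b: int
    intersection: int

    def __post_init__(self) -> None:
        if self.intersection > min(self.size_a, self.size_b):
            raise ValueError("intersection exceeds a set size")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def transition_table(
    states_t0: StateTable,
    states_t1: StateTable,
    gene_set: GeneSet | None = None,
) -> TransitionSummary:
    """Count state transitions gene by gene between two timepoints.

    Both tables must cover the same gene universe; an optional gene set
    restricts the census to its members (which must lie in the universe).
    """
    u0, u1 = states_t0.genes(), states_t1.genes()
    if u0 != u1:
        offending = sorted(u0 ^ u1)
        raise ValueError(f"gene universes differ; offending genes: {offending[:10]}")
    genes: Iterable[str] = u0
    if gene_set is not None:
        missing = gene_set.members - u0
        if missing:
            raise ValueError(
                f"gene set {gene_set.name!r} not contained in the universe: {sorted(missing)[:10]}"
            )
        genes = gene_set.members
    labels = [s.value for s in STATE_ORDER]
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for g in genes:
        counts.loc[states_t0.states[g].value, states_t1.states[g].value] += 1
    return TransitionSummary(
        condition_pair=(states_t0.condition, states_t1.condition),
        counts=counts,
        restricted_to=gene_set.name if gene_set is not None else None,
    )


def resolution_fraction(
    summary: TransitionSummary,
    from_state: ChromatinState,
    to_state: ChromatinState,
) -> ResolutionFraction:
    """Percentage of ``from_state`` genes at t0 found in ``to_state`` at t1.

    Reported as 100 * n(from->to) / n(from->any), with the nearest-integer
    rounding used when such fractions are quoted alongside raw counts.
    """
    row = summary.counts.loc[from_state.value]
    denominator = int(row.sum())
    if denominator == 0:
        raise ValueError(f"no genes in state {from_state.value} at t0")
    numerator = int(row[to_state.value])
    percent = 100.0 * numerator / denominator
    return ResolutionFraction(numerator, denominator, percent, _round_half_up(percent))


def resolved_fraction(
    summary: TransitionSummary, from_state: ChromatinState = ChromatinState.BIVALENT
) -> ResolutionFraction:
    """Percentage of ``from_state`` genes that left it (any other state)."""
    row = summary.counts.loc[from_state.value]
    denominator = int(row.sum())
    if denominator == 0:
        raise ValueError(f"no genes in state {from_state.value} at t0")
    numerator = denominator - int(row[from_state.value])
    percent = 100.0 * numerator / denominator
    return ResolutionFraction(numerator, denominator, percent, _round_half_up(percent))


def counts_to_percent(numerator: int, denominator: int) -> ResolutionFraction:
    """The bare printed-counts arithmetic: n/d as a rounded percentage."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    percent = 100.0 * numerator / denominator
    return ResolutionFraction(numerator, denominator, percent, _round_half_up(percent))


def shared_state_overlap(
    states_a: StateTable, states_b: StateTable, state: ChromatinState
) -> OverlapSummary:
    """Sizes and intersection of one state's gene sets in two tables."""
    if states_a.genes() != states_b.genes():
        raise ValueError("gene universes differ")
    set_a = states_a.genes_in_state(state)
    set_b = states_b.genes_in_state(state)
    return OverlapSummary(
        state=state,
        size_a=len(set_a),
        size_b=len(set_b),
        intersection=len(set_a & set_b),
    )


def expression_by_state(
    states: StateTable,
    expression: pd.DataFrame,
    condition: str | None = None,
    welch: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-state expression summaries and pairwise t-tests.

    ``expression`` has columns gene_id, condition, value. Returns
    (summary, pairs): per-state n/mean/SEM, and for every state pair with
    >= 2 expressed genes each, the t statistic and two-sided p-value
    (Welch by default; pooled-variance Student when ``welch=False``).
    Pairs lacking enough genes are skipped with a warning.
    """
    expr = expression
    if condition is not None:
        expr = expr[expr["condition"] == condition]
    values_by_state: Dict[ChromatinState, np.ndarray] = {}
    expr_map = dict(zip(expr["gene_id"], expr["value"]))
    for state in STATE_ORDER:
        vals = [expr_map[g] for g in states.genes_in_state(state) if g in expr_map]
        values_by_state[state] = np.asarray(vals, dtype=float)

    summary = pd.DataFrame(
        {
            "state": [s.value for s in STATE_ORDER],
            "n": [len(values_by_state[s]) for s in STATE_ORDER],
            "mean": [
                values_by_state[s].mean() if len(values_by_state[s]) else np.nan
                for s in STATE_ORDER
            ],
            "sem": [
                stats.sem(values_by_state[s]) if len(values_by_state[s]) > 1 else np.nan
                for s in STATE_ORDER
            ],
        }
    )

    rows: List[dict] = []
    for s1, s2 in combinations(STATE_ORDER, 2):
        v1, v2 = values_by_state[s1], values_by_state[s2]
        if len(v1) < 2 or len(v2) < 2:
            logger.warning(
                "skipping %s vs %s: fewer than 2 expressed genes in a group",
                s1.value,
                s2.value,
            )
            continue
        t, p = stats.ttest_ind(v1, v2, equal_var=not welch)
        rows.append(
            {"state_a": s1.value, "state_b": s2.value, "t": float(t), "p": float(p)}
        )
    pairs = pd.DataFrame(rows, columns=["state_a", "state_b", "t", "p"])
    return summary, pairs
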