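"""Inter-rater reliability (two-way ICC) and per-item internal consistency.

Pairwise ICCs are computed over survey *totals* for every rater pair that
scored enough of the same monkeys. Item-level Cronbach's alpha treats the
raters of a fully-crossed block as parallel measurements and the monkeys
as cases.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import SurveyTable
from .scoring import score_surveys

logger = logging.getLogger(__name__)

__all__ = [
    "icc_two_way",
    "pairwise_icc",
    "cronbach_alpha",
    "item_reliability",
    "ReliabilityReport",
    "ZERO_VARIANCE",
]

#: Sentinel for an item whose ratings show no variance at all.
ZERO_VARIANCE = "zero_variance"


class DegenerateMatrixError(ValueError):
    """The ratings matrix has no variance to apportion."""


def _two_way_mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (rows=subjects, columns=raters) of the two-way ANOVA."""
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way(m: np.ndarray, variant: str = "consistency_avg") -> float:
    """Two-way mixed, average-measures intraclass correlation.

    ``consistency_avg`` (McGraw-Wong C-k): ``(MSR - MSE) / MSR``.
    ``absolute_avg`` (A-k): ``(MSR - MSE) / (MSR + (MSC - MSE)/n)`` — also
    penalizes systematic rater offsets. The value is at most 1 and may be
    negative.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError(f"need an n>=2 by k>=2 matrix, got shape {m.shape}")
    if np.isnan(m).any():
        raise ValueError("ratings matrix must be complete (drop incomplete rows first)")
    msr, msc, mse = _two_way_mean_squares(m)
    if msr == 0 and mse == 0:
        raise DegenerateMatrixError("no between-subject or error variance")
    if variant == "consistency_avg":
        if msr == 0:
            raise DegenerateMatrixError("no between-subject variance")
        return float((msr - mse) / msr)
    if variant == "absolute_avg":
        n = m.shape[0]
        denom = msr + (msc - mse) / n
        if denom == 0:
            raise DegenerateMatrixError("degenerate variance decomposition")
        return float((msr - mse) / denom)
    raise ValueError(f"variant must be consistency_avg/absolute_avg, got {variant!r}")


def cronbach_alpha(m: np.ndarray):
    """Cronbach's alpha for an n-cases x k-measurements matrix.

    ``alpha = k/(k-1) * (1 - sum(col variances) / var(row sums))`` with
    n-1 denominators. Returns the :data:`ZERO_VARIANCE` sentinel when the
    matrix carries no variance at all.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError(f"need at least 2 measurement columns, got shape {m.shape}")
    if m.shape[0] < 2:
        raise ValueError(f"need at least 2 cases, got shape {m.shape}")
    k = m.shape[1]
    col_var = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        if np.all(col_var == 0):
            return ZERO_VARIANCE
        return float("-inf")  # columns perfectly cancel; maximally inconsistent
    return float(k / (k - 1) * (1 - col_var.sum() / total_var))


@dataclass
class ReliabilityReport:
    """Pairwise and item-level reliability results."""

    pairwise_icc: list = field(default_factory=list)
    mean_pairwise_icc: float = float("nan")
    #: all unordered pairs among raters present in the table
    n_possible_pairs: int = 0
    #: pairs among raters that share >= 1 monkey with some other rater;
    #: raters with no overlap at all cannot enter any comparison
    n_considered_pairs: int = 0
    group_icc: float = float("nan")
    icc_variant: str = "consistency_avg"
    min_shared: int = 3
    item_alphas: dict = field(default_factory=dict)
    zero_variance_items: list = field(default_factory=list)
    retained_items: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pairwise_icc": self.pairwise_icc,
            "mean_pairwise_icc": self.mean_pairwise_icc,
            "n_possible_pairs": self.n_possible_pairs,
            "n_considered_pairs": self.n_considered_pairs,
            "n_qualifying_pairs": len(self.pairwise_icc),
            "group_icc": self.group_icc,
            "icc_variant": self.icc_variant,
            "min_shared": self.min_shared,
            "item_alphas": {str(k): v for k, v in self.item_alphas.items()},
            "zero_variance_items": self.zero_variance_items,
            "retained_items": self.retained_items,
        }


def _totals_matrix(table: SurveyTable, missing_policy: str) -> pd.DataFrame:
    scored = score_surveys(table, missing_policy=missing_policy)
    return scored.pivot(index="monkey_id", columns="rater_id", values="total")


def pairwise_icc(
    table: SurveyTable,
    min_shared: int = 3,
    variant: str = "consistency_avg",
    missing_policy: str = "strict",
) -> ReliabilityReport:
    """One ICC per rater pair sharing at least ``min_shared`` monkeys.

    ICCs are computed on survey totals; pairs with fewer shared monkeys (or
    degenerate shared ratings) are omitted. ``n_possible_pairs`` counts all
    unordered pairs among the raters present, shared monkeys or not.
    """
    totals = _totals_matrix(table, missing_policy)
    raters = sorted(totals.columns)
    entries = []
    connected: set = set()
    for a, b in itertools.combinations(raters, 2):
        sub = totals[[a, b]].dropna()
        if len(sub) >= 1:
            connected.update((a, b))
        if len(sub) < min_shared:
            continue
        try:
            icc = icc_two_way(sub.to_numpy(), variant=variant)
        except DegenerateMatrixError:
            logger.warning("degenerate ratings for rater pair (%s, %s); skipped", a, b)
            continue
        entries.append({"rater_a": int(a), "rater_b": int(b), "n_shared": int(len(sub)), "icc": icc})
    if not entries:
        warnings.warn("no rater pair shares enough monkeys for an ICC", stacklevel=2)
    mean_icc = float(np.mean([e["icc"] for e in entries])) if entries else float("nan")
    n_raters = len(raters)
    n_conn = len(connected)
    return ReliabilityReport(
        pairwise_icc=entries,
        mean_pairwise_icc=mean_icc,
        n_possible_pairs=n_raters * (n_raters - 1) // 2,
        n_considered_pairs=n_conn * (n_conn - 1) // 2,
        icc_variant=variant,
        min_shared=min_shared,
    )


def group_icc(
    table: SurveyTable,
    block_raters,
    variant: str = "consistency_avg",
    missing_policy: str = "strict",
) -> float:
    """Single all-rater ICC over the fully-crossed block (complete cases)."""
    totals = _totals_matrix(table, missing_policy)
    block_raters = sorted(block_raters)
    absent = [r for r in block_raters if r not in totals.columns]
    if absent:
        raise KeyError(f"block raters absent from table: {absent}")
    sub = totals[block_raters].dropna()
    return icc_two_way(sub.to_numpy(), variant=variant)


def item_reliability(table: SurveyTable, block_raters) -> ReliabilityReport:
    """Per-item Cronbach's alpha over a fully-crossed rater block.

    For each item an (n monkeys x k raters) matrix of 0..3 scores is formed
    from complete cases; alpha is computed per item, zero-variance items are
    flagged, and the retained set is the items with positive alpha and
    nonzero variance.
    """
    block_raters = sorted(int(r) for r in block_raters)
    present = set(table.responses["rater_id"])
    absent = [r for r in block_raters if r not in present]
    if absent:
        raise KeyError(f"block raters absent from table: {absent}")
    scored = score_surveys(table, missing_policy="prorate")
    scored = scored[scored["rater_id"].isin(block_raters)]
    q = table.questionnaire
    item_alphas: dict[int, object] = {}
    zero_var, retained = [], []
    for item in q.item_ids:
        col = f"item_{item:02d}"
        mat = scored.pivot(index="monkey_id", columns="rater_id", values=col)
        mat = mat.reindex(columns=block_raters).dropna()
        if len(mat) < 2:
            logger.warning("item %d: fewer than 2 complete cases in block; skipped", item)
            item_alphas[item] = float("nan")
            continue
        alpha = cronbach_alpha(mat.to_numpy())
        item_alphas[item] = alpha
        if alpha == ZERO_VARIANCE:
            zero_var.append(item)
        elif isinstance(alpha, float) and alpha > 0:
            retained.append(item)
    return ReliabilityReport(
        item_alphas=item_alphas,
        zero_variance_items=zero_var,
        retained_items=retained,
    )
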