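"""Reverse-keyed scoring, per-monkey totals and distribution analysis.

Raw responses are ordinal 1..4; item scores are 0..3 with reverse-keyed
items flipped so that a higher score always means greater impairment.
A complete 36-item survey therefore totals between 0 and 108.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SurveyTable, VALID_RESPONSES

__all__ = [
    "score_item",
    "score_surveys",
    "total_score",
    "per_monkey_scores",
    "distribution_summary",
    "lilliefors_statistic",
    "lilliefors_test",
    "DistributionSummary",
]


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


def score_item(response: int, reverse_keyed: bool) -> int:
    """Map one ordinal response 1..4 to a 0..3 impairment score.

    Non-reversed items score ``response - 1``; reverse-keyed items score
    ``4 - response``.
    """
    if response not in VALID_RESPONSES:
        raise ValueError(f"response must be in {VALID_RESPONSES}, got {response!r}")
    return 4 - response if reverse_keyed else response - 1


def score_surveys(table: SurveyTable, missing_policy: str = "strict") -> pd.DataFrame:
    """Score every survey in a table.

    Returns one row per (rater_id, monkey_id) with columns
    ``item_01..item_NN`` (0..3 scores, NaN where skipped), ``n_answered``
    and ``total``. Under the ``strict`` policy the total is NaN whenever any
    item is missing; under ``prorate`` it is ``n_items * mean(answered)``
    rounded half-up.
    """
    if missing_policy not in ("strict", "prorate"):
        raise ValueError(f"missing_policy must be 'strict' or 'prorate', got {missing_policy!r}")
    q = table.questionnaire
    reverse = np.array([it.reverse_keyed for it in q.items])
    item_cols = [f"item_{i:02d}" for i in q.item_ids]
    if table.responses.empty:
        return pd.DataFrame(
            columns=["rater_id", "monkey_id", *item_cols, "n_answered", "total"])
    wide = table.to_wide()
    resp = wide[item_cols].to_numpy(dtype=float)
    scores = np.where(reverse[None, :], 4.0 - resp, resp - 1.0)
    out = wide[["rater_id", "monkey_id"]].copy()
    out[item_cols] = scores
    out["n_answered"] = np.sum(~np.isnan(scores), axis=1)
    out["total"] = _totals(scores, q.n_items, missing_policy)
    return out


def _totals(scores: np.ndarray, n_items: int, missing_policy: str) -> np.ndarray:
    n_answered = np.sum(~np.isnan(scores), axis=1)
    raw = np.nansum(scores, axis=1)
    if missing_policy == "strict":
        return np.where(n_answered == n_items, raw, np.nan)
    with np.errstate(invalid="ignore"):
        prorated = n_items * raw / n_answered
    # round half-up, not banker's rounding
    prorated = np.floor(prorated + 0.5)
    return np.where(n_answered > 0, prorated, np.nan)


def total_score(item_scores, n_items: int | None = None, missing_policy: str = "strict") -> float:
    """Total a single survey's item scores (0..3 each, NaN = skipped)."""
    if missing_policy not in ("strict", "prorate"):
        raise ValueError(f"missing_policy must be 'strict' or 'prorate', got {missing_policy!r}")
    scores = np.asarray(item_scores, dtype=float).reshape(1, -1)
    n_items = n_items or scores.shape[1]
    return float(_totals(scores, n_items, missing_policy)[0])


def per_monkey_scores(
    table: SurveyTable,
    aggregation: str = "mean",
    missing_policy: str = "strict",
) -> pd.Series:
    """Collapse survey totals to one value per monkey.

    Surveys whose total is undefined under the missing policy are dropped
    before aggregation. Returns a Series indexed by ``monkey_id``.
    """
    if aggregation not in ("mean", "median", "first"):
        raise ValueError(f"aggregation must be mean/median/first, got {aggregation!r}")
    scored = score_surveys(table, missing_policy=missing_policy)
    totals = scored.dropna(subset=["total"])
    if totals.empty:
        return pd.Series(dtype=float, name="score").rename_axis("monkey_id")
    grouped = totals.groupby("monkey_id")["total"]
    out = getattr(grouped, aggregation)() if aggregation != "first" else grouped.first()
    return out.rename("score")


def skewness(x: np.ndarray, corrected: bool = False) -> float:
    """Moment skewness g1 = m3 / m2^(3/2); G1 (bias-corrected) on request."""
    x = np.asarray(x, dtype=float)
    n = x.size
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        return float("nan")
    g1 = np.mean((x - x.mean()) ** 3) / m2 ** 1.5
    if corrected:
        g1 *= math.sqrt(n * (n - 1)) / (n - 2)
    return float(g1)


def lilliefors_statistic(x: np.ndarray) -> float:
    """Sup-distance between the ECDF and a normal CDF with estimated moments."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0:
        raise InsufficientDataError("Lilliefors statistic undefined for constant data")
    z = stats.norm.cdf((x - x.mean()) / sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - z)
    d_minus = np.max(z - (i - 1) / n)
    return float(max(d_plus, d_minus))


def _null_statistics(n: int, n_mc: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized null distribution of the Lilliefors statistic at size n."""
    samples = np.sort(rng.standard_normal((n_mc, n)), axis=1)
    means = samples.mean(axis=1, keepdims=True)
    sds = samples.std(axis=1, ddof=1, keepdims=True)
    z = stats.norm.cdf((samples - means) / sds)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - z, axis=1)
    d_minus = np.max(z - (i - 1) / n, axis=1)
    return np.maximum(d_plus, d_minus)


def lilliefors_test(
    x,
    n_mc: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Lilliefors normality test with a Monte-Carlo null.

    The p-value is the fraction of ``n_mc`` simulated normal samples (same
    n, statistic recomputed with estimated moments) whose statistic is at
    least the observed one; add-one smoothing keeps p in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise InsufficientDataError(f"need n >= 4, got {x.size}")
    ks = lilliefors_statistic(x)
    rng = np.random.default_rng(seed)
    null = _null_statistics(x.size, n_mc, rng)
    p = (1 + np.sum(null >= ks)) / (n_mc + 1)
    return ks, float(p)


@dataclass
class DistributionSummary:
    """Distributional analysis of per-monkey scores."""

    n: int
    mean: float
    sd: float
    skew: float
    ks_stat: float
    ks_p: float
    outlier_ids: list = field(default_factory=list)
    outlier_threshold: float = float("nan")
    outlier_k: float = 2.0
    skew_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "n": self.n, "mean": self.mean, "sd": self.sd, "skew": self.skew,
            "ks_stat": self.ks_stat, "ks_p": self.ks_p,
            "outlier_ids": list(self.outlier_ids),
            "outlier_threshold": self.outlier_threshold,
            "outlier_k": self.outlier_k, "skew_defined": self.skew_defined,
        }


def distribution_summary(
    scores: pd.Series,
    outlier_k: float = 2.0,
    corrected_skew: bool = False,
    n_mc: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> DistributionSummary:
    """Mean/SD/skewness, Lilliefors normality and the high-score outlier rule.

    Outliers are ids whose score is *strictly greater* than
    ``mean + outlier_k * sd``. ``scores`` may be any real Series indexed by
    monkey id (see :func:`per_monkey_scores`).
    """
    scores = pd.Series(scores).dropna()
    x = scores.to_numpy(dtype=float)
    if x.size < 4:
        raise InsufficientDataError(f"need n >= 4, got {x.size}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    threshold = mean + outlier_k * sd
    outliers = scores.index[x > threshold].tolist() if sd > 0 else []
    if sd == 0:
        skew, skew_defined = float("nan"), False
        ks_stat, ks_p = float("nan"), float("nan")
    else:
        skew, skew_defined = skewness(x, corrected=corrected_skew), True
        ks_stat, ks_p = lilliefors_test(x, n_mc=n_mc, seed=seed)
    return DistributionSummary(
        n=int(x.size), mean=mean, sd=sd, skew=skew,
        ks_stat=ks_stat, ks_p=ks_p,
        outlier_ids=outliers, outlier_threshold=threshold,
        outlier_k=outlier_k, skew_defined=skew_defined,
    )
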