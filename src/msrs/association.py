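"""Demographic associations: Spearman rank correlation and group summaries."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Demographics

__all__ = ["spearman_correlation", "group_summary", "AssociationReport"]


@dataclass
class AssociationReport:
    spearman_rho: float = float("nan")
    spearman_p: float = float("nan")
    n: int = 0
    group_means: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "n": self.n,
            "group_means": self.group_means,
        }


def _rank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # midranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2))
    return float(np.sum(rx * ry) / denom)


def spearman_correlation(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman's rho with midrank ties and a two-sided p-value.

    For n <= ``exact_max_n`` the p-value is an exact permutation p over all
    n! pairings; otherwise the usual t-approximation with n-2 df is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = _rank_pearson(x, y)
    if n <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt(np.sum(rx_c ** 2) * np.sum(ry_c ** 2))
        obs = abs(np.sum(rx_c * ry_c))
        count = 0
        total = 0
        # rho under pairing permutations is a monotone function of the dot product
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(np.sum(rx_c[list(perm)] * ry_c)) >= obs - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def group_summary(
    scores: pd.Series,
    demo: Demographics,
    by: str = "rank",
) -> dict:
    """Mean, SEM and n of per-monkey scores for each level of a demographic.

    ``by`` is ``rank`` or ``sex``. Levels with no scored monkeys are
    omitted with a warning; SEM is sd/sqrt(n) (NaN for singleton groups).
    """
    if by not in ("rank", "sex"):
        raise ValueError(f"by must be 'rank' or 'sex', got {by!r}")
    joined = (
        demo.records.set_index("monkey_id")[[by]]
        .join(pd.Series(scores, name="score"), how="inner")
        .dropna(subset=["score"])
    )
    out: dict[str, dict] = {}
    for level, grp in joined.groupby(by, observed=True):
        n = len(grp)
        sd = grp["score"].std(ddof=1) if n > 1 else float("nan")
        out[str(level)] = {
            "mean": float(grp["score"].mean()),
            "sem": float(sd / np.sqrt(n)) if n > 1 else float("nan"),
            "n": int(n),
        }
    expected = {"rank": ("low", "middle", "high"), "sex": ("female", "male")}[by]
    for level in expected:
        if level not in out:
            warnings.warn(f"no scored monkeys in {by} level {level!r}; omitted", stacklevel=2)
    return out


def association_report(scores: pd.Series, demo: Demographics) -> AssociationReport:
    """Spearman age correlation plus rank and sex group summaries."""
    ages = demo.age_of()
    joined = pd.DataFrame({"score": scores}).join(ages, how="inner").dropna()
    rho, p = spearman_correlation(joined["age_years"], joined["score"])
    return AssociationReport(
        spearman_rho=rho,
        spearman_p=p,
        n=len(joined),
        group_means={
            "rank": group_summary(scores, demo, by="rank"),
            "sex": group_summary(scores, demo, by="sex"),
        },
    )
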