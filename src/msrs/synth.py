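"""Multi-rater ordinal survey simulation from a latent factor model.

Monkeys draw latent factor scores; each item's latent value is a loading-
weighted combination plus item-specific noise; raters observe the latent
value through their own noise and a fixed threshold grid discretizes it to
the 1..4 response scale. Ground truth (factor scores, loadings, item
classes) is returned so downstream estimates can be checked against what
generated the data.

Item classes:

* ``reliable`` — shared monkey-level signal, modest rater noise; positive
  Cronbach's alpha by construction.
* ``unreliable`` — no shared signal; a monkey-level component enters with
  alternating sign across raters, so rater columns anti-correlate and the
  item's alpha is driven negative.
* ``zero_variance`` — a constant response from every rater.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import Demographics, ItemDef, Questionnaire, SurveyTable

__all__ = ["SimConfig", "SimTruth", "generate", "paperlike_preset"]

RANKS = ("low", "middle", "high")


@dataclass
class SimConfig:
    """Everything needed to generate one synthetic dataset."""

    n_monkeys: int = 105
    n_items: int = 36
    n_factors: int = 3
    loadings: np.ndarray | None = None          # p x K; zero rows = pure-noise items
    factor_corr: np.ndarray | None = None       # K x K, default identity
    rater_noise_sd: dict | float = 0.3          # per-rater or scalar
    thresholds: tuple = (-1.0, 0.5, 1.5)        # latent cutpoints -> scores 0..3
    reverse_keyed: frozenset = frozenset()
    zero_variance_items: frozenset = frozenset()
    unreliable_items: frozenset = frozenset()
    missing_rate: float = 0.0
    sparse: dict | None = None                  # {"n_raters": int, "n_surveys": int}
    complete_block: dict | None = None          # {"n_raters": int, "n_monkeys": int}
    age_effect: float = 0.0
    rank_effect: dict = field(default_factory=dict)   # level -> latent shift
    contaminant_frac: float = 0.0
    contaminant_shift: float = 0.0
    male_frac: float = 0.133
    unreliable_signal_sd: float = 1.0
    unreliable_noise_sd: float = 0.4
    seed: int = 0
    expect_positive_skew: bool = False          # metadata set by presets

    def __post_init__(self) -> None:
        if self.loadings is None:
            self.loadings = np.zeros((self.n_items, self.n_factors))
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape != (self.n_items, self.n_factors):
            raise ValueError(
                f"loadings must be {self.n_items} x {self.n_factors}, got {self.loadings.shape}"
            )
        if self.factor_corr is None:
            self.factor_corr = np.eye(self.n_factors)
        self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        if self.factor_corr.shape != (self.n_factors, self.n_factors):
            raise ValueError("factor_corr has inconsistent dimensions")
        if not all(a < b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError(f"thresholds must be strictly increasing, got {self.thresholds}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.sparse is None and self.complete_block is None:
            raise ValueError("at least one of sparse/complete_block design required")
        norms = np.sum(self.loadings ** 2, axis=1)
        if np.any(norms > 1.0 + 1e-9):
            raise ValueError("loading row norms must not exceed 1 (standardized items)")

    @property
    def reliable_items(self) -> frozenset:
        all_items = frozenset(range(1, self.n_items + 1))
        return all_items - self.zero_variance_items - self.unreliable_items

    def questionnaire(self) -> Questionnaire:
        return Questionnaire(
            tuple(
                ItemDef(i, f"item {i:02d}", i in self.reverse_keyed)
                for i in range(1, self.n_items + 1)
            )
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["loadings"] = self.loadings.tolist()
        d["factor_corr"] = self.factor_corr.tolist()
        for k in ("reverse_keyed", "zero_variance_items", "unreliable_items"):
            d[k] = sorted(d[k])
        return d


@dataclass
class SimTruth:
    """Ground truth underlying one generated dataset."""

    factor_scores: np.ndarray           # all monkeys (sparse + block) x K
    latent_item_values: np.ndarray      # monkeys x items, pre-noise/discretization
    loadings: np.ndarray
    item_class: dict                    # item_id -> reliable/unreliable/zero_variance
    monkey_ids: list
    block_monkey_ids: list
    block_rater_ids: list
    contaminant_ids: list
    rater_noise_sd: dict

    def to_dict(self) -> dict:
        return {
            "factor_scores": self.factor_scores.tolist(),
            "latent_item_values": self.latent_item_values.tolist(),
            "loadings": self.loadings.tolist(),
            "item_class": {str(k): v for k, v in self.item_class.items()},
            "monkey_ids": self.monkey_ids,
            "block_monkey_ids": self.block_monkey_ids,
            "block_rater_ids": self.block_rater_ids,
            "contaminant_ids": self.contaminant_ids,
            "rater_noise_sd": {str(k): v for k, v in self.rater_noise_sd.items()},
        }


def _rater_sd(config: SimConfig, rater: int) -> float:
    if isinstance(config.rater_noise_sd, dict):
        return float(config.rater_noise_sd[rater])
    return float(config.rater_noise_sd)


def _assignments(config: SimConfig, rng: np.random.Generator):
    """Survey design: (rater_id, monkey_id) pairs for sparse + block samples."""
    pairs: list[tuple[int, int]] = []
    n_sparse_monkeys = 0
    sparse_raters: list[int] = []
    if config.sparse is not None:
        n_raters = int(config.sparse["n_raters"])
        n_surveys = int(config.sparse["n_surveys"])
        n_sparse_monkeys = config.n_monkeys
        if n_surveys < n_sparse_monkeys:
            raise ValueError("sparse design needs at least one survey per monkey")
        sparse_raters = list(range(1, n_raters + 1))
        # primary rater covers a contiguous run of monkeys; extra surveys go
        # to a nearby rater so that some pairs share enough monkeys for ICC
        primary = {
            m: sparse_raters[(m - 1) * n_raters // n_sparse_monkeys]
            for m in range(1, n_sparse_monkeys + 1)
        }
        pairs.extend((primary[m], m) for m in primary)
        extras = n_surveys - n_sparse_monkeys
        monkeys = rng.choice(np.arange(1, n_sparse_monkeys + 1), size=extras,
                             replace=extras > n_sparse_monkeys)
        for m in monkeys:
            r = sparse_raters[(sparse_raters.index(primary[int(m)]) + 1) % n_raters]
            if (r, int(m)) not in pairs:
                pairs.append((r, int(m)))
    block_monkeys: list[int] = []
    block_raters: list[int] = []
    if config.complete_block is not None:
        kb = int(config.complete_block["n_raters"])
        nb = int(config.complete_block["n_monkeys"])
        first_rater = (max(sparse_raters) if sparse_raters else 0) + 1
        block_raters = list(range(first_rater, first_rater + kb))
        block_monkeys = list(range(n_sparse_monkeys + 1, n_sparse_monkeys + nb + 1))
        pairs.extend((r, m) for r in block_raters for m in block_monkeys)
    return pairs, block_monkeys, block_raters


def generate(config: SimConfig) -> tuple[SurveyTable, Demographics, SimTruth]:
    """Generate a survey table, demographics and ground truth from a config.

    Deterministic for a fixed config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    pairs, block_monkeys, block_raters = _assignments(config, rng)
    all_monkeys = sorted({m for _, m in pairs})
    all_raters = sorted({r for r, _ in pairs})
    n_total = len(all_monkeys)
    midx = {m: i for i, m in enumerate(all_monkeys)}

    # demographics -------------------------------------------------------
    ages = rng.uniform(4.0, 25.0, size=n_total)
    sexes = np.where(rng.random(n_total) < config.male_frac, "male", "female")
    ranks = rng.choice(RANKS, size=n_total)
    demo = Demographics(pd.DataFrame({
        "monkey_id": all_monkeys,
        "age_years": np.round(ages, 1),
        "sex": sexes,
        "rank": ranks,
        "housing": ["compound"] * n_total,
    }))

    # latent structure ---------------------------------------------------
    K = config.n_factors
    chol = np.linalg.cholesky(config.factor_corr + 1e-12 * np.eye(K))
    eta = rng.standard_normal((n_total, K)) @ chol.T
    n_contam = int(round(config.contaminant_frac * n_total))
    contam = sorted(rng.choice(all_monkeys, size=n_contam, replace=False).tolist()) if n_contam else []
    if contam:
        eta[[midx[m] for m in contam]] += config.contaminant_shift
    age_z = (ages - ages.mean()) / ages.std() if ages.std() > 0 else np.zeros(n_total)
    shift = config.age_effect * age_z
    if config.rank_effect:
        shift = shift + np.array([config.rank_effect.get(r, 0.0) for r in ranks])
    eta[:, 0] += shift

    p = config.n_items
    lam = config.loadings
    uniq = np.clip(1.0 - np.sum(lam ** 2, axis=1), 0.05, 1.0)
    latent = eta @ lam.T + rng.standard_normal((n_total, p)) * np.sqrt(uniq)

    # unreliable items: monkey-level component with alternating rater sign
    unreliable = sorted(config.unreliable_items)
    u_signal = rng.standard_normal((n_total, len(unreliable))) * config.unreliable_signal_sd
    rater_sign = {r: 1.0 if i % 2 == 0 else -1.0 for i, r in enumerate(all_raters)}

    thresholds = np.asarray(config.thresholds)
    zero_var = config.zero_variance_items
    reverse = config.reverse_keyed

    rows = []
    item_ids = np.arange(1, p + 1)
    ucol = {item: j for j, item in enumerate(unreliable)}
    for r, m in pairs:
        i = midx[m]
        sd_r = _rater_sd(config, r)
        observed = latent[i] + rng.standard_normal(p) * sd_r
        for item in unreliable:
            observed[item - 1] = (
                rater_sign[r] * u_signal[i, ucol[item]]
                + rng.standard_normal() * config.unreliable_noise_sd
            )
        scores = np.searchsorted(thresholds, observed, side="left")
        for item in item_ids:
            if item in zero_var:
                score = 0
            else:
                score = int(scores[item - 1])
            resp = (4 - score) if item in reverse else (score + 1)
            if config.missing_rate > 0 and rng.random() < config.missing_rate:
                resp = np.nan
            rows.append((r, m, int(item), resp))

    table = SurveyTable(
        pd.DataFrame(rows, columns=["rater_id", "monkey_id", "item_id", "response"]),
        config.questionnaire(),
    )
    item_class = {
        i: ("zero_variance" if i in zero_var else
            "unreliable" if i in config.unreliable_items else "reliable")
        for i in range(1, p + 1)
    }
    truth = SimTruth(
        factor_scores=eta,
        latent_item_values=latent,
        loadings=lam,
        item_class=item_class,
        monkey_ids=all_monkeys,
        block_monkey_ids=block_monkeys,
        block_rater_ids=block_raters,
        contaminant_ids=contam,
        rater_noise_sd={r: _rater_sd(config, r) for r in all_raters},
    )
    return table, demo, truth


# ---------------------------------------------------------------------------
# canonical preset


#: the 17 items with a shared signal (positive alpha by construction)
PRESET_RELIABLE = (1, 2, 3, 5, 9, 10, 13, 14, 15, 16, 17, 18, 21, 23, 26, 28, 31)
#: items emitting a constant response
PRESET_ZERO_VARIANCE = (7, 19, 24, 25, 30)


def paperlike_preset(seed: int = 0) -> SimConfig:
    """Canonical config: 105-monkey sparse sample rated by 15 raters across
    175 surveys, plus a separate fully-crossed 16-monkey x 4-rater block;
    36 items partitioned into 17 reliable / 14 unreliable / 5 zero-variance,
    3 latent factors, a mild positive age effect, scores decreasing with
    rank, and a small high-scoring contaminant subpopulation that makes the
    total-score distribution positively skewed.
    """
    n_items, K = 36, 3
    reliable = PRESET_RELIABLE
    zero_var = frozenset(PRESET_ZERO_VARIANCE)
    unreliable = frozenset(range(1, n_items + 1)) - set(reliable) - zero_var
    lam = np.zeros((n_items, K))
    # factor 1: 11 items (two reverse-keyed ones load negatively)
    for i in (1, 3, 9, 10, 13, 15, 17, 18, 21, 31):
        lam[i - 1, 0] = 0.72
    for i in (2, 5):
        lam[i - 1, 0] = -0.55
    # factor 2: three items; factor 3: two items plus a mild cross-loading
    for i in (14, 16, 23):
        lam[i - 1, 1] = 0.75
    for i in (26, 28):
        lam[i - 1, 2] = 0.72
    lam[31 - 1, 2] = 0.38
    lam[23 - 1, 2] = 0.38
    rater_sd = {r: 0.2 + 0.02 * (r - 1) for r in range(1, 16)}   # sparse raters
    rater_sd.update({r: 0.25 for r in range(16, 20)})            # block raters
    return SimConfig(
        n_monkeys=105,
        n_items=n_items,
        n_factors=K,
        loadings=lam,
        rater_noise_sd=rater_sd,
        thresholds=(-0.2, 1.1, 2.2),
        reverse_keyed=frozenset({2, 5, 14, 26, 28}),
        zero_variance_items=zero_var,
        unreliable_items=unreliable,
        missing_rate=0.01,
        sparse={"n_raters": 15, "n_surveys": 175},
        complete_block={"n_raters": 4, "n_monkeys": 16},
        age_effect=0.25,
        rank_effect={"low": 0.45, "middle": 0.0, "high": -0.45},
        contaminant_frac=0.055,
        contaminant_shift=2.2,
        seed=seed,
        expect_positive_skew=True,
    )
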