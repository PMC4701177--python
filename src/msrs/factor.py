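"""Exploratory factor analysis with bootstrap retention and loading CIs.

Extraction is maximum likelihood on the Pearson correlation matrix (the
classic Lawley profile-likelihood over uniquenesses, optimized with
L-BFGS-B), followed by varimax rotation. Factor retention uses the
eigenvalues-greater-than-one rule strengthened by bootstrap lower
confidence bounds; loading CIs come from refitting on bootstrap resamples
of the rows, with each replicate's factors aligned to the full-sample
solution by greedy Tucker-congruence matching and sign flips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_eigenvalues",
    "bootstrap_eigen_retention",
    "fit_efa",
    "varimax_rotate",
    "bootstrap_loadings",
    "significant_items",
    "align_to_reference",
    "tucker_congruence",
    "EigenReport",
    "FactorSolution",
]

_PSI_FLOOR = 0.005  # uniqueness clamp; Heywood guard


class ConvergenceError(RuntimeError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass
class EigenReport:
    """Ordered correlation-matrix eigenvalues with bootstrap retention."""

    eigenvalues: np.ndarray
    boot_median: np.ndarray | None = None
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    n_retained: int | None = None
    n_boot: int = 0
    level: float = 0.95
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {"eigenvalues": self.eigenvalues.tolist(), "n_boot": self.n_boot,
             "level": self.level, "seed": self.seed, "n_retained": self.n_retained}
        for k in ("boot_median", "ci_lower", "ci_upper"):
            v = getattr(self, k)
            d[k] = None if v is None else v.tolist()
        return d


@dataclass
class FactorSolution:
    """Rotated ML factor solution, optionally with bootstrap summaries."""

    loadings: np.ndarray            # p x K, full-sample, rotated
    uniquenesses: np.ndarray        # p
    var_explained: np.ndarray       # K, percent of total (p) variance
    item_ids: list = field(default_factory=list)
    rotation: str = "varimax"
    method: str = "ml"
    boot_median: np.ndarray | None = None
    boot_lower: np.ndarray | None = None
    boot_upper: np.ndarray | None = None
    significant: np.ndarray | None = None
    n_boot: int = 0
    n_failed: int = 0
    level: float = 0.95
    seed: int | None = None
    alignment: str = "tucker_congruence_greedy"

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> np.ndarray:
        return np.sum(self.loadings ** 2, axis=1)

    def to_dict(self) -> dict:
        d = {
            "item_ids": list(self.item_ids),
            "loadings": self.loadings.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "var_explained": self.var_explained.tolist(),
            "rotation": self.rotation, "method": self.method,
            "n_boot": self.n_boot, "n_failed": self.n_failed,
            "level": self.level, "seed": self.seed, "alignment": self.alignment,
        }
        for k in ("boot_median", "boot_lower", "boot_upper", "significant"):
            v = getattr(self, k)
            d[k] = None if v is None else np.asarray(v).tolist()
        return d


# ---------------------------------------------------------------------------
# eigenvalues & retention


def _correlation_matrix(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"need an n x p matrix with p >= 2, got shape {data.shape}")
    sds = data.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise DegenerateInputError(f"constant columns at indices {dead.tolist()}")
    return np.corrcoef(data, rowvar=False)


def correlation_eigenvalues(data: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the Pearson correlation matrix of columns."""
    corr = _correlation_matrix(data)
    vals = linalg.eigvalsh(corr)[::-1]
    return np.maximum(vals, 0.0) if vals[-1] > -1e-10 else vals


def bootstrap_eigen_retention(
    data: np.ndarray,
    n_boot: int = 10000,
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
) -> EigenReport:
    """Kaiser rule strengthened by bootstrap CIs on ordered eigenvalues.

    Rows (subjects) are resampled with replacement ``n_boot`` times; for
    each ordered eigenvalue a percentile CI is formed and the retained
    count is the number whose lower bound exceeds 1.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100 for stable percentiles, got {n_boot}")
    data = np.asarray(data, dtype=float)
    point = correlation_eigenvalues(data)
    rng = np.random.default_rng(seed)
    n, p = data.shape
    reps = np.empty((n_boot, p))
    got = 0
    while got < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            reps[got] = correlation_eigenvalues(data[idx])
        except DegenerateInputError:
            continue  # resample produced a constant column; redraw
        got += 1
    alpha = (1 - level) / 2
    lower = np.quantile(reps, alpha, axis=0)
    upper = np.quantile(reps, 1 - alpha, axis=0)
    median = np.median(reps, axis=0)
    n_retained = int(np.sum(lower > 1.0))
    return EigenReport(
        eigenvalues=point, boot_median=median, ci_lower=lower, ci_upper=upper,
        n_retained=n_retained, n_boot=n_boot, level=level,
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# maximum-likelihood extraction


def _ml_objective(psi: np.ndarray, corr: np.ndarray, k: int) -> float:
    sc = 1.0 / np.sqrt(psi)
    sstar = corr * np.outer(sc, sc)
    ev = linalg.eigvalsh(sstar)[::-1]
    e = ev[k:]
    e = np.maximum(e, 1e-12)
    return float(np.sum(e - np.log(e)) - (len(psi) - k))


def _ml_gradient(psi: np.ndarray, corr: np.ndarray, k: int) -> np.ndarray:
    sc = 1.0 / np.sqrt(psi)
    sstar = corr * np.outer(sc, sc)
    vals, vecs = linalg.eigh(sstar)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    lam = vecs[:, :k] * np.sqrt(np.maximum(vals[:k] - 1.0, 0.0))
    lam = lam * np.sqrt(psi)[:, None]
    g = lam @ lam.T + np.diag(psi) - corr
    return np.diag(g) / psi ** 2


def _loadings_from_psi(psi: np.ndarray, corr: np.ndarray, k: int) -> np.ndarray:
    sc = 1.0 / np.sqrt(psi)
    sstar = corr * np.outer(sc, sc)
    vals, vecs = linalg.eigh(sstar)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    lam = vecs[:, :k] * np.sqrt(np.maximum(vals[:k] - 1.0, 0.0))
    return lam * np.sqrt(psi)[:, None]


def _ml_extract(corr: np.ndarray, k: int, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    p = corr.shape[0]
    try:
        inv_diag = np.diag(linalg.inv(corr))
        start = (1 - 0.5 * k / p) / inv_diag
        start = np.clip(start, _PSI_FLOOR, 1.0)
    except linalg.LinAlgError:
        start = np.full(p, 0.5)
    res = optimize.minimize(
        _ml_objective, start, args=(corr, k), jac=_ml_gradient,
        method="L-BFGS-B", bounds=[(_PSI_FLOOR, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
    )
    psi = np.clip(res.x, _PSI_FLOOR, 1.0)
    if not res.success:
        # tolerate optimizer hiccups at an effectively stationary point
        g = _ml_gradient(psi, corr, k)
        interior = (psi > _PSI_FLOOR + 1e-9) & (psi < 1.0 - 1e-9)
        if np.max(np.abs(g[interior]), initial=0.0) > 1e-3:
            raise ConvergenceError(f"ML factor extraction failed: {res.message}")
    if np.any(res.x <= _PSI_FLOOR + 1e-9):
        logger.warning("Heywood case: %d uniqueness(es) clamped to %.3f",
                       int(np.sum(res.x <= _PSI_FLOOR + 1e-9)), _PSI_FLOOR)
    return _loadings_from_psi(psi, corr, k), psi


def _pa_extract(corr: np.ndarray, k: int, max_iter: int = 100, tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Principal-axis factoring (iterated communalities); sensitivity option."""
    p = corr.shape[0]
    try:
        h2 = 1 - 1 / np.diag(linalg.inv(corr))  # SMC start
    except linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    for _ in range(max_iter):
        r = corr.copy()
        np.fill_diagonal(r, h2)
        vals, vecs = linalg.eigh(r)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        lam = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))
        new_h2 = np.clip(np.sum(lam ** 2, axis=1), 0.0, 1.0 - _PSI_FLOOR)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    psi = np.clip(1 - h2, _PSI_FLOOR, 1.0)
    return lam, psi


def varimax_rotate(
    loadings: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    normalize: bool = True,
) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser-normalized by default).

    Preserves per-item communalities; a single-column matrix is returned
    unchanged.
    """
    lam = np.asarray(loadings, dtype=float).copy()
    p, k = lam.shape
    if k < 2:
        return lam
    if normalize:
        norms = np.sqrt(np.sum(lam ** 2, axis=1))
        norms[norms == 0] = 1.0
        lam = lam / norms[:, None]
    rot = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        lr = lam @ rot
        tmp = lr ** 3 - lr @ np.diag(np.sum(lr ** 2, axis=0)) / p
        u, s, vt = linalg.svd(lam.T @ tmp)
        rot = u @ vt
        d_new = np.sum(s)
        if d_new < d * (1 + tol):
            break
        d = d_new
    lam = lam @ rot
    if normalize:
        lam = lam * norms[:, None]
    return lam


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax objective: sum over factors of the variance of squared loadings."""
    sq = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(sq.var(axis=0)))


def fit_efa(
    data: np.ndarray,
    k: int,
    rotation: str = "varimax",
    method: str = "ml",
    item_ids=None,
    max_iter: int = 1000,
) -> FactorSolution:
    """Fit a k-factor model to an n x p item-score matrix.

    Variance explained per factor is ``100 * sum(loadings_j^2) / p``. The
    loading sign convention makes each factor's largest-|loading| item
    positive, so solutions are comparable across runs.
    """
    data = np.asarray(data, dtype=float)
    p = data.shape[1]
    if not 1 <= k < p:
        raise ValueError(f"need 1 <= k < p, got k={k}, p={p}")
    corr = _correlation_matrix(data)
    if method == "ml":
        lam, psi = _ml_extract(corr, k, max_iter=max_iter)
    elif method == "principal_axis":
        lam, psi = _pa_extract(corr, k)
    else:
        raise ValueError(f"method must be ml/principal_axis, got {method!r}")
    if rotation == "varimax":
        lam = varimax_rotate(lam)
    elif rotation != "none":
        raise ValueError(f"rotation must be varimax/none, got {rotation!r}")
    # order factors by explained variance, fix signs
    ssq = np.sum(lam ** 2, axis=0)
    order = np.argsort(ssq)[::-1]
    lam = lam[:, order]
    for j in range(k):
        if lam[np.argmax(np.abs(lam[:, j])), j] < 0:
            lam[:, j] = -lam[:, j]
    var_explained = 100.0 * np.sum(lam ** 2, axis=0) / p
    if item_ids is None:
        item_ids = list(range(1, p + 1))
    return FactorSolution(
        loadings=lam, uniquenesses=psi, var_explained=var_explained,
        item_ids=list(item_ids), rotation=rotation, method=method,
    )


# ---------------------------------------------------------------------------
# bootstrap loadings


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity between two loading vectors."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def align_to_reference(loadings: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permute and sign-flip columns to best match a reference solution.

    Greedy one-to-one matching on |Tucker congruence|; a column whose best
    congruence is negative is sign-flipped. Aligning a solution to itself
    is the identity.
    """
    lam = np.asarray(loadings, dtype=float)
    k = lam.shape[1]
    cong = np.array([
        [tucker_congruence(lam[:, j], reference[:, r]) for r in range(k)]
        for j in range(k)
    ])
    out = np.empty_like(lam)
    free_cols = set(range(k))
    free_refs = set(range(k))
    flat = sorted(
        ((abs(cong[j, r]), j, r) for j in range(k) for r in range(k)),
        reverse=True,
    )
    for _, j, r in flat:
        if j in free_cols and r in free_refs:
            out[:, r] = lam[:, j] * (1 if cong[j, r] >= 0 else -1)
            free_cols.discard(j)
            free_refs.discard(r)
    return out


def bootstrap_loadings(
    data: np.ndarray,
    k: int,
    n_boot: int = 10000,
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
    method: str = "ml",
    item_ids=None,
    max_fail_frac: float = 0.2,
) -> FactorSolution:
    """Full-sample EFA plus bootstrap medians, percentile CIs and
    significance flags for every loading.

    Each resample of the rows is refit, varimax-rotated and aligned to the
    full-sample solution before its loadings are recorded. A loading is
    significant when its CI excludes 0. Replicates that fail to converge or
    degenerate are dropped and counted; more than ``max_fail_frac`` of them
    aborts.
    """
    data = np.asarray(data, dtype=float)
    sol = fit_efa(data, k, rotation="varimax", method=method, item_ids=item_ids)
    rng = np.random.default_rng(seed)
    n, p = data.shape
    reps = np.empty((n_boot, p, k))
    failed = 0
    got = 0
    attempts = 0
    max_attempts = int(n_boot * (1 + max_fail_frac)) + 100
    while got < n_boot and attempts < max_attempts:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            rep = fit_efa(data[idx], k, rotation="varimax", method=method)
        except (ConvergenceError, DegenerateInputError, linalg.LinAlgError):
            failed += 1
            continue
        reps[got] = align_to_reference(rep.loadings, sol.loadings)
        got += 1
    if got < n_boot:
        raise ConvergenceError(
            f"bootstrap aborted: {failed}/{attempts} replicates failed "
            f"(> {max_fail_frac:.0%} allowed); only {got}/{n_boot} completed"
        )
    alpha = (1 - level) / 2
    sol.boot_median = np.median(reps, axis=0)
    sol.boot_lower = np.quantile(reps, alpha, axis=0)
    sol.boot_upper = np.quantile(reps, 1 - alpha, axis=0)
    sol.significant = (sol.boot_lower > 0) | (sol.boot_upper < 0)
    sol.n_boot = n_boot
    sol.n_failed = failed
    sol.level = level
    sol.seed = seed if isinstance(seed, int) else None
    return sol


def significant_items(solution: FactorSolution, factor: int) -> dict:
    """Item ids whose bootstrap CI on ``factor`` (0-based) excludes zero.

    Returns ``{"positive": [...], "negative": [...]}`` split by loading
    sign; a CI touching zero is not significant.
    """
    if solution.boot_lower is None or solution.boot_upper is None:
        raise ValueError("bootstrap summaries not populated; run bootstrap_loadings first")
    if not 0 <= factor < solution.n_factors:
        raise IndexError(f"factor index {factor} out of range [0, {solution.n_factors})")
    lo = solution.boot_lower[:, factor]
    hi = solution.boot_upper[:, factor]
    ids = np.asarray(solution.item_ids)
    return {
        "positive": ids[lo > 0].tolist(),
        "negative": ids[hi < 0].tolist(),
    }
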