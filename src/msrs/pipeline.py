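"""End-to-end analysis: score -> distribution -> reliability -> item filter
-> factor retention -> EFA + bootstrap -> demographic association.

A single seed governs all stochastic stages through spawned substreams, so
re-running with the same inputs and config reproduces the report exactly,
and any stage can be re-run in isolation with its own substream.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_report
from .core_io import Demographics, SurveyTable, validate
from .factor import bootstrap_eigen_retention, bootstrap_loadings
from .reliability import group_icc, item_reliability, pairwise_icc
from .scoring import distribution_summary, per_monkey_scores, score_surveys

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_report"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial = partial


@dataclass
class PipelineConfig:
    aggregation: str = "mean"
    missing_policy: str = "strict"
    outlier_k: float = 2.0
    icc_variant: str = "consistency_avg"
    min_shared: int = 3
    block_raters: list = field(default_factory=list)
    n_boot: int = 10000
    n_mc: int = 10000
    level: float = 0.95
    n_factors: int | None = None   # None = use bootstrap retention count
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seeds(seed: int) -> dict:
    names = ["distribution", "eigen", "loadings"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: child for name, child in zip(names, children)}


def efa_matrix(table: SurveyTable, items, missing_policy: str = "strict") -> tuple[np.ndarray, list]:
    """Complete-case survey x item score matrix restricted to ``items``."""
    scored = score_surveys(table, missing_policy="prorate")
    cols = [f"item_{i:02d}" for i in items]
    sub = scored[cols].dropna()
    return sub.to_numpy(dtype=float), list(items)


def run_pipeline(
    table: SurveyTable,
    demo: Demographics,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage and return the consolidated report as a dict."""
    config = config or PipelineConfig()
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "config": config.to_dict(),
        # timestamp goes to the log, not the report, so identical runs
        # produce byte-identical JSON
        "provenance": {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
        },
    }
    logger.info("pipeline start seed=%d at %s", config.seed,
                datetime.datetime.now(datetime.timezone.utc).isoformat())
    stage = "validate"
    try:
        report["validation"] = validate(table, demo).to_dict()

        stage = "distribution"
        scores = per_monkey_scores(table, aggregation=config.aggregation,
                                   missing_policy=config.missing_policy)
        summary = distribution_summary(
            scores, outlier_k=config.outlier_k, n_mc=config.n_mc,
            seed=np.random.default_rng(seeds["distribution"]),
        )
        report["distribution"] = summary.to_dict()

        stage = "pairwise_icc"
        rel = pairwise_icc(table, min_shared=config.min_shared,
                           variant=config.icc_variant,
                           missing_policy=config.missing_policy)
        report["reliability"] = rel.to_dict()

        stage = "item_reliability"
        retained = None
        if config.block_raters:
            report["reliability"]["group_icc"] = group_icc(
                table, config.block_raters, variant=config.icc_variant,
                missing_policy=config.missing_policy)
            item_rel = item_reliability(table, config.block_raters)
            report["reliability"]["item_alphas"] = {
                str(k): v for k, v in item_rel.item_alphas.items()}
            report["reliability"]["zero_variance_items"] = item_rel.zero_variance_items
            report["reliability"]["retained_items"] = item_rel.retained_items
            retained = item_rel.retained_items
        if not retained:
            # no block: keep every item with variance in the pooled data
            scored = score_surveys(table, missing_policy="prorate")
            retained = [
                i for i in table.questionnaire.item_ids
                if scored[f"item_{i:02d}"].std(ddof=1) > 0
            ]
            report["reliability"]["retained_items"] = retained

        stage = "eigen_retention"
        data, item_ids = efa_matrix(table, retained)
        eigen = bootstrap_eigen_retention(
            data, n_boot=config.n_boot,
            seed=np.random.default_rng(seeds["eigen"]), level=config.level)
        report["eigen"] = eigen.to_dict()

        stage = "efa"
        k = config.n_factors or eigen.n_retained
        if k and k >= 1:
            sol = bootstrap_loadings(
                data, k, n_boot=config.n_boot,
                seed=np.random.default_rng(seeds["loadings"]),
                level=config.level, item_ids=item_ids)
            report["factor_solution"] = sol.to_dict()
        else:
            logger.warning("no factor retained; EFA stage skipped")
            report["factor_solution"] = None

        stage = "association"
        report["association"] = association_report(scores, demo).to_dict()
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc, report) from exc
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, float) and (obj != obj):  # NaN -> null
        return None
    return obj


def report_json(report: dict) -> str:
    return json.dumps(_jsonable(report), indent=1, sort_keys=True, allow_nan=False)


def report_markdown(report: dict) -> str:
    """Human-readable summary mirroring the analysis stage order."""
    lines = ["# Survey analysis report", ""]
    dist = report.get("distribution")
    if dist:
        lines += [
            "## Score distribution",
            f"- n = {dist['n']}, mean = {dist['mean']:.2f}, sd = {dist['sd']:.2f}, "
            f"skew = {dist['skew']:.2f}",
            f"- Lilliefors KS = {dist['ks_stat']:.3f}, p = {dist['ks_p']:.4f}",
            f"- outliers (> mean + {dist['outlier_k']:g} sd): "
            f"{len(dist['outlier_ids'])} ({dist['outlier_ids']})",
            "",
        ]
    rel = report.get("reliability")
    if rel:
        lines += [
            "## Reliability",
            f"- qualifying rater pairs: {len(rel['pairwise_icc'])} of "
            f"{rel['n_possible_pairs']} possible",
            f"- mean pairwise ICC ({rel['icc_variant']}): {rel['mean_pairwise_icc']:.3f}",
        ]
        if not isinstance(rel.get("group_icc"), (type(None), str)) and rel.get("group_icc") == rel.get("group_icc"):
            lines.append(f"- block group ICC: {rel['group_icc']:.3f}")
        lines += [
            f"- zero-variance items: {rel.get('zero_variance_items', [])}",
            f"- retained items ({len(rel.get('retained_items', []))}): "
            f"{rel.get('retained_items', [])}",
            "",
        ]
    eigen = report.get("eigen")
    if eigen:
        lines += [
            "## Factor retention",
            f"- leading eigenvalues: "
            f"{[round(v, 3) for v in eigen['eigenvalues'][:5]]}",
            f"- retained (bootstrap lower CI > 1): {eigen['n_retained']}",
            "",
        ]
    sol = report.get("factor_solution")
    if sol:
        ve = ", ".join(f"{v:.2f}%" for v in sol["var_explained"])
        lines += ["## Factor solution", f"- variance explained: {ve}", ""]
    assoc = report.get("association")
    if assoc:
        lines += [
            "## Demographic association",
            f"- Spearman age correlation: rho = {assoc['spearman_rho']:.3f}, "
            f"p = {assoc['spearman_p']:.4f} (n = {assoc['n']})",
            "",
        ]
    return "\n".join(lines)


def write_report(report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_json(report))
    (out / "report.md").write_text(report_markdown(report))
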