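"""Domain types and file I/O for multi-rater ordinal survey data.

The in-memory representation of a survey table is a long-format
:class:`pandas.DataFrame` with one row per (rater, monkey, item) response.
Missing (skipped) answers are kept as ``NaN`` — they are never imputed at
load time; downstream stages decide how to handle them.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ItemDef",
    "Questionnaire",
    "SurveyTable",
    "Demographics",
    "ValidationReport",
    "SchemaError",
    "SurveyValidationError",
    "default_questionnaire",
    "load_survey_table",
    "save_survey_table",
    "load_demographics",
    "save_demographics",
    "validate",
]

VALID_RESPONSES = (1, 2, 3, 4)
RANK_LEVELS = ("low", "middle", "high", "unknown")
SEX_LEVELS = ("female", "male")

_LONG_COLUMNS = ["rater_id", "monkey_id", "item_id", "response"]
_DEMO_COLUMNS = ["monkey_id", "age_years", "sex", "rank", "housing"]


class SchemaError(ValueError):
    """A required column or field is absent or malformed."""


class SurveyValidationError(ValueError):
    """A record violates the survey response contract."""


@dataclass(frozen=True)
class ItemDef:
    """One questionnaire item."""

    item_id: int
    text: str
    reverse_keyed: bool


@dataclass(frozen=True)
class Questionnaire:
    """An ordered set of ordinal items with reverse-key flags.

    Invariants: item ids are unique and contiguous ``1..n``; at least one
    item is present.
    """

    items: tuple[ItemDef, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("questionnaire must contain at least one item")
        ids = [it.item_id for it in self.items]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(
                f"item ids must be contiguous 1..{len(ids)}, got {ids}"
            )

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[int]:
        return [it.item_id for it in self.items]

    @property
    def reverse_keyed_ids(self) -> frozenset[int]:
        return frozenset(it.item_id for it in self.items if it.reverse_keyed)

    def reversed_copy(self) -> "Questionnaire":
        """Return a questionnaire with every reverse flag flipped."""
        return Questionnaire(
            tuple(
                ItemDef(it.item_id, it.text, not it.reverse_keyed)
                for it in self.items
            )
        )

    @classmethod
    def from_dict(cls, payload: dict) -> "Questionnaire":
        items = tuple(
            ItemDef(int(d["item_id"]), str(d.get("text", "")), bool(d["reverse_keyed"]))
            for d in payload["items"]
        )
        return cls(items)

    def to_dict(self) -> dict:
        return {
            "items": [
                {"item_id": it.item_id, "text": it.text, "reverse_keyed": it.reverse_keyed}
                for it in self.items
            ]
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "Questionnaire":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def default_questionnaire() -> Questionnaire:
    """The packaged canonical 36-item questionnaire definition.

    The reverse-key set is data, not code: it is read from the packaged
    ``data/questionnaire.json`` and can be replaced by passing any other
    questionnaire file to the loaders.
    """
    payload = json.loads(
        resources.files("msrs").joinpath("data/questionnaire.json").read_text()
    )
    return Questionnaire.from_dict(payload)


@dataclass
class SurveyTable:
    """Long-format responses plus the questionnaire they answer.

    ``responses`` columns: ``rater_id, monkey_id, item_id, response`` where
    ``response`` is a float in {1,2,3,4} or ``NaN`` for a skipped answer.
    A *survey* is the set of rows sharing ``(rater_id, monkey_id)``.
    """

    responses: pd.DataFrame
    questionnaire: Questionnaire

    def __post_init__(self) -> None:
        missing = [c for c in _LONG_COLUMNS if c not in self.responses.columns]
        if missing:
            raise SchemaError(f"survey table missing columns: {missing}")
        self.responses = self.responses[_LONG_COLUMNS].reset_index(drop=True)
        bad_items = set(self.responses["item_id"]) - set(self.questionnaire.item_ids)
        if bad_items:
            raise SurveyValidationError(
                f"responses reference unknown item ids: {sorted(bad_items)}"
            )

    # -- basic counts ---------------------------------------------------
    @property
    def n_responses(self) -> int:
        return len(self.responses)

    @property
    def n_raters(self) -> int:
        return self.responses["rater_id"].nunique()

    @property
    def n_monkeys(self) -> int:
        return self.responses["monkey_id"].nunique()

    @property
    def n_surveys(self) -> int:
        return len(self.responses[["rater_id", "monkey_id"]].drop_duplicates())

    def survey_keys(self) -> pd.DataFrame:
        return (
            self.responses[["rater_id", "monkey_id"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    # -- layout conversion ----------------------------------------------
    def to_wide(self) -> pd.DataFrame:
        """One row per survey, item columns named ``item_01..item_NN``."""
        wide = self.responses.pivot(
            index=["rater_id", "monkey_id"],
            columns="item_id",
            values="response",
        )
        wide = wide.reindex(columns=self.questionnaire.item_ids)
        wide.columns = [f"item_{i:02d}" for i in self.questionnaire.item_ids]
        return wide.reset_index()

    @classmethod
    def from_wide(
        cls,
        wide: pd.DataFrame,
        questionnaire: Questionnaire,
        column_map: dict[str, int] | None = None,
    ) -> "SurveyTable":
        """Build a table from a one-row-per-survey frame.

        Item columns default to ``item_01..item_NN``; pass ``column_map``
        ({column name -> item id}) for any other header convention.
        """
        if column_map is None:
            column_map = {
                f"item_{i:02d}": i for i in questionnaire.item_ids
            }
        missing = [c for c in ("rater_id", "monkey_id") if c not in wide.columns]
        missing += [c for c in column_map if c not in wide.columns]
        if missing:
            raise SchemaError(f"wide survey table missing columns: {missing}")
        long = wide.melt(
            id_vars=["rater_id", "monkey_id"],
            value_vars=list(column_map),
            var_name="_col",
            value_name="response",
        )
        long["item_id"] = long["_col"].map(column_map)
        long = long.drop(columns="_col")
        # blank cells in a wide file are skipped answers, keep the rows
        return cls(_coerce_long(long), questionnaire)

    def copy(self) -> "SurveyTable":
        return SurveyTable(self.responses.copy(), self.questionnaire)


@dataclass
class Demographics:
    """Per-monkey demographic records."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("monkey_id", "age_years", "sex", "rank") if c not in self.records.columns]
        if missing:
            raise SchemaError(f"demographics missing columns: {missing}")
        if "housing" not in self.records.columns:
            self.records = self.records.assign(housing="")
        self.records = self.records[_DEMO_COLUMNS].reset_index(drop=True)
        bad_rank = set(self.records["rank"]) - set(RANK_LEVELS)
        if bad_rank:
            raise SurveyValidationError(f"unknown rank levels: {sorted(bad_rank)}")
        bad_sex = set(self.records["sex"]) - set(SEX_LEVELS)
        if bad_sex:
            raise SurveyValidationError(f"unknown sex levels: {sorted(bad_sex)}")
        if (self.records["age_years"] <= 0).any():
            bad = self.records.loc[self.records["age_years"] <= 0, "monkey_id"].tolist()
            raise SurveyValidationError(f"non-positive age for monkeys: {bad}")

    @property
    def n_monkeys(self) -> int:
        return len(self.records)

    def age_of(self) -> pd.Series:
        return self.records.set_index("monkey_id")["age_years"]


@dataclass
class ValidationReport:
    """Outcome of a non-throwing consistency check on a survey table."""

    n_surveys: int
    n_monkeys: int
    n_raters: int
    out_of_range: list = field(default_factory=list)
    missing_rate: dict = field(default_factory=dict)
    duplicate_keys: list = field(default_factory=list)
    unknown_monkeys: list = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.out_of_range) + len(self.duplicate_keys) + len(self.unknown_monkeys)

    def to_dict(self) -> dict:
        return {
            "n_surveys": self.n_surveys,
            "n_monkeys": self.n_monkeys,
            "n_raters": self.n_raters,
            "out_of_range": self.out_of_range,
            "missing_rate": self.missing_rate,
            "duplicate_keys": self.duplicate_keys,
            "unknown_monkeys": self.unknown_monkeys,
            "n_violations": self.n_violations,
        }


# ---------------------------------------------------------------------------
# readers / writers


def _read_frame(path: str | Path, fmt: str | None) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(path.suffix.lower(), "csv")
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    if fmt == "xlsx":
        return pd.read_excel(path, engine="openpyxl")
    raise ValueError(f"unsupported format: {fmt!r}")


def _write_frame(df: pd.DataFrame, path: str | Path, fmt: str | None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(path.suffix.lower(), "csv")
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "tsv":
        df.to_csv(path, index=False, sep="\t")
    elif fmt == "xlsx":
        df.to_excel(path, index=False, engine="openpyxl")
    else:
        raise ValueError(f"unsupported format: {fmt!r}")


def _coerce_long(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("rater_id", "monkey_id", "item_id"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    resp = pd.to_numeric(df["response"], errors="coerce")
    bad = resp.notna() & ~resp.isin(VALID_RESPONSES)
    # non-numeric junk (coerced to NaN above) must not be confused with blanks
    originally_blank = df["response"].isna() | (df["response"].astype(str).str.strip() == "")
    junk = resp.isna() & ~originally_blank
    if bad.any() or junk.any():
        rows = sorted(df.index[bad | junk].tolist())
        raise SurveyValidationError(
            f"responses outside {{1..4, blank}} at rows {rows[:20]}"
        )
    df["response"] = resp.astype(float)
    return df[_LONG_COLUMNS]


def load_survey_table(
    path: str | Path,
    questionnaire: Questionnaire | None = None,
    fmt: str | None = None,
    layout: str = "long",
    column_map: dict[str, int] | None = None,
) -> SurveyTable:
    """Read a survey table from CSV/TSV/XLSX in long or wide layout.

    Blank responses are preserved as missing; any non-blank response outside
    {1,2,3,4} raises :class:`SurveyValidationError` naming the rows.
    """
    questionnaire = questionnaire or default_questionnaire()
    df = _read_frame(path, fmt)
    if layout == "wide":
        return SurveyTable.from_wide(df, questionnaire, column_map=column_map)
    if layout != "long":
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"long survey table missing columns: {missing}")
    return SurveyTable(_coerce_long(df), questionnaire)


def save_survey_table(
    table: SurveyTable,
    path: str | Path,
    fmt: str | None = None,
    layout: str = "long",
) -> None:
    if layout == "long":
        df = table.responses.copy()
        df["response"] = df["response"].astype("Int64")  # blanks stay blank
    elif layout == "wide":
        df = table.to_wide()
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    _write_frame(df, path, fmt)


def load_demographics(path: str | Path, fmt: str | None = None) -> Demographics:
    df = _read_frame(path, fmt)
    if df.empty:
        warnings.warn(f"demographics file {path} is empty", stacklevel=2)
        logger.warning("demographics file %s is empty", path)
        return Demographics(pd.DataFrame(columns=_DEMO_COLUMNS).astype({"monkey_id": int, "age_years": float}))
    missing = [c for c in ("monkey_id", "age_years", "sex", "rank") if c not in df.columns]
    if missing:
        raise SchemaError(f"demographics missing columns: {missing}")
    df = df.copy()
    df["monkey_id"] = df["monkey_id"].astype(int)
    df["age_years"] = df["age_years"].astype(float)
    df["rank"] = df["rank"].fillna("unknown")
    if "housing" in df.columns:
        df["housing"] = df["housing"].fillna("").astype(str)
    return Demographics(df)


def save_demographics(demo: Demographics, path: str | Path, fmt: str | None = None) -> None:
    _write_frame(demo.records, path, fmt)


def anonymize_ids(values: Iterable) -> tuple[list[int], dict]:
    """Map arbitrary (e.g. string) identifiers to 1-based integers.

    Returns the mapped list and the lookup used, so the mapping can be
    persisted alongside the anonymized data.
    """
    lookup: dict = {}
    out = []
    for v in values:
        if v not in lookup:
            lookup[v] = len(lookup) + 1
        out.append(lookup[v])
    return out, lookup


def validate(table: SurveyTable, demo: Demographics | None = None) -> ValidationReport:
    """Check a table for contract violations without modifying or raising.

    Reports out-of-range responses, duplicated (rater, monkey, item) keys,
    per-item missing rates and (if demographics are given) monkeys absent
    from the demographics table.
    """
    df = table.responses
    resp = df["response"]
    out_of_range = [
        {"row": int(i), "rater_id": int(r.rater_id), "monkey_id": int(r.monkey_id),
         "item_id": int(r.item_id), "response": float(r.response)}
        for i, r in df[resp.notna() & ~resp.isin(VALID_RESPONSES)].iterrows()
    ]
    dup_mask = df.duplicated(subset=["rater_id", "monkey_id", "item_id"], keep="first")
    duplicate_keys = [
        {"rater_id": int(r.rater_id), "monkey_id": int(r.monkey_id), "item_id": int(r.item_id)}
        for r in df[dup_mask].itertuples()
    ]
    missing_rate = {
        int(item): float(grp.isna().mean())
        for item, grp in resp.groupby(df["item_id"])
    }
    unknown_monkeys: list[int] = []
    if demo is not None and demo.n_monkeys > 0:
        known = set(demo.records["monkey_id"])
        unknown_monkeys = sorted(int(m) for m in set(df["monkey_id"]) - known)
    return ValidationReport(
        n_surveys=table.n_surveys,
        n_monkeys=table.n_monkeys,
        n_raters=table.n_raters,
        out_of_range=out_of_range,
        missing_rate=missing_rate,
        duplicate_keys=duplicate_keys,
        unknown_monkeys=unknown_monkeys,
    )
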