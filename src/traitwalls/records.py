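"""Reading, validating and writing record, event and result tables.

The raw input is one row per design (a distinct engineered type, of which
many physical units may have been built) carrying a calendar year and a
positive functional-trait value. Validation is total: every input row is
either retained or counted in exactly one rejection category.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig

EVENT_KINDS = ("competitor", "disturbance")


class RecordsError(ValueError):
    """Malformed or unusable input table."""


@dataclass(frozen=True)
class EventRecord:
    """A dated event: a competitor first appearance or a disturbance."""

    name: str
    year: int
    kind: str

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise RecordsError(
                f"event {self.name!r}: unknown kind {self.kind!r} "
                f"(expected one of {EVENT_KINDS})"
            )


@dataclass
class ValidationReport:
    """Row-level accounting for a record-table read."""

    n_input: int = 0
    n_kept: int = 0
    counts: dict = field(default_factory=lambda: {
        "missing_field": 0,
        "nonpositive_trait": 0,
        "out_of_range_year": 0,
        "never_produced": 0,
    })

    @property
    def n_rejected(self) -> int:
        return sum(self.counts.values())

    def is_clean(self) -> bool:
        return self.n_rejected == 0

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept, "counts": dict(self.counts)}


def read_trait_records(path, config: PipelineConfig) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a delimited record table, validating each row.

    Returns the retained rows (columns ``design_id``, ``year``,
    ``trait_value`` and, when present, ``n_built``) plus a
    :class:`ValidationReport` counting rejected rows per category. Rows
    with a missing/empty id, unparsable year or trait, nonpositive trait,
    out-of-range year, or a false ``produced`` flag are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"record table not found: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except Exception as exc:  # malformed CSV structure
        raise RecordsError(f"unreadable record table {path}: {exc}") from exc

    cols = config.columns
    mandatory = [cols["design_id"], cols["year"], cols["trait_value"]]
    missing = [c for c in mandatory if c not in raw.columns]
    if missing:
        raise RecordsError(f"record table {path} is missing mandatory columns: {missing}")
    if len(raw) == 0:
        raise RecordsError(f"record table {path} contains no parsable rows")

    report = ValidationReport(n_input=len(raw))
    ids = raw[cols["design_id"]].str.strip()
    years = pd.to_numeric(raw[cols["year"]], errors="coerce")
    traits = pd.to_numeric(raw[cols["trait_value"]], errors="coerce")
    n_built = None
    if cols.get("n_built") in raw.columns:
        n_built = pd.to_numeric(raw[cols["n_built"]], errors="coerce")
    produced = None
    if cols.get("produced") in raw.columns:
        produced = raw[cols["produced"]].str.strip().str.lower()

    bad_field = (ids == "") | years.isna() | traits.isna() | (years % 1 != 0)
    bad_trait = ~bad_field & (traits <= 0)
    bad_year = ~bad_field & ~bad_trait & (
        (years < config.year_start) | (years > config.year_end)
    )
    if produced is not None:
        falsy = produced.isin(("0", "false", "no", "n", "f"))
        bad_produced = ~bad_field & ~bad_trait & ~bad_year & falsy
    else:
        bad_produced = pd.Series(False, index=raw.index)

    report.counts["missing_field"] = int(bad_field.sum())
    report.counts["nonpositive_trait"] = int(bad_trait.sum())
    report.counts["out_of_range_year"] = int(bad_year.sum())
    report.counts["never_produced"] = int(bad_produced.sum())

    keep = ~(bad_field | bad_trait | bad_year | bad_produced)
    out = pd.DataFrame({
        "design_id": ids[keep].to_numpy(),
        "year": years[keep].astype(int).to_numpy(),
        "trait_value": traits[keep].astype(float).to_numpy(),
    })
    if n_built is not None:
        out["n_built"] = n_built[keep].to_numpy()
    report.n_kept = len(out)
    if report.n_kept == 0:
        raise RecordsError(
            f"record table {path}: no parsable rows survive validation "
            f"(rejections: {report.counts})"
        )
    return out.reset_index(drop=True), report


def read_events(path) -> list[EventRecord]:
    """Read an event table (``name,year,kind``), sorted ascending by year."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"event table not found: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except pd.errors.EmptyDataError:
        return []
    except Exception as exc:
        raise RecordsError(f"unreadable event table {path}: {exc}") from exc
    if len(raw) == 0:
        return []
    for col in ("name", "year", "kind"):
        if col not in raw.columns:
            raise RecordsError(f"event table {path} is missing column {col!r}")
    events = []
    for i, row in raw.iterrows():
        try:
            year = int(row["year"])
        except ValueError as exc:
            raise RecordsError(f"event table {path}, row {i + 1}: bad year {row['year']!r}") from exc
        kind = row["kind"].strip()
        if kind not in EVENT_KINDS:
            raise RecordsError(
                f"event table {path}, row {i + 1} ({row['name']!r}): unknown kind {kind!r}"
            )
        events.append(EventRecord(name=row["name"], year=year, kind=kind))
    return sorted(events, key=lambda e: e.year)


def write_events(events: list[EventRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(e) for e in events]).to_csv(path, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_report(results, path) -> None:
    """Serialize a pipeline product to delimited or structured text.

    DataFrames go to CSV at full float precision (lossless round trip to
    well below 1e-9). Dataclasses, dicts and lists go to JSON. Anything
    with a ``to_frame()`` method (e.g. a model-fit table) is written as CSV
    via that frame — unless the target path ends in ``.json``, which forces
    structured JSON output.
    """
    path = Path(path)
    as_json = path.suffix.lower() == ".json"
    if not as_json and hasattr(results, "to_frame") and not isinstance(results, pd.Series):
        results = results.to_frame()
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, index=False)
        return
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(results), fh, indent=2, default=str)
        fh.write("\n")


def read_summary_series(path) -> pd.DataFrame:
    return pd.read_csv(path)
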