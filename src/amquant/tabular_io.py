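"""Reading, validating and writing colonization tables.

Two input dialects are supported, both plain delimited text with a header row:

* ``grid`` — one row per (sample, replicate) with percentage columns
  ``Total, Hyphopodia, IntrHyphae, Arbuscule, Vesicle`` (any non-empty
  subset of the five).
* ``trouvelot`` — one row per scored root fragment with a ``Scoring``
  column holding codes such as ``3A3``, ``5A2`` or ``0``.

Header names are matched case-insensitively after trimming; canonical names
are emitted on output.  An optional ``trt`` column (a second experimental
factor) is accepted in either dialect and carried through for two-way ANOVA.

The first sample encountered in the file is treated as the control, and the
first-appearance order of samples fixes all downstream ordering (tables,
comparisons, plots).
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .exceptions import DataValidationError, SchemaError

#: Canonical grid variable columns, in canonical display order.
GRID_VARIABLES = ("Total", "Hyphopodia", "IntrHyphae", "Arbuscule", "Vesicle")

#: Canonical Trouvelot index columns, in canonical display order.
TROUVELOT_VARIABLES = ("F", "M", "m", "a", "A")

SCORING_TYPES = ("grid", "trouvelot")

_CANONICAL = {"samples": "Samples", "replicates": "Replicates",
              "scoring": "Scoring", "trt": "trt"}
_CANONICAL.update({v.lower(): v for v in GRID_VARIABLES})


@dataclass(frozen=True)
class GridRecord:
    """One biological or technical replicate scored by gridline intersect."""

    sample: str
    replicate: str
    values: Mapping[str, float]
    trt: str | None = None


@dataclass(frozen=True)
class TrouvelotRecord:
    """One scored root fragment."""

    sample: str
    replicate: str
    scoring: str
    trt: str | None = None


@dataclass
class Dataset:
    """An ordered collection of colonization records of one scoring type."""

    scoring_type: str
    records: list
    sample_order: list[str]

    @property
    def control(self) -> str:
        """The control sample: first sample appearing in the input."""
        return self.sample_order[0]

    @property
    def variables(self) -> tuple[str, ...]:
        """Variables measured (grid columns present, or the Trouvelot indices)."""
        if self.scoring_type == "trouvelot":
            return TROUVELOT_VARIABLES
        present = set()
        for rec in self.records:
            present.update(rec.values)
        return tuple(v for v in GRID_VARIABLES if v in present)

    @property
    def has_trt(self) -> bool:
        return any(rec.trt is not None for rec in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame in file order with canonical column names."""
        rows = []
        for rec in self.records:
            row = {"Samples": rec.sample, "Replicates": rec.replicate}
            if self.scoring_type == "grid":
                row.update({v: rec.values[v] for v in self.variables
                            if v in rec.values})
            else:
                row["Scoring"] = rec.scoring
            if rec.trt is not None:
                row["trt"] = rec.trt
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Outcome of table validation.

    ``issues`` holds ``(row, column, message)`` triples; row numbers are
    1-based counting the header as row 1, i.e. what a spreadsheet shows.
    """

    issues: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def summary(self) -> str:
        if self.ok:
            return "ok"
        lines = [f"row {r}, column {c}: {m}" for r, c, m in self.issues]
        return "; ".join(lines)


def _canonicalize_header(columns: Iterable[str], scoring_type: str) -> dict[str, str]:
    """Map raw header names to canonical ones; raise SchemaError on problems."""
    mapping: dict[str, str] = {}
    seen: set[str] = set()
    for col in columns:
        key = str(col).strip().lower()
        if key not in _CANONICAL:
            raise SchemaError(f"unknown column {col!r}; expected one of "
                              f"{sorted(set(_CANONICAL.values()))}")
        canon = _CANONICAL[key]
        if canon in seen:
            raise SchemaError(f"duplicate column {canon!r}")
        seen.add(canon)
        mapping[col] = canon
    for required in ("Samples", "Replicates"):
        if required not in seen:
            raise SchemaError(f"missing required column {required!r}")
    if scoring_type == "trouvelot":
        if "Scoring" not in seen:
            raise SchemaError("missing required column 'Scoring'")
        extra = seen.intersection(GRID_VARIABLES)
        if extra:
            raise SchemaError(f"grid columns {sorted(extra)} not allowed in a "
                              "trouvelot table")
    elif scoring_type == "grid":
        if "Scoring" in seen:
            raise SchemaError("column 'Scoring' not allowed in a grid table")
        if not seen.intersection(GRID_VARIABLES):
            raise SchemaError("a grid table needs at least one variable column "
                              f"out of {list(GRID_VARIABLES)}")
    else:
        raise SchemaError(f"unknown scoring type {scoring_type!r}; "
                          f"expected one of {list(SCORING_TYPES)}")
    return mapping


def validate(rows: pd.DataFrame, scoring_type: str) -> ValidationReport:
    """Validate parsed table rows and enumerate *all* problems found.

    ``rows`` is a DataFrame of raw strings with canonical column names
    (as produced during :func:`read_colonization_table`).  Checks run in
    order: dimensions, NA/empty cells, grid value range, score grammar.
    """
    from .trouvelot import parse_score  # deferred: avoid import cycle

    report = ValidationReport()
    if len(rows) == 0:
        report.issues.append((1, "-", "empty dataset: no data rows"))
        return report

    value_cols = [c for c in rows.columns if c in GRID_VARIABLES]
    for i, (_, row) in enumerate(rows.iterrows()):
        file_row = i + 2  # header is row 1
        for col in rows.columns:
            cell = row[col]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) \
                    or str(cell).strip() == "":
                report.issues.append((file_row, col, "empty or NA cell"))
                continue
            text = str(cell).strip()
            if col in value_cols:
                try:
                    value = float(text)
                except ValueError:
                    report.issues.append(
                        (file_row, col, f"non-numeric value {text!r}"))
                    continue
                if not math.isfinite(value) or not 0.0 <= value <= 100.0:
                    report.issues.append(
                        (file_row, col,
                         f"value {text!r} outside the percentage range [0, 100]"))
            elif col == "Scoring" and scoring_type == "trouvelot":
                try:
                    parse_score(text)
                except Exception:
                    report.issues.append(
                        (file_row, col, f"invalid score code {text!r}"))
    return report


def read_colonization_table(source: Union[str, os.PathLike, io.TextIOBase],
                            scoring_type: str,
                            delimiter: str = ",") -> Dataset:
    """Read a colonization table from ``source`` into a validated Dataset.

    Parameters
    ----------
    source
        Path or open text stream of a delimited table with a header row.
    scoring_type
        ``"grid"`` or ``"trouvelot"``.
    delimiter
        Field separator, comma by default.

    Raises
    ------
    SchemaError
        If required columns are missing or unknown columns are present.
    DataValidationError
        If any cell fails validation; the error message lists every
        offending cell, so nothing is returned partially.
    """
    if scoring_type not in SCORING_TYPES:
        raise SchemaError(f"unknown scoring type {scoring_type!r}; "
                          f"expected one of {list(SCORING_TYPES)}")
    raw = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False,
                      skipinitialspace=True)
    mapping = _canonicalize_header(raw.columns, scoring_type)
    raw = raw.rename(columns=mapping)

    report = validate(raw, scoring_type)
    if not report.ok:
        raise DataValidationError(
            f"invalid {scoring_type} table: {report.summary()}", report)

    has_trt = "trt" in raw.columns
    records: list = []
    sample_order: list[str] = []
    for _, row in raw.iterrows():
        sample = str(row["Samples"]).strip()
        replicate = str(row["Replicates"]).strip()
        trt = str(row["trt"]).strip() if has_trt else None
        if sample not in sample_order:
            sample_order.append(sample)
        if scoring_type == "grid":
            values = {v: float(row[v]) for v in GRID_VARIABLES if v in raw.columns}
            records.append(GridRecord(sample, replicate, values, trt))
        else:
            records.append(TrouvelotRecord(sample, replicate,
                                           str(row["Scoring"]).strip(), trt))
    return Dataset(scoring_type, records, sample_order)


def _format_float(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return format(float(value), ".6f")


def write_summary_tables(summary, basename: str) -> tuple[str, str]:
    """Write the two summary CSVs and return their paths.

    Produces ``<basename>_per_Replicate.csv`` and ``<basename>_per_Sample.csv``
    with numeric cells at 6 decimal places; a missing standard error (single
    biological replicate) is written as an empty cell.
    """
    rep_path = f"{basename}_per_Replicate.csv"
    sample_path = f"{basename}_per_Sample.csv"
    try:
        summary.per_replicate.to_csv(rep_path, index=False,
                                     float_format="%.6f")
        per_sample = summary.per_sample.copy()
        for col in per_sample.columns:
            if per_sample[col].dtype.kind == "f":
                per_sample[col] = per_sample[col].map(_format_float)
        per_sample.to_csv(sample_path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write summary tables for {basename!r}: {exc}") from exc
    return rep_path, sample_path


def write_stat_table(stat, basename: str) -> str:
    """Write ``<basename>_stat.csv``: sample pair columns then one adjusted
    p-value column per variable.  Returns the path."""
    path = f"{basename}_stat.csv"
    wide = stat.wide()
    try:
        wide.to_csv(path, index=False, float_format="%.6g")
    except OSError as exc:
        raise OSError(f"cannot write stat table {path!r}: {exc}") from exc
    return path
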