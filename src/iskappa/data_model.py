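"""Case-level data model: reading, validation, eligibility, and per-rater aggregation.

One row of input is one sign-out case: an opaque case id, the rater
(pathologist) who signed it out, and ordinal scores on up to four grading
axes — tubular score (TS), nuclear score (NS), mitotic score (MS), each in
{1, 2, 3}, and the Nottingham grade (G) derived from their sum.  Any score
may be absent: resections without an invasive focus (e.g. post-neoadjuvant
pT0, pure DCIS pTis) carry no grade.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Grading axes, in conventional reporting order.
AXES = ("TS", "NS", "MS", "G")

#: Valid ordinal score levels on every axis.
SCORE_LEVELS = (1, 2, 3)

#: Default CSV column for each logical field; overridable via a schema map.
DEFAULT_SCHEMA: dict[str, str] = {
    "case_id": "case_id",
    "rater_id": "pathologist",
    "TS": "tubular_score",
    "NS": "nuclear_score",
    "MS": "mitotic_score",
    "G": "grade",
    "t_stage": "t_stage",
}


@dataclass(frozen=True)
class CaseRecord:
    """A single signed-out case with its ordinal scores.

    ``ts``/``ns``/``ms``/``grade`` are ``None`` when the score was not
    reported; ``t_stage`` is a free-text pathologic stage label when present.
    """

    case_id: str
    rater_id: str
    ts: int | None = None
    ns: int | None = None
    ms: int | None = None
    grade: int | None = None
    t_stage: str | None = None

    def __post_init__(self) -> None:
        if not self.rater_id:
            raise ValueError("rater_id must be non-empty")
        for name in ("ts", "ns", "ms", "grade"):
            v = getattr(self, name)
            if v is not None and v not in SCORE_LEVELS:
                raise ValueError(f"{name}={v!r} outside {{1,2,3}}")

    def score(self, axis: str) -> int | None:
        """Score on ``axis`` (one of TS/NS/MS/G), or None if absent."""
        return getattr(self, _AXIS_ATTR[axis])


_AXIS_ATTR = {"TS": "ts", "NS": "ns", "MS": "ms", "G": "grade"}


@dataclass
class RaterProfile:
    """Per-rater score-level counts and interpretive rates on one axis.

    ``counts[k-1]`` is the number of the rater's cases scored ``k``; the
    denominator ``n_axis`` excludes cases with no score on this axis, so it
    may be smaller than the rater's total volume.  ``pir`` is the rater's
    interpretive-rate vector counts / n_axis, or None when the rater has no
    scored case on the axis (``degenerate`` is then set).
    """

    rater_id: str
    axis: str
    counts: tuple[int, int, int]
    n_axis: int = field(init=False)
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if any(c < 0 for c in self.counts) or len(self.counts) != 3:
            raise ValueError("counts must be 3 non-negative integers")
        self.counts = tuple(int(c) for c in self.counts)
        self.n_axis = sum(self.counts)
        self.degenerate = self.n_axis == 0

    @property
    def pir(self) -> tuple[float, float, float] | None:
        if self.degenerate:
            return None
        n = self.n_axis
        return tuple(c / n for c in self.counts)


@dataclass
class CohortSummary:
    """Cohort-level tallies and the eligible-rater filter result."""

    total_cases: int
    cases_with_grade: int
    grade_counts: tuple[int, int, int]
    eligible_rater_ids: frozenset[str]
    eligible_case_total: int


@dataclass
class ValidationReport:
    """Row-level bookkeeping from CSV parsing, serialisable as JSON."""

    n_rows: int = 0
    n_records: int = 0
    invalid_scores: dict[str, int] = field(default_factory=dict)
    dropped_rows: int = 0
    grade_component_mismatches: int = 0
    messages: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "rows_read": self.n_rows,
                "records_created": self.n_records,
                "rows_dropped": self.dropped_rows,
                "invalid_score_cells": self.invalid_scores,
                "grade_component_mismatches": self.grade_component_mismatches,
                "messages": self.messages,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _parse_score(value: object) -> tuple[int | None, bool]:
    """Parse one score cell. Returns (score or None, was_invalid)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None, False
    s = str(value).strip()
    if s == "" or s.lower() in {"na", "nan", "none"}:
        return None, False
    try:
        iv = int(float(s))
    except ValueError:
        return None, True
    if iv in SCORE_LEVELS and float(s) == iv:
        return iv, False
    return None, True


def read_cases(
    path: str | Path,
    schema_map: Mapping[str, str] | None = None,
) -> list[CaseRecord]:
    """Read case records from a CSV file.

    ``schema_map`` maps logical field names (``case_id``, ``rater_id``,
    ``TS``, ``NS``, ``MS``, ``G``, ``t_stage``) to the file's column names;
    unmapped fields fall back to the defaults.  Unparseable or out-of-range
    score cells become absent scores and are counted in the validation
    report, never silently coerced.
    """
    records, _ = read_cases_with_report(path, schema_map)
    return records


def read_cases_with_report(
    path: str | Path,
    schema_map: Mapping[str, str] | None = None,
) -> tuple[list[CaseRecord], ValidationReport]:
    """As :func:`read_cases` but also return the :class:`ValidationReport`."""
    schema = dict(DEFAULT_SCHEMA)
    if schema_map:
        unknown = set(schema_map) - set(schema)
        if unknown:
            raise ValueError(f"schema_map has unknown fields: {sorted(unknown)}")
        schema.update(schema_map)

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    report = ValidationReport(n_rows=len(df))

    rater_col = schema["rater_id"]
    if rater_col not in df.columns:
        raise ValueError(
            f"required rater column {rater_col!r} not found in {path} "
            f"(columns: {list(df.columns)})"
        )
    axis_cols = {ax: schema[ax] for ax in AXES if schema[ax] in df.columns}
    if not axis_cols:
        raise ValueError(
            f"no score column found in {path}; expected at least one of "
            f"{[schema[ax] for ax in AXES]}"
        )

    records: list[CaseRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        rater = str(row_d.get(rater_col, "")).strip()
        if not rater:
            report.dropped_rows += 1
            report.messages.append(f"row {i}: empty rater id, dropped")
            continue
        scores: dict[str, int | None] = {}
        for ax, col in axis_cols.items():
            val, bad = _parse_score(row_d.get(col))
            if bad:
                report.invalid_scores[col] = report.invalid_scores.get(col, 0) + 1
                logger.warning(
                    "row %d: %s=%r outside {1,2,3}; treated as absent",
                    i, col, row_d.get(col),
                )
            scores[ax] = val
        case_id = str(row_d.get(schema["case_id"], "")).strip() or f"row{i}"
        t_stage_raw = str(row_d.get(schema["t_stage"], "")).strip()
        rec = CaseRecord(
            case_id=case_id,
            rater_id=rater,
            ts=scores.get("TS"),
            ns=scores.get("NS"),
            ms=scores.get("MS"),
            grade=scores.get("G"),
            t_stage=t_stage_raw or None,
        )
        if (
            rec.grade is not None
            and None not in (rec.ts, rec.ns, rec.ms)
            and grade_from_components(rec.ts, rec.ns, rec.ms) != rec.grade
        ):
            # reported grade is kept; mismatch only logged
            report.grade_component_mismatches += 1
        records.append(rec)
    report.n_records = len(records)
    return records, report


def write_cases(cases: Iterable[CaseRecord], path: str | Path) -> None:
    """Write case records to CSV in the default schema (round-trips with
    :func:`read_cases`)."""
    rows = [
        {
            "case_id": c.case_id,
            "pathologist": c.rater_id,
            "tubular_score": c.ts if c.ts is not None else "",
            "nuclear_score": c.ns if c.ns is not None else "",
            "mitotic_score": c.ms if c.ms is not None else "",
            "grade": c.grade if c.grade is not None else "",
            "t_stage": c.t_stage or "",
        }
        for c in cases
    ]
    pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA.values())).to_csv(
        path, index=False
    )


def grade_from_components(
    ts: int | None, ns: int | None, ms: int | None
) -> int | None:
    """Nottingham grade from its component scores (Elston–Ellis cut-offs).

    Sum 3–5 → grade 1, 6–7 → grade 2, 8–9 → grade 3.  Returns None if any
    component is absent.  Used as a consistency check on input data; the
    reported grade is always analysed as reported.
    """
    if ts is None or ns is None or ms is None:
        return None
    for name, v in (("ts", ts), ("ns", ns), ("ms", ms)):
        if v not in SCORE_LEVELS:
            raise ValueError(f"{name}={v!r} outside {{1,2,3}}")
    total = ts + ns + ms
    if total <= 5:
        return 1
    if total <= 7:
        return 2
    return 3


def summarize_cohort(
    cases: Sequence[CaseRecord], min_cases: int = 35
) -> CohortSummary:
    """Cohort tallies plus the strict volume-eligibility filter.

    A rater is eligible when their total case count (any axis, scored or
    not) strictly exceeds ``min_cases``; the default reproduces the
    ">35 cases" rule.  Per-axis denominators of eligible raters may still
    be smaller than ``min_cases`` because of absent scores.
    """
    if min_cases < 0:
        raise ValueError("min_cases must be >= 0")
    volume: dict[str, int] = {}
    grade_counts = [0, 0, 0]
    for c in cases:
        volume[c.rater_id] = volume.get(c.rater_id, 0) + 1
        if c.grade is not None:
            grade_counts[c.grade - 1] += 1
    eligible = frozenset(r for r, n in volume.items() if n > min_cases)
    return CohortSummary(
        total_cases=len(cases),
        cases_with_grade=sum(grade_counts),
        grade_counts=tuple(grade_counts),
        eligible_rater_ids=eligible,
        eligible_case_total=sum(volume[r] for r in eligible),
    )


def profile_raters(
    cases: Sequence[CaseRecord],
    axis: str,
    rater_ids: Iterable[str] | None = None,
) -> list[RaterProfile]:
    """Aggregate cases into per-rater score counts on one axis.

    Cases with an absent score on ``axis`` are excluded from that axis's
    denominator only.  If ``rater_ids`` is given, exactly one profile per
    requested rater is returned (possibly degenerate with ``n_axis=0``);
    otherwise one per rater observed in ``cases``.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")
    counts: dict[str, list[int]] = {}
    if rater_ids is not None:
        for r in rater_ids:
            counts[r] = [0, 0, 0]
    for c in cases:
        if rater_ids is not None and c.rater_id not in counts:
            continue
        s = c.score(axis)
        bucket = counts.setdefault(c.rater_id, [0, 0, 0])
        if s is not None:
            bucket[s - 1] += 1
    profiles = [
        RaterProfile(rater_id=r, axis=axis, counts=tuple(counts[r]))
        for r in sorted(counts)
    ]
    for p in profiles:
        if p.degenerate:
            logger.warning(
                "rater %s has no scored case on axis %s; PIR undefined",
                p.rater_id, axis,
            )
    return profiles


def profiles_from_counts(
    counts, axis: str, rater_ids: Sequence[str] | None = None
) -> list[RaterProfile]:
    """Build profiles directly from an (R, 3) count matrix (one row per
    rater), bypassing case records; the aggregate-level twin of
    :func:`profile_raters`."""
    import numpy as np

    mat = np.asarray(counts, dtype=int)
    if mat.ndim != 2 or mat.shape[1] != 3:
        raise ValueError("counts must have shape (n_raters, 3)")
    if rater_ids is None:
        rater_ids = [f"P{i + 1:02d}" for i in range(mat.shape[0])]
    if len(rater_ids) != mat.shape[0]:
        raise ValueError("rater_ids length must match counts rows")
    return [
        RaterProfile(rater_id=r, axis=axis, counts=tuple(row))
        for r, row in zip(rater_ids, mat)
    ]
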