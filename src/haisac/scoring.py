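"""Deterministic scoring of HAI-SAC item responses and companion scale summaries.

The HAI-SAC battery combines three objective subtests — confrontational naming
of objects, colors and details (CNOCD), memory for photo locations (ML) and
recall of object functions (RFO) — with two informant questions on cognitive
decline (CD) and its functional impact (FD).  Negative informant reports score
points, so higher totals always mean better cognition.  This module also
implements the CASI short-term-memory and language composites, the NPI
sum-of-boxes and the Lawton IADL independence count, which the validation
pipeline consumes as comparator scales.

All scoring here is pure: no rounding, no randomness, no state.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WatchTimeGrade",
    "ItemResponseRecord",
    "ComponentScores",
    "score_cnocd",
    "score_ml",
    "score_rfo",
    "score_informant",
    "score_haisac",
    "casi_short_term_memory",
    "casi_language",
    "npi_sum_of_boxes",
    "iadl_sum",
    "score_items_frame",
]

#: Objects shown to the participant, in their fixed presentation order.
STIMULUS_OBJECTS = ("umbrella", "glasses", "mobile_phone", "key", "watch", "kettle")

#: Component maxima (used for validation and by the simulator's bounded mode).
COMPONENT_MAXIMA = {
    "cnocd": 16,
    "ml": 12,
    "rfo": 12,
    "haisac3": 40,
    "cd": 8,
    "fd": 12,
    "haisaci": 20,
    "haisac_total": 60,
}


class WatchTimeGrade(Enum):
    """Grade of the watch-reading detail question.

    FULL — fully correct time (4 points); HOUR_MIN — correct hour and minute
    but wrong second (2 points); MIN_ONLY — correct minute only (1 point);
    NONE — no credit.
    """

    FULL = "full"
    HOUR_MIN = "hour_min"
    MIN_ONLY = "min_only"
    NONE = "none"


_WATCH_POINTS = {
    WatchTimeGrade.FULL: 4,
    WatchTimeGrade.HOUR_MIN: 2,
    WatchTimeGrade.MIN_ONLY: 1,
    WatchTimeGrade.NONE: 0,
}


@dataclass(frozen=True)
class ItemResponseRecord:
    """One subject's raw HAI-SAC responses.

    ``naming_correct`` / ``color_correct`` hold one boolean per stimulus
    object; ``ml_correct_count`` counts correctly placed photos (0–6);
    ``rfo_correct_count`` counts correctly recalled functions (0–12, two per
    object).  The informant booleans are *negative* reports: ``cd_no_decline``
    is True when the informant reports no cognitive decline.
    """

    subject_id: str
    naming_correct: tuple[bool, ...]
    color_correct: tuple[bool, ...]
    watch_time: WatchTimeGrade
    ml_correct_count: int
    rfo_correct_count: int
    cd_no_decline: bool
    fd_no_interference: bool

    def __post_init__(self) -> None:
        if len(self.naming_correct) != 6 or len(self.color_correct) != 6:
            raise ValueError("naming_correct and color_correct need exactly 6 entries")
        if not 0 <= self.ml_correct_count <= 6:
            raise ValueError(f"ml_correct_count {self.ml_correct_count} outside [0, 6]")
        if not 0 <= self.rfo_correct_count <= 12:
            raise ValueError(f"rfo_correct_count {self.rfo_correct_count} outside [0, 12]")


@dataclass(frozen=True)
class ComponentScores:
    """Scored HAI-SAC components for one subject."""

    cnocd: int
    ml: int
    rfo: int
    haisac3: int
    cd: int
    fd: int
    haisaci: int
    total: int

    def __post_init__(self) -> None:
        if self.haisac3 != self.cnocd + self.ml + self.rfo:
            raise ValueError("haisac3 must equal cnocd + ml + rfo")
        if self.haisaci != self.cd + self.fd:
            raise ValueError("haisaci must equal cd + fd")
        if self.total != self.haisac3 + self.haisaci:
            raise ValueError("total must equal haisac3 + haisaci")
        bounds = dict(COMPONENT_MAXIMA)
        bounds["total"] = bounds.pop("haisac_total")
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0 <= v <= bounds[f.name]:
                raise ValueError(f"{f.name}={v} outside [0, {bounds[f.name]}]")


def _check_six(name: str, flags: Sequence[bool]) -> np.ndarray:
    arr = np.asarray(flags, dtype=bool)
    if arr.shape != (6,):
        raise ValueError(f"{name} must contain exactly 6 booleans, got shape {arr.shape}")
    return arr


def score_cnocd(
    naming_correct: Sequence[bool],
    color_correct: Sequence[bool],
    watch_time: WatchTimeGrade,
) -> int:
    """Score confrontational naming of objects, colors and details (0–16).

    One point per correctly named object and per correct color; the watch
    detail contributes 4 / 2 / 1 / 0 points by :class:`WatchTimeGrade`.
    """
    naming = _check_six("naming_correct", naming_correct)
    color = _check_six("color_correct", color_correct)
    return int(naming.sum() + color.sum() + _WATCH_POINTS[WatchTimeGrade(watch_time)])


def score_ml(ml_correct_count: int) -> int:
    """Score memory for location (0–12).

    Two points per correctly placed photo with the per-photo base capped at
    10; a perfect six-of-six arrangement earns a 2-point bonus, restoring the
    printed 12-point maximum.  Algebraically this is ``2 * count`` over the
    whole range, but the cap-plus-bonus reading is kept explicit because it is
    the instrument's stated rule.
    """
    count = int(ml_correct_count)
    if not 0 <= count <= 6:
        raise ValueError(f"ml_correct_count {count} outside [0, 6]")
    base = min(2 * count, 10)
    bonus = 2 if count == 6 else 0
    return base + bonus


def score_rfo(rfo_correct_count: int) -> int:
    """Score recall of object functions: one point per function (0–12)."""
    count = int(rfo_correct_count)
    if not 0 <= count <= 12:
        raise ValueError(f"rfo_correct_count {count} outside [0, 12]")
    return count


def score_informant(cd_no_decline: bool, fd_no_interference: bool) -> tuple[int, int, int]:
    """Score the informant questions: (cd, fd, haisaci).

    A negative report of cognitive decline scores 8 points; a negative report
    of functional interference scores 12 points.
    """
    cd = 8 if cd_no_decline else 0
    fd = 12 if fd_no_interference else 0
    return cd, fd, cd + fd


def score_haisac(record: ItemResponseRecord) -> ComponentScores:
    """Score a full item-response record into its component scores."""
    cnocd = score_cnocd(record.naming_correct, record.color_correct, record.watch_time)
    ml = score_ml(record.ml_correct_count)
    rfo = score_rfo(record.rfo_correct_count)
    cd, fd, haisaci = score_informant(record.cd_no_decline, record.fd_no_interference)
    haisac3 = cnocd + ml + rfo
    return ComponentScores(
        cnocd=cnocd, ml=ml, rfo=rfo, haisac3=haisac3,
        cd=cd, fd=fd, haisaci=haisaci, total=haisac3 + haisaci,
    )


def _check_range(name: str, value: float, lo: float, hi: float) -> float:
    value = float(value)
    if not lo <= value <= hi:
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
    return value


def casi_short_term_memory(short_delayed: float, long_delayed: float, recognition: float) -> float:
    """CASI short-term-memory composite (0–12).

    ``0.5 * (short delayed recall + long delayed recall) + 0.6 * recognition``
    with recall trials scored 0–9 and recognition 0–5.  Kept as an exact
    decimal; no rounding.
    """
    s = _check_range("short_delayed", short_delayed, 0, 9)
    l = _check_range("long_delayed", long_delayed, 0, 9)
    r = _check_range("recognition", recognition, 0, 5)
    return 0.5 * (s + l) + 0.6 * r


def casi_language(reading: float, writing: float, naming: float, commands: float) -> float:
    """CASI language composite (0–10).

    ``0.5 * (reading + writing) + 0.3 * naming + commands`` with reading 0–3,
    writing 0–5, confrontational naming 0–10 and commands 0–3.
    """
    rd = _check_range("reading", reading, 0, 3)
    wr = _check_range("writing", writing, 0, 5)
    nm = _check_range("naming", naming, 0, 10)
    cm = _check_range("commands", commands, 0, 3)
    return 0.5 * (rd + wr) + 0.3 * nm + cm


def npi_sum_of_boxes(
    per_item_frequency: Sequence[int], per_item_severity: Sequence[int]
) -> int:
    """NPI sum of boxes: Σ frequency × severity over the 12 symptom domains.

    Frequency is rated 0–4, severity 0–3, giving the 144-point maximum.  The
    caregiver-distress rating is not part of this summary score.
    """
    freq = np.asarray(per_item_frequency, dtype=int)
    sev = np.asarray(per_item_severity, dtype=int)
    if freq.shape != (12,) or sev.shape != (12,):
        raise ValueError("frequency and severity must each have exactly 12 items")
    if freq.min() < 0 or freq.max() > 4:
        raise ValueError("frequency ratings must lie in [0, 4]")
    if sev.min() < 0 or sev.max() > 3:
        raise ValueError("severity ratings must lie in [0, 3]")
    return int((freq * sev).sum())


def iadl_sum(independent_flags: Sequence[bool]) -> int:
    """Lawton IADL summary: count of the 8 activities performed independently."""
    flags = np.asarray(independent_flags, dtype=bool)
    if flags.shape != (8,):
        raise ValueError("independent_flags must contain exactly 8 booleans")
    return int(flags.sum())


# ---------------------------------------------------------------------------
# Tabular (CSV-level) interface

ITEM_CSV_COLUMNS = (
    ["subject_id"]
    + [f"name_{i}" for i in range(1, 7)]
    + [f"color_{i}" for i in range(1, 7)]
    + ["watch_grade", "ml_correct", "rfo_correct", "cd_no_decline", "fd_no_interference"]
)

SCORE_COLUMNS = ["cnocd", "ml", "rfo", "haisac3", "cd", "fd", "haisaci", "haisac_total"]


def _record_from_row(row: pd.Series) -> ItemResponseRecord:
    return ItemResponseRecord(
        subject_id=str(row["subject_id"]),
        naming_correct=tuple(bool(row[f"name_{i}"]) for i in range(1, 7)),
        color_correct=tuple(bool(row[f"color_{i}"]) for i in range(1, 7)),
        watch_time=WatchTimeGrade(str(row["watch_grade"])),
        ml_correct_count=int(row["ml_correct"]),
        rfo_correct_count=int(row["rfo_correct"]),
        cd_no_decline=bool(row["cd_no_decline"]),
        fd_no_interference=bool(row["fd_no_interference"]),
    )


def score_items_frame(items: pd.DataFrame) -> pd.DataFrame:
    """Score an item-level table, appending the component-score columns.

    ``items`` must follow the item CSV schema (:data:`ITEM_CSV_COLUMNS`).
    Returns a copy with the eight score columns appended; row order and count
    are preserved.  Raises ``ValueError`` naming offending columns or rows.
    """
    missing = [c for c in ITEM_CSV_COLUMNS if c not in items.columns]
    if missing:
        raise ValueError(f"item table is missing columns: {missing}")
    out = items.copy()
    scored_rows: list[ComponentScores] = []
    errors: list[str] = []
    for idx, row in items.iterrows():
        try:
            scored_rows.append(score_haisac(_record_from_row(row)))
        except (ValueError, KeyError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValueError("invalid item responses: " + "; ".join(errors))
    for col, attr in zip(SCORE_COLUMNS, ["cnocd", "ml", "rfo", "haisac3", "cd", "fd", "haisaci", "total"]):
        out[col] = [getattr(s, attr) for s in scored_rows]
    return out
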