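"""Coded capture histories and breeding records: types, validation, file I/O.

An individual's history is one coded event per annual occasion, from its
birth year to the end of the study:

====  =========================
code  meaning
====  =========================
0     not observed
1     juvenile (J)
2     subadult (SA)
3     adult non-breeder (NB)
4     adult breeder (B)
5     recovered dead (D)
====  =========================

Histories are stored dense (one slot per calendar year); an individual's age
at occasion ``y`` is ``y - birth_year`` (age 0 at birth).  Every animal is
first encountered as a juvenile in its birth year, so the first event is
always code 1, and nothing can be observed after a dead recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_CODES",
    "EVENT_LABELS",
    "CaptureHistory",
    "CaptureHistorySet",
    "BreedingRecord",
    "ParseError",
    "ValidationError",
    "Violation",
    "ValidationReport",
    "SetSummary",
    "read_capture_histories",
    "write_capture_histories",
    "read_breeding_records",
    "write_breeding_records",
    "validate_set",
    "summarize_set",
]

EVENT_CODES = (0, 1, 2, 3, 4, 5)
EVENT_LABELS = {0: "0", 1: "J", 2: "SA", 3: "NB", 4: "B", 5: "D"}


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


class ValidationError(ValueError):
    """A history violates a structural invariant."""


@dataclass(frozen=True)
class CaptureHistory:
    """One individual's birth year plus coded annual events."""

    individual_id: str
    birth_year: int
    events: tuple[int, ...]

    @property
    def years(self) -> range:
        return range(self.birth_year, self.birth_year + len(self.events))

    @property
    def last_year(self) -> int:
        return self.birth_year + len(self.events) - 1

    def age_at(self, year: int) -> int:
        return year - self.birth_year

    def violations(self) -> list["Violation"]:
        """All invariant violations for this single history."""
        out: list[Violation] = []
        ev = self.events

        def bad(occ_idx: int, msg: str) -> None:
            out.append(Violation(self.individual_id, self.birth_year + occ_idx, msg))

        if len(ev) == 0:
            out.append(Violation(self.individual_id, self.birth_year, "empty history"))
            return out
        for i, e in enumerate(ev):
            if e not in EVENT_CODES:
                bad(i, f"unknown event code {e!r}")
        if any(e not in EVENT_CODES for e in ev):
            return out
        if ev[0] != 1:
            bad(0, "first event must be code 1 (juvenile at birth)")
        dead = [i for i, e in enumerate(ev) if e == 5]
        if len(dead) > 1:
            bad(dead[1], "more than one dead recovery")
        if dead:
            for i in range(dead[0] + 1, len(ev)):
                if ev[i] != 0:
                    bad(i, "event after dead recovery")
        first_j = ev.index(1) if 1 in ev else None
        first_adult = next((i for i, e in enumerate(ev) if e in (2, 3, 4)), None)
        if first_adult is not None and (first_j is None or first_adult < first_j):
            bad(first_adult, "adult/subadult code precedes first juvenile code")
        return out


@dataclass
class CaptureHistorySet:
    """A collection of histories sharing one occasion range (calendar years)."""

    histories: list[CaptureHistory]
    occasion_range: tuple[int, int]

    def __len__(self) -> int:
        return len(self.histories)

    def __iter__(self):
        return iter(self.histories)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CaptureHistorySet)
            and self.occasion_range == other.occasion_range
            and self.histories == other.histories
        )

    @property
    def years(self) -> range:
        return range(self.occasion_range[0], self.occasion_range[1] + 1)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: id, birth_year, one event column per occasion year.

        Pre-birth cells are NA (the occasion does not exist for that animal).
        """
        first, last = self.occasion_range
        years = list(range(first, last + 1))
        rows = []
        for h in self.histories:
            row: dict = {"id": h.individual_id, "birth_year": h.birth_year}
            for y in years:
                row[str(y)] = h.events[y - h.birth_year] if y >= h.birth_year else pd.NA
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BreedingRecord:
    """Per-season reproductive output for one breeding (code 4) year."""

    individual_id: str
    season_year: int
    n_clutches: int
    n_eggs: int

    def violations(self) -> list[str]:
        out = []
        if self.n_clutches < 0 or self.n_eggs < 0:
            out.append("negative clutch or egg count")
        if self.n_clutches > 0 and self.n_eggs < self.n_clutches:
            out.append("fewer eggs than clutches")
        return out


@dataclass(frozen=True)
class Violation:
    individual_id: str
    occasion_year: int | None
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "valid (no violations)"
        lines = [
            f"{v.individual_id} @ {v.occasion_year}: {v.message}"
            for v in self.violations
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class SetSummary:
    n_individuals: int
    mean_recaptures: float
    sd_recaptures: float
    n_dead_recoveries: int


def validate_set(history_set: CaptureHistorySet) -> ValidationReport:
    """Report every invariant violation; an empty report means a valid set."""
    report = ValidationReport()
    seen: set[str] = set()
    first, last = history_set.occasion_range
    for h in history_set.histories:
        if h.individual_id in seen:
            report.violations.append(
                Violation(h.individual_id, None, "duplicate individual id")
            )
        seen.add(h.individual_id)
        if h.birth_year < first or h.last_year != last:
            report.violations.append(
                Violation(
                    h.individual_id,
                    None,
                    f"history span {h.birth_year}-{h.last_year} outside "
                    f"occasion range {first}-{last}",
                )
            )
        report.violations.extend(h.violations())
    return report


def _require_valid(history_set: CaptureHistorySet) -> None:
    report = validate_set(history_set)
    if not report.ok:
        v = report.violations[0]
        raise ValidationError(
            f"invalid capture-history set ({len(report.violations)} violations); "
            f"first: {v.individual_id} @ {v.occasion_year}: {v.message}"
        )


def summarize_set(history_set: CaptureHistorySet) -> SetSummary:
    """Recaptures per individual (non-zero events after the first) and dead recoveries."""
    if len(history_set) == 0:
        raise ValueError("cannot summarize an empty capture-history set")
    recaps = np.array(
        [sum(1 for e in h.events[1:] if e != 0) for h in history_set], dtype=float
    )
    dead = sum(1 for h in history_set for e in h.events if e == 5)
    sd = float(np.std(recaps, ddof=1)) if len(recaps) > 1 else float("nan")
    return SetSummary(len(history_set), float(np.mean(recaps)), sd, dead)


# ---------------------------------------------------------------------------
# File I/O.  CSV is canonical: columns id,birth_year,<year1>,<year2>,...
# The INP-like dialect mirrors MARK/E-SURGE digit strings, one record per
# line: `id birth_year <digitstring>;` where the digit string runs from the
# animal's birth year to the shared study end.
# ---------------------------------------------------------------------------


def read_capture_histories(path, dialect: str = "csv") -> CaptureHistorySet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        out = _read_csv(path)
    elif dialect == "inp":
        out = _read_inp(path)
    else:
        raise ValueError(f"unsupported dialect {dialect!r} (use 'csv' or 'inp')")
    _require_valid(out)
    return out


def _read_csv(path: Path) -> CaptureHistorySet:
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns or "birth_year" not in df.columns:
        raise ParseError(f"{path}: header must contain 'id' and 'birth_year'")
    year_cols = [c for c in df.columns if c not in ("id", "birth_year")]
    try:
        years = [int(c) for c in year_cols]
    except ValueError as exc:
        raise ParseError(f"{path}: non-year column in header: {exc}") from None
    if years != sorted(years):
        raise ParseError(f"{path}: year columns must be ascending")
    histories = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            birth = int(row["birth_year"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}:{line_no}: bad birth_year {row['birth_year']!r}")
        events = []
        for y, c in zip(years, year_cols):
            cell = row[c]
            if y < birth:
                if not pd.isna(cell):
                    raise ParseError(
                        f"{path}:{line_no}: event recorded before birth year ({y})"
                    )
                continue
            if pd.isna(cell):
                raise ParseError(f"{path}:{line_no}: missing event for year {y}")
            try:
                events.append(int(cell))
            except (TypeError, ValueError):
                raise ParseError(f"{path}:{line_no}: bad event code {cell!r}")
        histories.append(CaptureHistory(str(row["id"]), birth, tuple(events)))
    if not histories:
        raise ParseError(f"{path}: no histories")
    return CaptureHistorySet(histories, (min(years), max(years)))


def _read_inp(path: Path) -> CaptureHistorySet:
    histories = []
    last_years = set()
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("/*"):
            continue
        if not line.endswith(";"):
            raise ParseError(f"{path}:{line_no}: record must end with ';'")
        parts = line[:-1].split()
        if len(parts) != 3:
            raise ParseError(
                f"{path}:{line_no}: expected 'id birth_year digitstring;'"
            )
        ind, birth_s, digits = parts
        try:
            birth = int(birth_s)
        except ValueError:
            raise ParseError(f"{path}:{line_no}: bad birth year {birth_s!r}")
        if not digits.isdigit():
            raise ParseError(f"{path}:{line_no}: non-digit event string {digits!r}")
        events = tuple(int(d) for d in digits)
        histories.append(CaptureHistory(ind, birth, events))
        last_years.add(birth + len(events) - 1)
    if not histories:
        raise ParseError(f"{path}: no histories")
    if len(last_years) != 1:
        raise ParseError(f"{path}: histories do not share a common final year")
    first = min(h.birth_year for h in histories)
    return CaptureHistorySet(histories, (first, last_years.pop()))


def write_capture_histories(path, history_set: CaptureHistorySet, dialect: str = "csv") -> None:
    path = Path(path)
    if dialect == "csv":
        history_set.to_frame().to_csv(path, index=False)
    elif dialect == "inp":
        with open(path, "w") as fh:
            for h in history_set.histories:
                fh.write(
                    f"{h.individual_id} {h.birth_year} "
                    f"{''.join(str(e) for e in h.events)};\n"
                )
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")


def read_breeding_records(path) -> list[BreedingRecord]:
    df = pd.read_csv(path, dtype={"id": str})
    needed = {"id", "season_year", "n_clutches", "n_eggs"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: header must contain {sorted(needed)}")
    records = []
    for i, row in df.iterrows():
        rec = BreedingRecord(
            str(row["id"]), int(row["season_year"]),
            int(row["n_clutches"]), int(row["n_eggs"]),
        )
        problems = rec.violations()
        if problems:
            raise ValidationError(
                f"{path}:{i + 2}: {rec.individual_id} @ {rec.season_year}: "
                + "; ".join(problems)
            )
        records.append(rec)
    return records


def write_breeding_records(path, records: Iterable[BreedingRecord]) -> None:
    pd.DataFrame(
        [
            {
                "id": r.individual_id,
                "season_year": r.season_year,
                "n_clutches": r.n_clutches,
                "n_eggs": r.n_eggs,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
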