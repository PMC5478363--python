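"""Domain types, CSV I/O and validation for quartet dominance data.

The study design this package serves puts sibling groups of four birds
("quartets", one per natal family) into a cage and records two behavioural
streams per family:

* **displacement events** — directed contests at a food bowl in which one
  bird (the displacer) causes another (the displaced) to move away; and
* **perch scans** — instantaneous orderings of the birds present on the
  highest (sloping) perch, sampled at fixed intervals from video.

Each bird carries its developmental-treatment metadata: a 2x2 factorial of
food *Amount* (Plenty/Lean) and begging *Effort* (Easy/Hard) applied as a
nestling, plus sex, biometrics and standardized developmental telomere
change (``delta_tl``, more negative = greater attrition; may be missing).

One family may contain a treatment-matched *substitute* bird drafted in
from another family to keep group size at four.  Its interactions count
towards the scores of its three hosts but never towards its own
(:func:`focal_event_sets`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Bird",
    "DisplacementEvent",
    "ScanSample",
    "Sociomatrix",
    "ValidationError",
    "read_birds",
    "write_birds",
    "read_displacements",
    "write_displacements",
    "read_scans",
    "write_scans",
    "sort_events",
    "build_sociomatrix",
    "focal_event_sets",
]

SEX_LEVELS = ("F", "M")
AMOUNT_LEVELS = ("Plenty", "Lean")
EFFORT_LEVELS = ("Easy", "Hard")
VALID_WEEKS = (1, 2, 3)


class ValidationError(ValueError):
    """Raised when an input table violates the data contract.

    The message names the offending row (1-based, excluding the header)
    and field wherever possible.
    """


@dataclass(frozen=True)
class Bird:
    """One subject with its family, treatments and biometrics."""

    id: str
    family: str
    sex: str
    amount: str
    effort: str
    tarsus: float | None = None
    weight: float | None = None
    delta_tl: float | None = None
    is_substitute: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEX_LEVELS:
            raise ValidationError(f"bird {self.id!r}: sex must be one of {SEX_LEVELS}, got {self.sex!r}")
        if self.amount not in AMOUNT_LEVELS:
            raise ValidationError(f"bird {self.id!r}: amount must be one of {AMOUNT_LEVELS}, got {self.amount!r}")
        if self.effort not in EFFORT_LEVELS:
            raise ValidationError(f"bird {self.id!r}: effort must be one of {EFFORT_LEVELS}, got {self.effort!r}")
        if self.tarsus is not None and not self.tarsus > 0:
            raise ValidationError(f"bird {self.id!r}: tarsus must be > 0, got {self.tarsus}")
        if self.weight is not None and not self.weight > 0:
            raise ValidationError(f"bird {self.id!r}: weight must be > 0, got {self.weight}")


@dataclass(frozen=True)
class DisplacementEvent:
    """One directed displacer -> displaced contest outcome.

    ``video_order`` is the event's position within its day's video; the
    triple (week, day, video_order) gives the total time ordering used by
    sequential algorithms.  No clock timestamps are recorded.
    """

    family: str
    week: int
    day: int
    video_order: int
    displacer: str
    displaced: str

    def __post_init__(self) -> None:
        if self.displacer == self.displaced:
            raise ValidationError(
                f"event ({self.family}, w{self.week}, d{self.day}, #{self.video_order}):"
                f" displacer equals displaced ({self.displacer!r})"
            )
        if self.week not in VALID_WEEKS:
            raise ValidationError(
                f"event ({self.family}, d{self.day}, #{self.video_order}): week must be in"
                f" {VALID_WEEKS}, got {self.week} (habituation week 0 yields no analysis data)"
            )

    @property
    def order_key(self) -> tuple[int, int, int]:
        return (self.week, self.day, self.video_order)


@dataclass(frozen=True)
class ScanSample:
    """One instantaneous ordering of birds on the sloping perch.

    ``occupants`` lists bird ids highest-first; an empty list is a valid
    scan with no bird on the perch.
    """

    family: str
    week: int
    day: int
    scan_index: int
    occupants: tuple[str, ...]

    def __post_init__(self) -> None:
        occ = tuple(self.occupants)
        object.__setattr__(self, "occupants", occ)
        if len(set(occ)) != len(occ):
            raise ValidationError(
                f"scan ({self.family}, w{self.week}, d{self.day}, #{self.scan_index}):"
                f" duplicate occupant in {occ}"
            )
        if len(occ) > 4:
            raise ValidationError(
                f"scan ({self.family}, w{self.week}, d{self.day}, #{self.scan_index}):"
                f" more than 4 occupants"
            )
        if self.week not in VALID_WEEKS:
            raise ValidationError(
                f"scan ({self.family}, d{self.day}, #{self.scan_index}): week must be in"
                f" {VALID_WEEKS}, got {self.week}"
            )


@dataclass
class Sociomatrix:
    """Within-family square matrix of displacement counts.

    ``counts[i, j]`` is the number of times ``ids[i]`` displaced
    ``ids[j]`` (rows win, columns lose).
    """

    family: str
    ids: tuple[str, ...]
    counts: np.ndarray
    week_filter: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.ids)
        if self.counts.shape != (n, n):
            raise ValidationError(f"sociomatrix {self.family}: counts shape {self.counts.shape} != ({n}, {n})")
        if (self.counts < 0).any():
            raise ValidationError(f"sociomatrix {self.family}: negative count")
        if np.diagonal(self.counts).any():
            raise ValidationError(f"sociomatrix {self.family}: nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.ids), columns=list(self.ids))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_BIRD_COLUMNS = ["id", "family", "sex", "amount", "effort", "tarsus", "weight", "delta_tl", "is_substitute"]
_EVENT_COLUMNS = ["family", "week", "day", "video_order", "displacer", "displaced"]
_SCAN_COLUMNS = ["family", "week", "day", "scan_index", "occupants"]


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing required column(s) {missing}")
    return df


def _as_float(value: str, row: int, fieldname: str) -> float | None:
    if value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise ValidationError(f"row {row}: field {fieldname!r}: not a number: {value!r}") from None


def _as_int(value: str, row: int, fieldname: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"row {row}: field {fieldname!r}: not an integer: {value!r}") from None


def read_birds(path: str | Path) -> list[Bird]:
    """Read a bird roster CSV.

    Expected columns: id, family, sex, amount, effort, tarsus, weight,
    delta_tl, is_substitute.  A missing ``delta_tl`` is encoded as an
    empty cell.  Raises :class:`ValidationError` naming the row and field
    for unknown enum levels, duplicate ids, or malformed numbers.
    """
    df = _read_table(path, _BIRD_COLUMNS)
    birds: list[Bird] = []
    seen: set[str] = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        if rec["id"] in seen:
            raise ValidationError(f"row {i}: field 'id': duplicate bird id {rec['id']!r}")
        seen.add(rec["id"])
        sub = rec["is_substitute"].strip().lower()
        if sub not in {"true", "false", "1", "0", ""}:
            raise ValidationError(f"row {i}: field 'is_substitute': expected boolean, got {rec['is_substitute']!r}")
        try:
            birds.append(
                Bird(
                    id=rec["id"],
                    family=rec["family"],
                    sex=rec["sex"],
                    amount=rec["amount"],
                    effort=rec["effort"],
                    tarsus=_as_float(rec["tarsus"], i, "tarsus"),
                    weight=_as_float(rec["weight"], i, "weight"),
                    delta_tl=_as_float(rec["delta_tl"], i, "delta_tl"),
                    is_substitute=sub in {"true", "1"},
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
    return birds


def write_birds(birds: Iterable[Bird], path: str | Path) -> None:
    rows = []
    for b in birds:
        rows.append(
            {
                "id": b.id,
                "family": b.family,
                "sex": b.sex,
                "amount": b.amount,
                "effort": b.effort,
                "tarsus": "" if b.tarsus is None else repr(b.tarsus),
                "weight": "" if b.weight is None else repr(b.weight),
                "delta_tl": "" if b.delta_tl is None else repr(b.delta_tl),
                "is_substitute": str(b.is_substitute).lower(),
            }
        )
    pd.DataFrame(rows, columns=_BIRD_COLUMNS).to_csv(path, index=False)


def read_displacements(path: str | Path) -> list[DisplacementEvent]:
    """Read displacement events; enforces unique (family, week, day, video_order)."""
    df = _read_table(path, _EVENT_COLUMNS)
    events: list[DisplacementEvent] = []
    seen: set[tuple] = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            ev = DisplacementEvent(
                family=rec["family"],
                week=_as_int(rec["week"], i, "week"),
                day=_as_int(rec["day"], i, "day"),
                video_order=_as_int(rec["video_order"], i, "video_order"),
                displacer=rec["displacer"],
                displaced=rec["displaced"],
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
        key = (ev.family, ev.week, ev.day, ev.video_order)
        if key in seen:
            raise ValidationError(f"row {i}: duplicate event key {key}")
        seen.add(key)
        events.append(ev)
    return events


def write_displacements(events: Iterable[DisplacementEvent], path: str | Path) -> None:
    rows = [
        {
            "family": e.family,
            "week": e.week,
            "day": e.day,
            "video_order": e.video_order,
            "displacer": e.displacer,
            "displaced": e.displaced,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def read_scans(path: str | Path) -> list[ScanSample]:
    """Read perch scans; ``occupants`` is a semicolon-joined highest-first list."""
    df = _read_table(path, _SCAN_COLUMNS)
    scans: list[ScanSample] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        occ = tuple(x for x in rec["occupants"].split(";") if x)
        try:
            scans.append(
                ScanSample(
                    family=rec["family"],
                    week=_as_int(rec["week"], i, "week"),
                    day=_as_int(rec["day"], i, "day"),
                    scan_index=_as_int(rec["scan_index"], i, "scan_index"),
                    occupants=occ,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
    return scans


def write_scans(scans: Iterable[ScanSample], path: str | Path) -> None:
    rows = [
        {
            "family": s.family,
            "week": s.week,
            "day": s.day,
            "scan_index": s.scan_index,
            "occupants": ";".join(s.occupants),
        }
        for s in scans
    ]
    pd.DataFrame(rows, columns=_SCAN_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Analysis-set construction
# ---------------------------------------------------------------------------


def sort_events(events: Iterable[DisplacementEvent]) -> list[DisplacementEvent]:
    """Sort events into their canonical (week, day, video_order) sequence."""
    return sorted(events, key=lambda e: (e.family, e.week, e.day, e.video_order))


def _family_index(birds: Sequence[Bird]) -> dict[str, list[Bird]]:
    out: dict[str, list[Bird]] = {}
    for b in birds:
        out.setdefault(b.family, []).append(b)
    return out


def build_sociomatrix(
    events: Sequence[DisplacementEvent],
    birds: Sequence[Bird],
    weeks: Iterable[int] | None = None,
) -> Sociomatrix:
    """Count displacements into a square win matrix for one family.

    ``counts[i, j]`` is the number of events where ``ids[i]`` displaced
    ``ids[j]``, restricted to the given week subset when ``weeks`` is not
    None.  All events must come from a single family and both ids of
    every counted event must resolve to the roster.
    """
    families = {e.family for e in events} | {b.family for b in birds}
    if len({b.family for b in birds}) != 1:
        raise ValidationError(f"build_sociomatrix expects birds from one family, got {sorted({b.family for b in birds})}")
    if len(families) > 1:
        raise ValidationError(f"events span multiple families: {sorted(families)}")
    family = birds[0].family
    ids = tuple(b.id for b in birds)
    pos = {bid: k for k, bid in enumerate(ids)}
    week_set = None if weeks is None else frozenset(weeks)
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for e in events:
        if week_set is not None and e.week not in week_set:
            continue
        if e.displacer not in pos or e.displaced not in pos:
            raise ValidationError(
                f"event ({e.family}, w{e.week}, d{e.day}, #{e.video_order}) references"
                f" unknown bird: {e.displacer!r} or {e.displaced!r}"
            )
        counts[pos[e.displacer], pos[e.displaced]] += 1
    return Sociomatrix(
        family=family,
        ids=ids,
        counts=counts,
        week_filter=None if week_set is None else tuple(sorted(week_set)),
    )


def focal_event_sets(
    events: Sequence[DisplacementEvent],
    birds: Sequence[Bird],
) -> dict[str, list[DisplacementEvent]]:
    """Per-focal-bird event sets implementing the substitute-bird rule.

    A substitute bird's interactions in its host family are informative
    about the hosts but not about the substitute itself (it is re-running
    the experiment outside its own family).  Hence: a non-substitute
    focal bird keeps the full family event list, substitute events
    included; a substitute focal bird's set excludes every event it
    participates in.  At most one substitute per family is allowed.
    """
    out: dict[str, list[DisplacementEvent]] = {}
    for family, members in _family_index(birds).items():
        subs = [b for b in members if b.is_substitute]
        if len(subs) > 1:
            raise ValidationError(f"family {family!r} has {len(subs)} substitute birds; at most one allowed")
        fam_events = [e for e in events if e.family == family]
        sub_id = subs[0].id if subs else None
        for b in members:
            if b.id == sub_id:
                out[b.id] = [e for e in fam_events if sub_id not in (e.displacer, e.displaced)]
            else:
                out[b.id] = list(fam_events)
    return out
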