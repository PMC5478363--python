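"""Relative perch-position scores from scan samples.

Birds on the sloping perch are scan-sampled at fixed intervals; each
scan records the occupants ordered highest-first.  The occupant at
position ``p`` (1 = highest) of a scan with ``k`` birds present scores

    ``1 - p / k``,

so the top bird always gets the scan's highest score and the bottom bird
0.  Scans with fewer than two occupants are discarded as uninformative
about *relative* position.  Scores are then averaged in two stages —
scans within a video, then videos within a week (or across all weeks for
the overall score) — so that videos contribute equally regardless of how
many usable scans they produced.

A complementary continuous measure, seconds spent as the highest-placed
bird of several, can be aggregated with :func:`highest_occupancy_time`
or derived from the scans themselves via :func:`highest_time_from_scans`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import Bird, ScanSample, ValidationError

__all__ = [
    "PerchScore",
    "score_scan",
    "average_perch_position",
    "highest_occupancy_time",
    "highest_time_from_scans",
]


@dataclass(frozen=True)
class PerchScore:
    """Mean relative perch position for one bird within one scope."""

    bird: str
    scope: str
    score: float
    n_scans: int


def score_scan(scan: ScanSample) -> dict[str, float]:
    """Score one scan: occupant at position p of k gets ``1 - p/k``.

    Returns an empty mapping for scans with fewer than two occupants
    (discarded: a lone bird's position carries no relative information).
    """
    k = len(scan.occupants)
    if k < 2:
        return {}
    return {bid: 1.0 - (p + 1) / k for p, bid in enumerate(scan.occupants)}


def average_perch_position(
    scans: Sequence[ScanSample],
    birds: Sequence[Bird],
    weeks: Iterable[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Two-stage mean perch-position score per bird, weekly and overall.

    Stage 1: mean of a bird's scan scores within each video, where a
    video is one (family, week, day).  Stage 2: unweighted mean of video
    means within each week; the overall score is the unweighted mean of
    video means across all weeks (not a mean of weekly means).  A bird
    absent from every scored scan of a video contributes no video mean;
    a bird absent from every video in a scope gets NaN with n_scans 0.

    Substitute birds follow the same focal rule as dominance: their
    presence shapes their hosts' scores, but their own score within the
    host family is not reported (NaN).
    """
    weeks = tuple(weeks)
    fam_of = {b.id: b.family for b in birds}
    subs = {b.id for b in birds if b.is_substitute}

    # per-(bird, video) mean scan score and contributing-scan count
    records: list[dict] = []
    for s in scans:
        for bid, val in score_scan(s).items():
            if bid not in fam_of:
                raise ValidationError(f"scan occupant {bid!r} not on roster")
            records.append({"bird": bid, "week": s.week, "day": s.day, "score": val})
    per_scan = pd.DataFrame(records, columns=["bird", "week", "day", "score"])

    rows: list[dict] = []
    scopes: list[tuple[str, tuple[int, ...]]] = [(f"week{w}", (w,)) for w in weeks]
    scopes.append(("overall", weeks))
    if not per_scan.empty:
        video_means = (
            per_scan.groupby(["bird", "week", "day"])["score"]
            .agg(["mean", "size"])
            .reset_index()
        )
    else:
        video_means = pd.DataFrame(columns=["bird", "week", "day", "mean", "size"])
    for b in birds:
        mine = video_means[video_means["bird"] == b.id]
        for scope, wk in scopes:
            sub = mine[mine["week"].isin(wk)]
            if b.id in subs or sub.empty:
                rows.append({"bird": b.id, "scope": scope,
                             "score": np.nan, "n_scans": 0 if b.id in subs else int(sub["size"].sum())})
            else:
                rows.append({"bird": b.id, "scope": scope,
                             "score": float(sub["mean"].mean()), "n_scans": int(sub["size"].sum())})
    return pd.DataFrame(rows, columns=["bird", "scope", "score", "n_scans"])


def highest_occupancy_time(records: Iterable[tuple[str, int, float]]) -> pd.DataFrame:
    """Total per-bird, per-week seconds spent as the highest bird of several.

    ``records`` are (bird, week, seconds) measurements from continuous
    sampling; durations must be nonnegative.  Returns a tidy frame with
    columns bird, week, seconds summed over records.
    """
    rows = []
    for bid, week, seconds in records:
        if seconds < 0:
            raise ValidationError(f"bird {bid!r}, week {week}: negative duration {seconds}")
        rows.append({"bird": bid, "week": int(week), "seconds": float(seconds)})
    if not rows:
        return pd.DataFrame(columns=["bird", "week", "seconds"])
    return (
        pd.DataFrame(rows)
        .groupby(["bird", "week"], as_index=False)["seconds"]
        .sum()
        .sort_values(["bird", "week"], ignore_index=True)
    )


def highest_time_from_scans(scans: Sequence[ScanSample], interval_s: float = 30.0) -> pd.DataFrame:
    """Approximate highest-bird occupancy time from the scan record.

    Each scan with >= 2 occupants credits its top bird with one sampling
    interval (default 30 s).  Returns (bird, week, seconds) totals in the
    same shape as :func:`highest_occupancy_time`.
    """
    recs = [(s.occupants[0], s.week, float(interval_s)) for s in scans if len(s.occupants) >= 2]
    return highest_occupancy_time(recs)
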