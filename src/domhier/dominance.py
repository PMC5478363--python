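"""David's scores, sequential Elo-ratings and hierarchy stability.

Two complementary dominance indices are computed from the same stream of
displacement events:

* **David's score** (DS) works on the matrix of dyadic win counts.  For
  each dyad the raw win proportion ``P_ij = s_ij / n_ij`` is shrunk
  towards 0.5 in proportion to how little the dyad was observed,

      ``D_ij = P_ij - (P_ij - 0.5) / (n_ij + 1)``,

  so that sparsely observed dyads carry less weight.  A bird's score
  combines direct and indirect success::

      w_i  = sum_j D_ij            (dyadic indices won)
      w2_i = sum_j w_j * D_ij      (wins weighted by opponents' wins)
      l_i  = sum_j D_ji            (dyadic indices lost)
      l2_i = sum_j l_j * D_ji      (losses weighted by opponents' losses)
      DS_i = w_i + w2_i - l_i - l2_i

  DS sums to zero within a group, so it expresses dominance relative to
  the group mean.

* **Elo-rating** consumes the raw event sequence.  Everyone starts at
  the same rating (1000); at each contest the winner takes
  ``k * (1 - E_w)`` points from the loser, where ``E_w`` is the winner's
  expected success given the pre-contest rating gap.  Updates are
  zero-sum, so the family total stays at ``n * 1000`` forever.

A day-to-day **stability statistic** summarises how much the Elo-implied
rank order reshuffles between consecutive observation days: 0 means the
order never changes, 0.5 means it reverses completely every day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import Bird, DisplacementEvent, Sociomatrix, ValidationError, build_sociomatrix, focal_event_sets

__all__ = [
    "DavidsResult",
    "EloTrajectory",
    "StabilityResult",
    "dyadic_index",
    "dyadic_index_matrix",
    "davids_scores",
    "davids_weekly_and_overall",
    "elo_sequence",
    "daily_final_ratings",
    "stability_statistic",
    "elo_stability",
]

ELO_START = 1000.0
ELO_K = 100.0


@dataclass(frozen=True)
class DavidsResult:
    """David's score decomposition for one bird within one scope."""

    bird: str
    w: float
    w2: float
    l: float
    l2: float
    ds: float
    scope: str = "overall"


@dataclass
class EloTrajectory:
    """Elo rating time series for one bird.

    ``series`` holds (event index within the family sequence, rating
    after that event) pairs, recorded only at events the bird took part
    in.  ``final`` is the rating after the last family event.
    """

    bird: str
    start: float
    k: float
    series: list[tuple[int, float]]
    final: float


@dataclass(frozen=True)
class StabilityResult:
    """Rank-order stability of a family's hierarchy; S in [0, 0.5]."""

    family: str
    s: float | None
    n_days: int


# ---------------------------------------------------------------------------
# David's score
# ---------------------------------------------------------------------------


def dyadic_index(s_ij: int | float, s_ji: int | float) -> float:
    """Dyadic dominance index ``D_ij`` corrected for observation effort.

    ``D_ij = P_ij - (P_ij - 0.5) / (n_ij + 1)`` with ``P_ij = s_ij/n_ij``
    and ``n_ij = s_ij + s_ji``.  Antisymmetric: ``D_ij + D_ji = 1``
    whenever the dyad interacted.  An unobserved dyad (``n_ij = 0``) is
    uninformative and returns 0.5 for both directions, with a warning.
    """
    if s_ij < 0 or s_ji < 0:
        raise ValueError("win counts must be nonnegative")
    n_ij = s_ij + s_ji
    if n_ij == 0:
        warnings.warn("dyad never interacted; dyadic index set to uninformative 0.5", stacklevel=2)
        return 0.5
    p_ij = s_ij / n_ij
    return p_ij - (p_ij - 0.5) / (n_ij + 1)


def dyadic_index_matrix(counts: np.ndarray) -> np.ndarray:
    """Matrix of D_ij for all dyads; unobserved dyads get 0.5 both ways.

    The diagonal is set to 0 (a bird has no dyad with itself).
    """
    counts = np.asarray(counts, dtype=float)
    n_mat = counts + counts.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_mat > 0, counts / np.where(n_mat > 0, n_mat, 1.0), 0.5)
    d = p - (p - 0.5) / (n_mat + 1.0)
    d = np.where(n_mat > 0, d, 0.5)
    np.fill_diagonal(d, 0.0)
    return d


def davids_scores(m: Sociomatrix, scope: str = "overall") -> list[DavidsResult]:
    """David's scores for every bird in a family sociomatrix.

    Requires at least two birds.  Zero-interaction dyads contribute the
    uninformative index 0.5 in both directions (warned once per matrix);
    the returned scores always sum to zero.
    """
    if m.n < 2:
        raise ValidationError(f"David's score needs >= 2 birds, got {m.n}")
    off_diag = ~np.eye(m.n, dtype=bool)
    n_mat = (m.counts + m.counts.T)[off_diag]
    if (n_mat == 0).any():
        warnings.warn(
            f"family {m.family}: {int((n_mat == 0).sum()) // 2} dyad(s) never interacted;"
            " their dyadic indices are set to the uninformative 0.5",
            stacklevel=2,
        )
    d = dyadic_index_matrix(m.counts)
    w = d.sum(axis=1)
    l = d.sum(axis=0)
    w2 = d @ w
    l2 = d.T @ l
    ds = w + w2 - l - l2
    return [
        DavidsResult(bird=m.ids[i], w=float(w[i]), w2=float(w2[i]), l=float(l[i]), l2=float(l2[i]),
                     ds=float(ds[i]), scope=scope)
        for i in range(m.n)
    ]


def davids_weekly_and_overall(
    events: Sequence[DisplacementEvent],
    birds: Sequence[Bird],
    weeks: Iterable[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Per-bird David's scores for each week and for all data pooled.

    The substitute-bird rule is applied first: every focal bird's score
    is computed from its own focal event set (see
    :func:`domhier.data_model.focal_event_sets`), so a substitute's score
    within its host family is undefined (NaN) while its hosts' scores
    include the substitute's interactions.

    Returns a tidy frame with columns bird, scope, w, w2, l, l2, ds,
    where scope is ``week1`` ... or ``overall``.
    """
    weeks = tuple(weeks)
    focal_sets = focal_event_sets(events, birds)
    by_family: dict[str, list[Bird]] = {}
    for b in birds:
        by_family.setdefault(b.family, []).append(b)

    rows: list[dict] = []
    scopes: list[tuple[str, Iterable[int] | None]] = [(f"week{w}", (w,)) for w in weeks]
    scopes.append(("overall", None))
    for family, members in by_family.items():
        subs = {b.id for b in members if b.is_substitute}
        hosts = [b for b in members if not b.is_substitute]
        host_events = focal_sets[hosts[0].id] if hosts else []
        for scope, wk in scopes:
            if hosts:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = build_sociomatrix(host_events, members, weeks=wk)
                    results = {r.bird: r for r in davids_scores(m, scope=scope)}
            else:
                results = {}
            for b in members:
                if b.id in subs:
                    rows.append({"bird": b.id, "scope": scope, "w": np.nan, "w2": np.nan,
                                 "l": np.nan, "l2": np.nan, "ds": np.nan})
                else:
                    r = results[b.id]
                    rows.append({"bird": r.bird, "scope": r.scope, "w": r.w, "w2": r.w2,
                                 "l": r.l, "l2": r.l2, "ds": r.ds})
    return pd.DataFrame(rows, columns=["bird", "scope", "w", "w2", "l", "l2", "ds"])


# ---------------------------------------------------------------------------
# Elo-rating
# ---------------------------------------------------------------------------


def _expected_success(d: float, expectation: str) -> float:
    """Winner's expected success probability at pre-contest rating gap d."""
    if expectation == "normal":
        return float(norm.cdf(d / (200.0 * np.sqrt(2.0))))
    if expectation == "logistic":
        return 1.0 / (1.0 + 10.0 ** (-d / 400.0))
    raise ValueError(f"expectation must be 'normal' or 'logistic', got {expectation!r}")


def elo_sequence(
    events: Sequence[DisplacementEvent],
    ids: Sequence[str],
    start: float = ELO_START,
    k: float = ELO_K,
    expectation: str = "normal",
) -> dict[str, EloTrajectory]:
    """Run sequential Elo-rating over one family's event stream.

    Events must already be in (week, day, video_order) order.  The
    winner (displacer) gains ``k * (1 - E_w)`` and the loser drops by
    the same amount; with the default normal expectation
    ``E_w = Phi((r_w - r_l) / (200 * sqrt(2)))``.
    """
    keys = [e.order_key for e in events]
    if any(b <= a for a, b in zip(keys, keys[1:])):
        raise ValidationError("events are not sorted by (week, day, video_order)")
    known = set(ids)
    ratings = {bid: float(start) for bid in ids}
    series: dict[str, list[tuple[int, float]]] = {bid: [] for bid in ids}
    for idx, e in enumerate(events):
        if e.displacer not in known or e.displaced not in known:
            raise ValidationError(f"event references unknown bird: {e.displacer!r} or {e.displaced!r}")
        d = ratings[e.displacer] - ratings[e.displaced]
        delta = k * (1.0 - _expected_success(d, expectation))
        ratings[e.displacer] += delta
        ratings[e.displaced] -= delta
        series[e.displacer].append((idx, ratings[e.displacer]))
        series[e.displaced].append((idx, ratings[e.displaced]))
    return {
        bid: EloTrajectory(bird=bid, start=float(start), k=float(k), series=series[bid], final=ratings[bid])
        for bid in ids
    }


def daily_final_ratings(
    events: Sequence[DisplacementEvent],
    ids: Sequence[str],
    start: float = ELO_START,
    k: float = ELO_K,
    expectation: str = "normal",
) -> pd.DataFrame:
    """End-of-day Elo rating snapshots, one row per interaction day.

    Index is (week, day); columns are bird ids.  Only days with at least
    one event appear.
    """
    keys = [e.order_key for e in events]
    if any(b <= a for a, b in zip(keys, keys[1:])):
        raise ValidationError("events are not sorted by (week, day, video_order)")
    ratings = {bid: float(start) for bid in ids}
    snapshots: dict[tuple[int, int], dict[str, float]] = {}
    for e in events:
        d = ratings[e.displacer] - ratings[e.displaced]
        delta = k * (1.0 - _expected_success(d, expectation))
        ratings[e.displacer] += delta
        ratings[e.displaced] -= delta
        snapshots[(e.week, e.day)] = dict(ratings)
    if not snapshots:
        return pd.DataFrame(columns=list(ids))
    df = pd.DataFrame.from_dict(snapshots, orient="index")[list(ids)]
    df.index = pd.MultiIndex.from_tuples(df.index, names=["week", "day"])
    return df.sort_index()


# ---------------------------------------------------------------------------
# Stability statistic
# ---------------------------------------------------------------------------


def _dense_ranks(row: np.ndarray) -> np.ndarray:
    """Dense ranks, 1 = highest rating; exact ties share the better rank."""
    order = np.argsort(-row, kind="stable")
    ranks = np.empty(len(row), dtype=float)
    rank = 0
    prev = None
    for pos in order:
        if prev is None or row[pos] != prev:
            rank += 1
            prev = row[pos]
        ranks[pos] = rank
    return ranks


def stability_statistic(daily_ratings: pd.DataFrame, family: str = "") -> StabilityResult:
    """Day-to-day stability of the Elo rank order, scaled to [0, 0.5].

    For each consecutive pair of interaction days, rank changes are
    weighted by the changing individuals' ratings standardized to [0, 1]
    within the later day (rank changes high in the hierarchy count more
    than churn at the bottom).  Each day-pair's weighted change is
    normalized by the weighted change a complete rank reversal would
    have produced under the same weights, and the mean over day pairs is
    halved, so S = 0 when the order never changes and S = 0.5 under
    complete reversal every day.

    With a single interaction day stability is undefined: returns
    ``s=None`` with a warning.
    """
    n_days = len(daily_ratings)
    if n_days < 2:
        warnings.warn(f"family {family or '?'}: fewer than 2 interaction days; stability undefined", stacklevel=2)
        return StabilityResult(family=family, s=None, n_days=n_days)
    values = daily_ratings.to_numpy(dtype=float)
    n = values.shape[1]
    pair_scores: list[float] = []
    for t in range(1, n_days):
        r_prev = _dense_ranks(values[t - 1])
        r_curr = _dense_ranks(values[t])
        span = values[t].max() - values[t].min()
        if span > 0:
            weight = (values[t] - values[t].min()) / span
        else:
            weight = np.full(n, 0.5)
        changed = np.abs(r_curr - r_prev)
        observed = float((weight * changed).sum())
        # complete reversal of the current order: rank i -> n + 1 - i
        reversal = np.abs((n + 1 - r_curr) - r_curr)
        max_possible = float((weight * reversal).sum())
        pair_scores.append(observed / max_possible if max_possible > 0 else 0.0)
    s = 0.5 * float(np.mean(pair_scores))
    return StabilityResult(family=family, s=s, n_days=n_days)


def elo_stability(
    events: Sequence[DisplacementEvent],
    ids: Sequence[str],
    family: str = "",
    start: float = ELO_START,
    k: float = ELO_K,
    expectation: str = "normal",
) -> StabilityResult:
    """Convenience wrapper: run Elo, snapshot day ends, compute stability."""
    daily = daily_final_ratings(events, ids, start=start, k=k, expectation=expectation)
    return stability_statistic(daily, family=family)
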