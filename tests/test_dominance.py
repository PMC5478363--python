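import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from domhier.data_model import DisplacementEvent, Sociomatrix, ValidationError
from domhier.dominance import (
    daily_final_ratings,
    davids_scores,
    davids_weekly_and_overall,
    dyadic_index,
    elo_sequence,
    elo_stability,
    stability_statistic,
)
from domhier.synthetic_data import SimulationConfig, generate_cohort, generate_displacements


def brute_force_davids(counts):
    """Independent loop-level oracle for David's scores."""
    n = len(counts)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            nij = counts[i][j] + counts[j][i]
            if nij == 0:
                D[i, j] = 0.5
            else:
                p = counts[i][j] / nij
                D[i, j] = p - (p - 0.5) / (nij + 1)
    ds = []
    for i in range(n):
        w = sum(D[i, j] for j in range(n) if j != i)
        l = sum(D[j, i] for j in range(n) if j != i)
        w2 = sum(sum(D[j, k] for k in range(n) if k != j) * D[i, j] for j in range(n) if j != i)
        l2 = sum(sum(D[k, j] for k in range(n) if k != j) * D[j, i] for j in range(n) if j != i)
        ds.append(w + w2 - l - l2)
    return ds


count_matrices = st.integers(min_value=2, max_value=5).flatmap(
    lambda n: st.lists(
        st.lists(st.integers(min_value=0, max_value=20), min_size=n, max_size=n),
        min_size=n,
        max_size=n,
    ).map(lambda rows: np.array(rows) * (1 - np.eye(n, dtype=int)))
)


class TestDyadicIndex:
    def test_two_zero_dyad(self):
        # P = 1, shrunk by 0.5/(n+1): 1 - 0.5/3
        assert dyadic_index(2, 0) == pytest.approx(1 - 0.5 / 3)

    def test_balanced_dyad_is_half(self):
        assert dyadic_index(5, 5) == pytest.approx(0.5)

    def test_unobserved_dyad_uninformative_with_warning(self):
        with pytest.warns(UserWarning, match="never interacted"):
            assert dyadic_index(0, 0) == 0.5

    @given(st.integers(0, 50), st.integers(0, 50))
    def test_antisymmetry(self, s_ij, s_ji):
        if s_ij + s_ji == 0:
            return
        assert dyadic_index(s_ij, s_ji) + dyadic_index(s_ji, s_ij) == pytest.approx(1.0)
        assert 0.0 <= dyadic_index(s_ij, s_ji) <= 1.0


class TestDavidsScores:
    def test_linear_triad_oracle(self):
        m = Sociomatrix("f1", ("A", "B", "C"), np.array([[0, 2, 2], [0, 0, 2], [0, 0, 0]]))
        ds = {r.bird: r.ds for r in davids_scores(m)}
        assert ds == pytest.approx({"A": 2.0, "B": 0.0, "C": -2.0})

    def test_symmetric_matrix_all_zero(self):
        counts = np.array([[0, 3, 1], [3, 0, 2], [1, 2, 0]])
        assert all(r.ds == pytest.approx(0.0) for r in davids_scores(Sociomatrix("f1", "XYZ", counts)))

    def test_single_bird_rejected(self):
        with pytest.raises(ValidationError, match=">= 2"):
            davids_scores(Sociomatrix("f1", ("A",), np.zeros((1, 1), dtype=int)))

    @given(count_matrices)
    def test_zero_sum_and_matches_brute_force(self, counts):
        m = Sociomatrix("f1", tuple(f"b{i}" for i in range(len(counts))), counts)
        results = davids_scores(m)
        assert sum(r.ds for r in results) == pytest.approx(0.0, abs=1e-9)
        expected = brute_force_davids(counts)
        for r, exp in zip(results, expected):
            assert r.ds == pytest.approx(exp)
            assert r.ds == pytest.approx(r.w + r.w2 - r.l - r.l2)


class TestElo:
    def test_first_event_from_equal_ratings(self, make_events):
        for expectation in ("normal", "logistic"):
            traj = elo_sequence(make_events([("A", "B")]), ["A", "B"], expectation=expectation)
            assert traj["A"].final == pytest.approx(1050.0)
            assert traj["B"].final == pytest.approx(950.0)

    def test_second_event_normal_expectation_oracle(self, make_events):
        # after A beats B once: 1050 vs 950; E_w = Phi(100 / (200 sqrt 2))
        traj = elo_sequence(make_events([("A", "B"), ("A", "B")]), ["A", "B"])
        e_w = norm.cdf(100 / (200 * np.sqrt(2)))
        assert e_w == pytest.approx(0.6382, abs=1e-4)
        assert traj["A"].final == pytest.approx(1050 + 100 * (1 - e_w))
        assert traj["A"].final == pytest.approx(1086.2, abs=0.05)
        assert traj["B"].final == pytest.approx(913.8, abs=0.05)

    def test_ratings_update_only_on_own_events(self, make_events):
        traj = elo_sequence(make_events([("A", "B"), ("A", "B")]), ["A", "B", "C"])
        assert traj["C"].series == [] and traj["C"].final == 1000.0

    def test_unsorted_events_rejected(self, make_events):
        events = make_events([("A", "B")], week=2) + make_events([("B", "A")], week=1)
        with pytest.raises(ValidationError, match="not sorted"):
            elo_sequence(events, ["A", "B"])

    def test_unknown_id_rejected(self, make_events):
        with pytest.raises(ValidationError, match="unknown bird"):
            elo_sequence(make_events([("A", "Z")]), ["A", "B"])

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)).filter(lambda p: p[0] != p[1]),
                    min_size=1, max_size=40))
    def test_constant_family_total(self, pairs):
        ids = ["b0", "b1", "b2", "b3"]
        events = [
            DisplacementEvent(family="f1", week=1, day=1, video_order=i + 1,
                              displacer=f"b{a}", displaced=f"b{b}")
            for i, (a, b) in enumerate(pairs)
        ]
        for expectation in ("normal", "logistic"):
            traj = elo_sequence(events, ids, expectation=expectation)
            assert sum(t.final for t in traj.values()) == pytest.approx(4000.0)


class TestStability:
    def test_frozen_ranks_give_zero(self):
        daily = pd.DataFrame([[1200, 1050, 950, 800]] * 5, columns=list("ABCD"))
        assert stability_statistic(daily).s == pytest.approx(0.0)

    def test_daily_complete_reversal_gives_half(self):
        up = [1300, 1100, 900, 700]
        daily = pd.DataFrame([up, up[::-1], up, up[::-1]], columns=list("ABCD"))
        assert stability_statistic(daily).s == pytest.approx(0.5)

    def test_single_day_undefined(self):
        daily = pd.DataFrame([[1100, 900]], columns=list("AB"))
        with pytest.warns(UserWarning, match="stability undefined"):
            assert stability_statistic(daily).s is None

    def test_bounds_on_random_walks(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            daily = pd.DataFrame(1000 + rng.normal(0, 80, size=(6, 4)).cumsum(axis=0))
            s = stability_statistic(daily).s
            assert 0.0 <= s <= 0.5

    def test_stable_quartet_low_stability(self):
        # strongly separated latent hierarchy, >= 50 contests per day
        cfg = SimulationConfig(seed=5, beta_sex_dom=0.0, sd_dom=0.0, events_per_hour=55.0)
        cohort = generate_cohort(cfg)
        for family, ids in cohort.family_ids().items():
            for rank, bid in enumerate(ids):
                cohort.dominance_ability[bid] = 2.0 * (3 - rank)
        events = generate_displacements(cohort, cfg)
        for family, ids in cohort.family_ids().items():
            fam_events = [e for e in events if e.family == family]
            res = elo_stability(fam_events, ids, family=family)
            assert res.s < 0.15

    def test_daily_ratings_one_row_per_interaction_day(self, make_events):
        events = (
            make_events([("A", "B")], week=1, day=1)
            + make_events([("B", "A")], week=1, day=3)
            + make_events([("A", "B")], week=2, day=1)
        )
        daily = daily_final_ratings(events, ["A", "B"])
        assert list(daily.index) == [(1, 1), (1, 3), (2, 1)]


class TestWeeklyAndOverall:
    def test_single_week_weekly_equals_overall(self, quartet, make_events):
        events = make_events([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        table = davids_weekly_and_overall(events, quartet, weeks=(1,))
        wide = table.pivot(index="bird", columns="scope", values="ds")
        assert np.allclose(wide["week1"], wide["overall"])

    def test_substitute_score_undefined_in_host_family(self, substitute_family, make_events):
        events = make_events([("P", "S"), ("S", "Q"), ("P", "Q")], family="f2")
        table = davids_weekly_and_overall(events, substitute_family, weeks=(1,))
        overall = table[table.scope == "overall"].set_index("bird")["ds"]
        assert np.isnan(overall["S"])
        assert overall.drop("S").notna().all()
        # hosts' scores sum to zero among themselves
        assert overall.drop("S").sum() == pytest.approx(0.0, abs=1e-9)

    def test_weekly_scores_track_fixed_hierarchy(self):
        cfg = SimulationConfig(seed=17)
        cohort = generate_cohort(cfg)
        events = generate_displacements(cohort, cfg)
        table = davids_weekly_and_overall(events, cohort.birds)
        wide = table.pivot(index="bird", columns="scope", values="ds")
        for a, b in [("week1", "week2"), ("week1", "week3"), ("week2", "week3")]:
            assert np.corrcoef(wide[a], wide[b])[0, 1] > 0.8
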