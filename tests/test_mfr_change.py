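"""Block MFRs, Kruskal-Wallis, Scheffé post hoc, and the change classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envshift import (
    SpikeTrain,
    block_mfr,
    classify_mfr_change,
    kruskal_wallis,
    posthoc_pairwise,
    summarize_population,
    truncate_triplet,
    validate_triplet,
)
from envshift.core import SessionTriplet
from envshift.mfr_change import PopulationSummary
from envshift.synthetic_data import CellTruth, SimConfig, generate_triplet


def kw_brute_force(groups):
    """Rank-formula oracle: H = 12/(N(N+1)) * sum R_j^2/n_j - 3(N+1)."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    # average ties
    for val in np.unique(pooled):
        sel = pooled == val
        ranks[sel] = ranks[sel].mean()
    N = len(pooled)
    start, H = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (N * (N + 1)) * H - 3 * (N + 1)


class TestBlockMFR:
    def test_metronomic_rate_constant_blocks(self):
        spikes = SpikeTrain(np.arange(0, 765, 0.5), "a")  # 2 Hz
        b = block_mfr(spikes)
        assert np.allclose(b.rates, 2.0)
        assert b.block_duration == pytest.approx(76.5)
        assert len(b) == 10

    def test_blocks_average_to_session_mfr(self, rng):
        times = np.sort(rng.uniform(0, 765, 2000))
        b = block_mfr(SpikeTrain(times, "a"))
        assert b.rates.mean() == pytest.approx(b.session_mfr)

    def test_poisson_counting_oracle(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 765, rng.poisson(3 * 765)))
        b = block_mfr(SpikeTrain(times, "a"))
        brute = [np.sum((times >= i * 76.5) & (times < (i + 1) * 76.5)) / 76.5 for i in range(10)]
        assert np.allclose(b.rates, brute)


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        H, p = kruskal_wallis([np.ones(10)] * 3)
        assert H == 0.0 and p == 1.0

    def test_matches_brute_force_rank_formula(self):
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        H, _ = kruskal_wallis(groups)
        assert H == pytest.approx(7.2)
        assert H == pytest.approx(kw_brute_force(groups))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_oracle_on_random_groups(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 20, size=rng.integers(3, 9)).astype(float) for _ in range(3)]
        if np.all(np.concatenate(groups) == groups[0][0]):
            return
        H, _ = kruskal_wallis(groups)
        # scipy applies the tie correction; the plain rank formula must agree
        # after the same correction factor
        pooled = np.concatenate(groups)
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1 - np.sum(counts**3 - counts) / (len(pooled) ** 3 - len(pooled))
        assert H == pytest.approx(kw_brute_force(groups) / tie)

    def test_null_calibration(self):
        """Rejection rate at alpha=0.05 within [0.04, 0.06] over 10000 nulls."""
        rng = np.random.default_rng(42)
        rej = 0
        n_sim = 10000
        for _ in range(n_sim):
            g = rng.standard_normal((3, 10))
            _, p = kruskal_wallis(list(g))
            rej += p < 0.05
        assert 0.04 <= rej / n_sim <= 0.06


class TestPosthoc:
    def test_identical_groups_maximal_p(self):
        pw = posthoc_pairwise([np.ones(10)] * 3, labels=["a", "b", "c"])
        assert all(p == 1.0 for p in pw.values())

    def test_separated_group_detected(self):
        g1 = np.arange(1.0, 11)
        g2 = np.arange(1.0, 11)
        g3 = np.arange(101.0, 111)
        pw = posthoc_pairwise([g1, g2, g3], labels=["pre", "manip", "post"])
        assert pw[("pre", "manip")] > 0.5
        assert pw[("pre", "post")] < 0.05
        assert pw[("manip", "post")] < 0.05

    def test_familywise_error_controlled(self):
        """Any-pair false rejection over null triplets stays <= alpha."""
        rng = np.random.default_rng(7)
        any_rej = 0
        n_sim = 2000
        for _ in range(n_sim):
            g = rng.standard_normal((3, 10))
            pw = posthoc_pairwise(list(g))
            any_rej += min(pw.values()) < 0.05
        assert any_rej / n_sim <= 0.05


def _triplet_from_rates(rates, seed=0, duration=765.0):
    """Homogeneous-Poisson triplet for one cell with given session rates."""
    from envshift.core import Arena, PositionTrace, Session

    rng = np.random.default_rng(seed)
    n = int(duration * 30)
    t = np.arange(n) / 30.0
    sessions = []
    for cond, rate in zip(("pre", "manipulation", "post"), rates):
        times = np.sort(rng.uniform(0, duration, rng.poisson(rate * duration)))
        trace = PositionTrace(t, np.full(n, 10.0), np.full(n, 10.0))
        sessions.append(
            Session(cond, "object", Arena(), trace, {"c": SpikeTrain(times, "c")}, duration)
        )
    return validate_triplet(*sessions)


class TestClassifier:
    def test_shift_up_and_back_is_increase(self):
        trip = _triplet_from_rates((3.0, 7.0, 3.0), seed=1)
        c = classify_mfr_change(trip, "c")
        assert c.label == "increase" and c.delta > 0

    def test_shift_down_and_back_is_decrease(self):
        trip = _triplet_from_rates((8.0, 3.0, 8.0), seed=2)
        c = classify_mfr_change(trip, "c")
        assert c.label == "decrease" and c.delta < 0

    def test_no_return_to_baseline_is_none(self):
        trip = _triplet_from_rates((3.0, 7.0, 7.0), seed=3)
        assert classify_mfr_change(trip, "c").label == "none"

    def test_null_cell_usually_none(self):
        labels = [
            classify_mfr_change(_triplet_from_rates((3.0, 3.0, 3.0), seed=s), "c").label
            for s in range(40)
        ]
        assert labels.count("none") >= 38

    def test_silent_cell_flagged(self):
        trip = _triplet_from_rates((0.0, 0.0, 0.0), seed=4)
        c = classify_mfr_change(trip, "c")
        assert c.label == "none" and "silent_cell" in c.flags

    def test_session_order_symmetry(self):
        """Swapping pre and post sessions cannot change a label."""
        trip = _triplet_from_rates((3.0, 7.0, 3.5), seed=5)
        swapped = SessionTriplet(
            pre=_swap_condition(trip.post, "pre"),
            manip=trip.manip,
            post=_swap_condition(trip.pre, "post"),
            roster=trip.roster,
        )
        assert classify_mfr_change(trip, "c").label == classify_mfr_change(swapped, "c").label

    def test_time_unit_scale_equivariance(self):
        """Relabelling time units rescales rates monotonically: ranks, H, p
        and the label are unchanged."""
        trip = _triplet_from_rates((3.0, 7.0, 3.0), seed=6)
        base = classify_mfr_change(trip, "c")
        groups = [base.block_rates[k] for k in ("pre", "manip", "post")]
        scaled = [g * 1000.0 for g in groups]
        assert kruskal_wallis(groups) == pytest.approx(kruskal_wallis(scaled))
        pw1 = posthoc_pairwise(groups)
        pw2 = posthoc_pairwise(scaled)
        for k in pw1:
            assert pw1[k] == pytest.approx(pw2[k])


def _swap_condition(session, new_condition):
    from dataclasses import replace

    return replace(session, condition=new_condition)


class TestPopulationSummary:
    def test_printed_percentages_reproduced(self):
        s = PopulationSummary.from_counts(23, 15, 200)
        assert s.pct_significant == 19.0
        assert s.pct_increase_of_significant == 60.5
        assert s.pct_decrease_of_significant == 39.5
        assert s.pct_increase == 11.5
        assert s.pct_decrease == 7.5

    def test_zero_significant(self):
        trip = _triplet_from_rates((3.0, 3.0, 3.0), seed=10)
        cls = [classify_mfr_change(trip, "c")]
        s = summarize_population(cls)
        if s.n_significant == 0:
            assert s.pct_significant == 0.0
            assert s.mean_increase is None and s.mean_decrease is None

    def test_mean_shift_magnitudes_recovered(self, default_triplet):
        triplet, truth = default_triplet
        from envshift import classify_triplet

        s = summarize_population(classify_triplet(triplet))
        assert s.mean_increase == pytest.approx(4.0, abs=0.5)
        assert s.mean_decrease == pytest.approx(5.7, abs=0.5)
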