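"""Speed series, tuning curves, the uniform-vs-linear F-test, shapes."""

import numpy as np
import pytest

from envshift import (
    compute_speed,
    categorize_tuning_shape,
    classify_speed_cell,
    linear_vs_uniform_ftest,
    simulate_cell,
    speed_tuning_curve,
    split_half_curves,
)
from envshift.core import PositionTrace, SpikeTrain
from envshift.speed_tuning import ANALYSIS_EDGES, DISPLAY_EDGES, SpeedTuningCurve
from envshift.synthetic_data import CellTruth, SpeedGain


def line_trace(cm_per_frame, n=300, frame_rate=30.0):
    t = np.arange(n) / frame_rate
    x = np.arange(n) * cm_per_frame
    return PositionTrace(t, x, np.zeros(n))


class TestComputeSpeed:
    def test_stationary_trace_zero_speed(self):
        tr = PositionTrace(np.arange(100) / 30.0, np.full(100, 5.0), np.full(100, 5.0))
        assert np.all(compute_speed(tr).v == 0.0)

    def test_straight_line_constant_speed(self):
        sp = compute_speed(line_trace(1.0), smooth_frames=0)
        assert np.allclose(sp.v, 30.0)

    def test_unsmoothed_matches_finite_difference_oracle(self, rng):
        n = 200
        tr = PositionTrace(np.arange(n) / 30.0, rng.uniform(0, 50, n), rng.uniform(0, 50, n))
        sp = compute_speed(tr, smooth_frames=0)
        oracle = np.hypot(np.diff(tr.x), np.diff(tr.y)) * 30.0
        assert np.allclose(sp.v[1:], oracle)
        assert sp.v[0] == oracle[0]

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            compute_speed(PositionTrace([0.0], [1.0], [1.0]))


class TestTuningCurve:
    def test_constant_speed_rate_definition(self):
        # 4 s all at 10 cm/s; 20 spikes -> 5 spikes/s in the bin holding 10
        tr = line_trace(10.0 / 30.0, n=120)
        spikes = SpikeTrain(np.linspace(0.05, 3.95, 20), "a")
        curve = speed_tuning_curve(spikes, tr, flavor="analysis")
        b = np.digitize(10.0, ANALYSIS_EDGES) - 1
        assert curve.rate[b] == pytest.approx(20.0 / 4.0)
        assert curve.occupancy[b] == pytest.approx(4.0)

    def test_occupancy_weighted_mean_equals_restricted_mfr(self, trajectory):
        truth = CellTruth(base_rate={"pre": 3.0, "manip": 3.0, "post": 3.0})
        st = simulate_cell(truth, trajectory, "pre", seed=21, cell_id="x")
        speed = compute_speed(trajectory)
        curve = speed_tuning_curve(st, trajectory, speed, "analysis")
        ok = curve.defined
        weighted = np.sum(curve.rate[ok] * curve.occupancy[ok]) / np.sum(curve.occupancy[ok])
        # independent tally of spikes/time on frames inside the speed range
        from envshift.core import nearest_sample_index
        from envshift.speed_tuning import _bin_frames

        idx = _bin_frames(speed.v, ANALYSIS_EDGES)
        in_range = idx >= 0
        t_in = in_range.sum() / 30.0
        spk_in = np.sum(in_range[nearest_sample_index(trajectory.t, st.times)])
        assert weighted == pytest.approx(spk_in / t_in)

    def test_out_of_range_session_errors(self):
        tr = PositionTrace(np.arange(100) / 30.0, np.full(100, 5.0), np.full(100, 5.0))
        sp = compute_speed(tr)  # all zeros: outside the 5-55 analysis range
        with pytest.raises(ValueError):
            speed_tuning_curve(SpikeTrain([1.0], "a"), tr, sp, "analysis")

    def test_analysis_flavor_has_25_bins(self):
        assert len(ANALYSIS_EDGES) - 1 == 25
        assert ANALYSIS_EDGES[0] == 5.0 and ANALYSIS_EDGES[-1] == 55.0
        assert np.allclose(np.diff(ANALYSIS_EDGES), 2.0)
        assert DISPLAY_EDGES[0] == 0.0 and DISPLAY_EDGES[-1] == 60.0
        assert np.allclose(np.diff(DISPLAY_EDGES), 2.5)


def curve_from_rates(rates, edges=ANALYSIS_EDGES):
    rates = np.asarray(rates, dtype=float)
    return SpeedTuningCurve(edges, rates, np.ones(len(rates)), "analysis")


class TestFTest:
    def test_exactly_linear_perfect_fit(self):
        centers = 0.5 * (ANALYSIS_EDGES[:-1] + ANALYSIS_EDGES[1:])
        r = linear_vs_uniform_ftest(curve_from_rates(1.0 + 0.1 * centers))
        assert r.perfect_fit and r.p == 0.0

    def test_exactly_constant_no_evidence(self):
        r = linear_vs_uniform_ftest(curve_from_rates(np.full(25, 2.0)))
        assert r.F == 0.0 and r.p == 1.0

    def test_offset_invariance(self, rng):
        y = rng.normal(3.0, 0.5, 25)
        r1 = linear_vs_uniform_ftest(curve_from_rates(y))
        r2 = linear_vs_uniform_ftest(curve_from_rates(y + 100.0))
        assert r1.F == pytest.approx(r2.F) and r1.p == pytest.approx(r2.p)

    def test_too_few_bins_errors(self):
        c = SpeedTuningCurve(ANALYSIS_EDGES[:3], np.array([1.0, 2.0]), np.ones(2), "analysis")
        with pytest.raises(ValueError):
            linear_vs_uniform_ftest(c)

    def test_power_increases_with_gain_slope(self, trajectory):
        """Detection power grows with the simulated speed-gain strength."""
        speed = compute_speed(trajectory)
        rates = []
        for strength in (0.15, 0.4, 1.0):
            rej = 0
            for k in range(40):
                truth = CellTruth(
                    base_rate={"pre": 3.0, "manip": 3.0, "post": 3.0},
                    speed_gain=SpeedGain("increasing", strength=strength),
                )
                st = simulate_cell(truth, trajectory, "pre", seed=3000 + k, cell_id=f"s{strength}{k}")
                curve = speed_tuning_curve(st, trajectory, speed, "analysis")
                rej += linear_vs_uniform_ftest(curve).p < 0.05
            rates.append(rej / 40)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]


class TestShapeAndClassification:
    def test_monotone_increasing_line(self):
        c = curve_from_rates(np.linspace(1, 5, 24), DISPLAY_EDGES)
        assert categorize_tuning_shape(c) == "increasing"

    def test_monotone_decreasing_line(self):
        c = curve_from_rates(np.linspace(5, 1, 24), DISPLAY_EDGES)
        assert categorize_tuning_shape(c) == "decreasing"

    def test_symmetric_bump_preferred(self):
        centers = 0.5 * (DISPLAY_EDGES[:-1] + DISPLAY_EDGES[1:])
        bump = 1 + 3 * np.exp(-0.5 * ((centers - 30) / 8) ** 2)
        assert categorize_tuning_shape(curve_from_rates(bump, DISPLAY_EDGES)) == "preferred"

    def test_noisy_flat_cells_mostly_unclassified(self, default_triplet):
        triplet, truth = default_triplet
        flat = [cid for cid, ct in truth.cells.items() if ct.speed_gain.shape == "flat"]
        cats = [classify_speed_cell(triplet, cid).category for cid in flat]
        assert cats.count("unclassified") / len(cats) > 0.5

    def test_any_session_rule(self, default_triplet):
        """speed_sensitive is exactly 'p < alpha in at least one session'."""
        triplet, _ = default_triplet
        for cid in triplet.roster[:25]:
            sc = classify_speed_cell(triplet, cid)
            assert sc.speed_sensitive == any(r.p < 0.05 for r in sc.per_session.values())

    def test_tuned_population_recovery(self, default_triplet):
        """Detected sensitive fraction within +-7 points of truth plus the
        any-of-three type-I inflation on untuned cells."""
        triplet, truth = default_triplet
        detected = np.mean([classify_speed_cell(triplet, cid).speed_sensitive for cid in triplet.roster])
        frac_tuned = np.mean([ct.speed_tuned for ct in truth.cells.values()])
        expected = frac_tuned + (1 - frac_tuned) * (1 - 0.95**3)
        assert abs(detected - expected) <= 0.07


class TestSplitHalf:
    def test_deterministic_masking_oracle(self, small_triplet):
        from envshift import truncate_triplet
        from envshift.core import nearest_sample_index
        from envshift.speed_tuning import _accumulate, _bin_frames

        triplet, _ = small_triplet
        triplet = truncate_triplet(triplet)
        cid = triplet.roster[0]
        first, second, merged = split_half_curves(triplet, cid)
        # independent oracle: total spike count in range is conserved across halves
        tot = 0.0
        for sess in triplet.sessions:
            sp = compute_speed(sess.trace)
            idx = _bin_frames(sp.v, DISPLAY_EDGES)
            sf = nearest_sample_index(sess.trace.t, sess.spikes[cid].times)
            tot += np.sum(idx[sf] >= 0)
        counted = np.nansum(first.rate * first.occupancy) + np.nansum(second.rate * second.occupancy)
        assert counted == pytest.approx(tot)
        # occupancy halves sum to the merged occupancy
        assert np.allclose(first.occupancy + second.occupancy, merged.occupancy)

    def test_halves_of_identical_data_equal_merged(self):
        c = curve_from_rates(np.linspace(1, 5, 24), DISPLAY_EDGES)
        # merged curve of two identical halves equals either half by construction:
        # pooled counts/occupancy double, the ratio is unchanged
        pooled = SpeedTuningCurve(DISPLAY_EDGES, c.rate, 2 * c.occupancy, "display")
        assert np.allclose(pooled.rate, c.rate)

    def test_time_homogeneous_cells_are_stable(self, default_triplet):
        """Half-curves of tuned, non-drifting cells correlate > 0.8 on average."""
        triplet, truth = default_triplet
        tuned = [cid for cid, ct in truth.cells.items() if ct.speed_tuned][:20]
        cors = []
        for cid in tuned:
            f, s, _ = split_half_curves(triplet, cid)
            ok = np.isfinite(f.rate) & np.isfinite(s.rate)
            cors.append(np.corrcoef(f.rate[ok], s.rate[ok])[0, 1])
        assert np.mean(cors) > 0.8
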