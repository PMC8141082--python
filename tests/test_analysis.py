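import math

import numpy as np
import pytest

import kinktrap as kt


def straight_trace(length=100.0, spacing=1.0, angle=0.0, mid="line"):
    s = np.arange(0.0, length + spacing / 2, spacing)
    pts = np.stack([s * math.cos(angle), s * math.sin(angle)], axis=1)
    return kt.ContourTrace(mid, pts)


class TestMsed:
    def test_straight_trace_chord_equals_arc(self):
        curve = kt.mean_square_end_to_end([straight_trace(100.0)], step=25.0)
        i = np.argmin(np.abs(curve.L_grid - 50.0))
        assert curve.R2[i] == pytest.approx(2500.0, rel=1e-9)

    def test_semicircle_chord_oracle(self):
        r = 100.0 / math.pi  # quarter-arc lands exactly on the 50-nm grid point
        t = np.linspace(0.0, math.pi, 400)
        pts = np.stack([r * np.cos(t), r * np.sin(t)], axis=1)
        curve = kt.mean_square_end_to_end([kt.ContourTrace("arc", pts)], step=25.0)
        i = np.argmin(np.abs(curve.L_grid - 50.0))
        # chord of a circular arc: 2 r sin(s / 2r) with s = pi r / 2
        assert curve.R2[i] == pytest.approx(2 * r ** 2, rel=0.01)

    def test_r2_cannot_exceed_L_squared(self, eq_traces_small):
        curve = kt.mean_square_end_to_end(eq_traces_small[:50])
        assert np.all(curve.R2 <= curve.L_grid ** 2 * (1 + 1e-9))

    def test_rigid_motion_invariance(self, eq_traces_small):
        traces = eq_traces_small[:20]
        base = kt.mean_square_end_to_end(traces)
        ang = 0.77
        R = np.array([[math.cos(ang), -math.sin(ang)],
                      [math.sin(ang), math.cos(ang)]])
        moved = [kt.ContourTrace(t.molecule_id,
                                 (t.points @ R.T) * np.array([1.0, -1.0]) + 13.5)
                 for t in traces]
        other = kt.mean_square_end_to_end(moved)
        assert np.allclose(base.R2, other.R2, rtol=1e-9)

    def test_short_traces_excluded_with_warning(self):
        short = straight_trace(30.0, mid="short")
        ok = straight_trace(200.0, mid="ok")
        with pytest.warns(UserWarning):
            curve = kt.mean_square_end_to_end([short, ok], step=25.0)
        assert curve.metadata["n_molecules"] == 1

    def test_no_usable_traces_raises(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                kt.mean_square_end_to_end([straight_trace(30.0)], step=25.0)


class TestTheoryCurves:
    def test_stiff_limit_quadratic(self):
        # both laws become quadratic in L for a stiff chain; the
        # projected one carries the 2/3 orientational projection factor
        P = 53.0
        L = np.array([0.01 * P])
        eq = kt.wlc_theory_curve(P, "equilibrated2d", L).R2[0]
        pr = kt.wlc_theory_curve(P, "projected", L).R2[0]
        assert eq == pytest.approx(L[0] ** 2, rel=0.01)
        assert pr == pytest.approx(2.0 / 3.0 * L[0] ** 2, rel=0.01)

    def test_flexible_limit_ratio_three(self):
        P = 53.0
        L = np.array([100.0 * P])
        eq = kt.wlc_theory_curve(P, "equilibrated2d", L).R2[0]
        pr = kt.wlc_theory_curve(P, "projected", L).R2[0]
        assert eq / pr == pytest.approx(3.0, rel=0.02)

    def test_equilibrated_dominates_projected(self):
        L = np.arange(25.0, 2000.0, 25.0)
        eq = kt.wlc_theory_curve(53.0, "equilibrated2d", L).R2
        pr = kt.wlc_theory_curve(53.0, "projected", L).R2
        assert np.all(eq >= pr)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            kt.wlc_theory_curve(53.0, "helix", np.array([25.0]))


class TestPersistenceFit:
    def test_self_consistency_exact_curve(self):
        L = np.arange(25.0, 500.0, 25.0)
        th = kt.wlc_theory_curve(40.0, "equilibrated2d", L)
        curve = kt.MsedCurve(L, th.R2, np.full(len(L), 100), np.zeros(len(L)))
        fit = kt.fit_persistence_length(curve, "equilibrated2d")
        assert fit.P_eff == pytest.approx(40.0, abs=1e-3)

    def test_recovery_from_simulated_ensembles(self, eq_traces_small):
        curve = kt.mean_square_end_to_end(eq_traces_small)
        fit = kt.fit_persistence_length(curve, "equilibrated2d", L_max=450.0)
        assert fit.P_eff == pytest.approx(53.0, rel=0.05)
        assert fit.ci[0] < fit.P_eff < fit.ci[1]

    def test_trapped_fitted_as_projected_is_softer(self, trapped_small):
        traces = kt.chains_to_traces(trapped_small)
        curve = kt.mean_square_end_to_end(traces)
        fit = kt.fit_persistence_length(curve, "projected", L_max=225.0)
        assert fit.P_eff < 53.0  # apparent softening from low-scale bending

    def test_too_few_points_rejected(self):
        L = np.arange(25.0, 100.0, 25.0)
        th = kt.wlc_theory_curve(40.0, "equilibrated2d", L)
        curve = kt.MsedCurve(L, th.R2, np.full(len(L), 5), np.zeros(len(L)))
        with pytest.raises(ValueError):
            kt.fit_persistence_length(curve, "equilibrated2d")


class TestClassification:
    def _curve(self, R2, L, se_frac=0.02):
        return kt.MsedCurve(L, R2, np.full(len(L), 50), se_frac * R2)

    def test_exact_equilibrated(self):
        L = np.arange(25.0, 500.0, 25.0)
        th = kt.wlc_theory_curve(53.0, "equilibrated2d", L)
        assert kt.classify_conformation(self._curve(th.R2, L), 53.0) == "equilibrated"

    def test_exact_projected(self):
        L = np.arange(25.0, 500.0, 25.0)
        th = kt.wlc_theory_curve(53.0, "projected", L)
        assert kt.classify_conformation(self._curve(th.R2, L), 53.0) == "close_to_projected"

    def test_compact_below_projected(self):
        L = np.arange(25.0, 500.0, 25.0)
        th = kt.wlc_theory_curve(53.0, "projected", L)
        assert kt.classify_conformation(self._curve(0.7 * th.R2, L), 53.0) == "subprojected"

    def test_too_few_points_unclassified(self):
        L = np.array([25.0, 50.0])
        th = kt.wlc_theory_curve(53.0, "projected", L)
        assert kt.classify_conformation(self._curve(th.R2, L), 53.0) == "unclassified"


class TestKinkDetection:
    def test_right_angle_polyline_single_call(self):
        a = np.stack([np.arange(0.0, 30.0), np.zeros(30)], axis=1)
        b = np.stack([np.full(30, 29.0), np.arange(1.0, 31.0)], axis=1)
        trace = kt.ContourTrace("L", np.vstack([a, b]))
        calls = kt.detect_kinks(trace)
        assert len(calls) == 1
        assert calls[0].angle_deg == pytest.approx(90.0, abs=3.0)

    def test_smooth_arc_above_threshold_radius_is_clean(self):
        r = 10.0
        t = np.arange(0.0, math.pi, 1.0 / r)
        pts = np.stack([r * np.cos(t), r * np.sin(t)], axis=1)
        assert kt.detect_kinks(kt.ContourTrace("arc", pts)) == []

    def test_planted_kinks_recovered(self):
        errs, found, total = [], 0, 0
        for s in range(10):
            base = kt.generate_wlc_2d(53.0, 900.0, 1.0, seed=300 + s)
            planted = kt.plant_kinks(base, 20, seed=400 + s)
            trace = kt.chains_to_traces([planted], seed=s)[0]
            calls = kt.detect_kinks(trace)
            for site, angle, _ in planted.kinks:
                total += 1
                near = [c for c in calls if abs(c.arc_position - site) <= 4.0]
                if near:
                    found += 1
                    best = min(near, key=lambda c: abs(c.arc_position - site))
                    errs.append(best.angle_deg - angle)
        assert found / total >= 0.95
        assert math.sqrt(np.mean(np.square(errs))) <= 10.0

    def test_false_positive_rate_on_smooth_chains(self, eq_traces_small):
        calls = sum(len(kt.detect_kinks(t)) for t in eq_traces_small[:30])
        per_10P = calls / (30 * 900.0 / 53.0 / 10.0)
        assert per_10P <= 1.0

    def test_spacing_guard(self):
        pts = np.stack([np.arange(0.0, 100.0, 3.0), np.zeros(34)], axis=1)
        with pytest.raises(ValueError):
            kt.detect_kinks(kt.ContourTrace("coarse", pts), window=4.0)

    def test_linear_density_arithmetic(self):
        trace = straight_trace(500.0)
        calls = [kt.KinkCall("line", 50.0 * i, 90.0, 2.0) for i in range(1, 11)]
        assert kt.kink_linear_density(trace, calls, P=50.0) == pytest.approx(1.0)
        assert kt.kink_linear_density(trace, [], P=50.0) == 0.0


class TestHistogramsAndProfiles:
    def test_constant_values_single_mode(self):
        edges, counts, mode = kt.segment_length_histogram(np.full(20, 8.0), 1.0)
        assert mode[0] <= 8.0 <= mode[1]
        assert counts.sum() == 20

    def test_needs_enough_values(self):
        with pytest.raises(ValueError):
            kt.segment_length_histogram(np.arange(5), 1.0)

    def test_cosine_profile_spacings(self):
        arc, h, _ = kt.make_height_profile(period=8.0, noise=0.0, seed=0)
        sp = kt.profile_minima_spacings(arc, h)
        assert np.allclose(sp, 8.0, atol=0.3)

    def test_noise_robustness(self):
        arc, h, _ = kt.make_height_profile(period=8.0, noise=0.05, seed=4)
        sp = kt.profile_minima_spacings(arc, h)
        _, _, mode = kt.segment_length_histogram(sp, 1.0)
        assert mode[0] <= 8.0 <= mode[1] + 1.0

    def test_height_band_enforced(self):
        arc = np.arange(0.0, 50.0, 0.5)
        with pytest.raises(ValueError):
            kt.profile_minima_spacings(arc, np.full_like(arc, 2.5), d_DNA=2.0)

    def test_flat_profile_warns_empty(self):
        arc = np.arange(0.0, 50.0, 0.5)
        with pytest.warns(UserWarning):
            sp = kt.profile_minima_spacings(arc, np.full_like(arc, 1.0))
        assert sp.size == 0


class TestAnisotropy:
    def test_perfect_sixfold(self):
        traces = [straight_trace(100.0, angle=math.radians(a), mid=f"t{i}")
                  for i, a in enumerate(np.repeat([0.0, 60.0, 120.0], 40))]
        score = kt.orientation_anisotropy(traces)
        assert score == pytest.approx(1.0, abs=1e-6)

    def test_isotropic_null_is_small(self):
        rng = np.random.default_rng(0)
        traces = [straight_trace(100.0, angle=rng.uniform(0, math.pi), mid=f"t{i}")
                  for i in range(300)]
        score, p, _ = kt.orientation_anisotropy(traces, n_permutations=199, seed=1)
        assert score < 2.0 / math.sqrt(300) + 0.05
        assert p > 0.05

    def test_needs_enough_segments(self):
        with pytest.raises(ValueError):
            kt.orientation_anisotropy([straight_trace(100.0)])

    def test_extended_segments_split_at_sharp_turns(self):
        a = np.stack([np.arange(0.0, 40.0), np.zeros(40)], axis=1)
        b = np.stack([np.full(40, 39.0), np.arange(1.0, 41.0)], axis=1)
        segs = kt.extended_segments(kt.ContourTrace("L", np.vstack([a, b])))
        assert len(segs) == 2
        angles = sorted(s[0] for s in segs)
        assert angles[0] == pytest.approx(0.0, abs=2.0)
        assert angles[1] == pytest.approx(90.0, abs=2.0)
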