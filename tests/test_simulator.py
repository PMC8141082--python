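import math

import numpy as np
import pytest

import kinktrap as kt
from conftest import between_molecule_dev


class TestWlc2d:
    def test_rigid_limit_is_straight(self):
        chain = kt.generate_wlc_2d(P=1e7, L=300.0, a=1.0, seed=1)
        assert chain.end_to_end_sq == pytest.approx(300.0 ** 2, rel=1e-3)

    def test_spacing_invariant(self):
        chain = kt.generate_wlc_2d(53.0, 200.0, 1.0, seed=2)
        seg = np.linalg.norm(np.diff(chain.points, axis=0), axis=1)
        assert np.max(np.abs(seg - 1.0)) < 1e-9

    def test_segment_too_coarse_rejected(self):
        with pytest.raises(ValueError):
            kt.generate_wlc_2d(P=5.0, L=100.0, a=1.0, seed=0)

    def test_ensemble_matches_equilibrated_law(self, eq_ensemble_small,
                                               eq_traces_small):
        curve = kt.mean_square_end_to_end(eq_traces_small)
        theory = kt.wlc_theory_curve(53.0, "equilibrated2d", curve.L_grid)
        mask = curve.L_grid <= 450.0
        dev = between_molecule_dev(curve, theory)
        assert np.nanmax(dev[mask]) < 3.0

    def test_tangent_correlation_length_is_2P(self, eq_ensemble_small):
        lags = np.arange(1, 40)
        corr = np.zeros(len(lags))
        for c in eq_ensemble_small[:150]:
            phi = c.tangent_angles
            for i, k in enumerate(lags):
                corr[i] += np.mean(np.cos(phi[k:] - phi[:-k]))
        corr /= 150
        slope = np.polyfit(lags.astype(float), np.log(corr), 1)[0]
        assert -1.0 / slope == pytest.approx(2 * 53.0, rel=0.05)


class TestProjected:
    def test_projection_ratio_two_thirds(self):
        chains = kt.wlc3d_projected_ensemble(400, 53.0, 900.0, 1.0, seed=5)
        r2p = np.array([c.end_to_end_sq for c in chains])
        r23 = np.array([c.metadata["end_to_end_sq_3d"] for c in chains])
        ratio = r2p.mean() / r23.mean()
        se = ratio * (r2p.std() / r2p.mean() + r23.std() / r23.mean()) / math.sqrt(len(chains))
        assert abs(ratio - 2.0 / 3.0) < 3 * se + 0.02

    def test_large_L_slope(self):
        # asymptotic slope of the projected law is (4/3) P per nm
        L = np.array([5000.0, 6000.0])
        th = kt.wlc_theory_curve(53.0, "projected", L)
        slope = np.diff(th.R2)[0] / np.diff(L)[0]
        assert slope == pytest.approx(4.0 / 3.0 * 53.0, rel=0.02)

    def test_stiff_limit_straight(self):
        chain = kt.generate_wlc_3d_projected(P=1e7, L=300.0, a=1.0, seed=3)
        # projection of a straight 3D rod is straight (shorter) in-plane
        d = np.diff(chain.points, axis=0)
        phi = np.arctan2(d[:, 1], d[:, 0])
        assert np.ptp(phi) < 1e-2


class TestTrapping:
    def test_zero_charge_reproduces_input_exactly(self, default_params, sim_cfg):
        field0 = kt.SurfaceChargeField(grains=kt.sample_adlayer(0.0, seed=1),
                                       params=default_params)
        base = kt.generate_wlc_2d(53.0, 450.0, 1.0, seed=8)
        trapped = kt.trap_on_surface(base, field0, sim_cfg, seed=9)
        assert np.allclose(trapped.points - trapped.points[0],
                           base.points - base.points[0], atol=1e-9)
        assert not trapped.kinks

    def test_requires_field(self, sim_cfg):
        base = kt.generate_wlc_2d(53.0, 450.0, 1.0, seed=8)
        with pytest.raises(ValueError):
            kt.trap_on_surface(base, None, sim_cfg, seed=0)

    def test_contour_length_conserved(self, trapped_small):
        for c in trapped_small[:10]:
            assert abs(c.contour_length - 450.0) < 1e-6 * 450.0

    def test_bit_identical_reproducibility(self, template_field, sim_cfg):
        base = kt.generate_wlc_3d_projected(53.0, 300.0, 1.0, seed=4)
        c1 = kt.trap_on_surface(base, template_field, sim_cfg, seed=17)
        c2 = kt.trap_on_surface(base, template_field, sim_cfg, seed=17)
        assert np.array_equal(c1.points, c2.points)
        assert c1.kinks == c2.kinks

    def test_kink_formation_torque_overcritical(self, trapped_small,
                                                default_params):
        torques = [k[2] for c in trapped_small for k in c.kinks]
        assert torques
        assert min(torques) >= default_params.tau_K

    def test_kink_density_several_per_P(self, trapped_small):
        per_P = np.mean([len(c.kinks) for c in trapped_small]) / (450.0 / 53.0)
        assert per_P >= 2.0

    def test_trapped_more_compact_than_equilibrated(self, trapped_small):
        r2 = np.mean([c.end_to_end_sq for c in trapped_small])
        eq = kt.wlc_theory_curve(53.0, "equilibrated2d", np.array([450.0])).R2[0]
        assert r2 < eq

    def test_kinks_survive_high_salt_but_rarer(self, sim_cfg):
        dens = {}
        for I in (0.002, 0.2):
            params = kt.ElectrostaticParams.from_ionic_strength(I)
            field = kt.SurfaceChargeField(
                template=kt.LamellarTemplate(extent=600.0), params=params)
            chains = kt.trap_ensemble(12, field, sim_cfg, seed=31)
            dens[I] = np.mean([len(c.kinks) for c in chains]) / (450.0 / 53.0)
        assert dens[0.2] > 0.0
        assert dens[0.2] < dens[0.002]

    def test_stress_fields_populated(self, trapped_small):
        c = trapped_small[0]
        assert set(c.stress) == {"torque", "tension", "unzip"}
        assert len(c.stress["torque"]) == len(c.points)
        assert set(np.unique(c.site_labels)) <= {"plain", "B", "S"}


class TestZigzag:
    def test_right_angle_segment_length(self):
        z = kt.confined_zigzag_chain(4.0, (90.0, 90.0), 10, seed=0)
        assert np.allclose(z.metadata["segment_lengths"],
                           4.0 / math.sin(math.radians(45.0)), atol=1e-9)

    def test_chord_geometry(self):
        z = kt.confined_zigzag_chain(4.0, (85.0, 105.0), 30, seed=2)
        v = np.array(z.metadata["vertex_angles"])
        expected = 4.0 / np.sin(np.radians((180.0 - v) / 2.0))
        assert np.allclose(z.metadata["segment_lengths"][1:], expected, atol=1e-9)

    def test_mode_in_5_to_6_nm(self):
        segs = []
        for s in range(40):
            z = kt.confined_zigzag_chain(4.0, (85.0, 105.0), 25, seed=s)
            segs.extend(z.metadata["segment_lengths"])
        _, _, mode = kt.segment_length_histogram(segs, 1.0)
        assert 5.0 <= mode[0] and mode[1] <= 6.5

    def test_kink_density_order_ten_per_P(self):
        z = kt.confined_zigzag_chain(4.0, (85.0, 105.0), 40, seed=1)
        per_P = len(z.kinks) / z.contour_length * 53.0
        assert 6.0 <= per_P <= 12.0

    def test_vertices_alternate_rows(self):
        z = kt.confined_zigzag_chain(4.0, (90.0, 90.0), 8, seed=0)
        kink_pts = z.points[[k[0] for k in z.kinks]]
        assert np.allclose(np.abs(np.diff(kink_pts[:, 1])), 4.0, atol=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            kt.confined_zigzag_chain(-1.0)
        with pytest.raises(ValueError):
            kt.confined_zigzag_chain(4.0, (0.0, 200.0))
        with pytest.raises(ValueError):
            kt.confined_zigzag_chain(4.0, n_segments=1)


class TestTwistAndAnomalies:
    def test_twist_variance_formula(self):
        assert kt.twist_variance(100.0, 100.0) == 1.0
        assert kt.twist_variance(0.0, 100.0) == 0.0
        assert kt.twist_variance(40.0, 100.0) == 2 * kt.twist_variance(20.0, 100.0)
        with pytest.raises(ValueError):
            kt.twist_variance(10.0, 0.0)

    def _make_chain(self, n=120):
        pts = np.stack([np.arange(n, dtype=float), np.zeros(n)], axis=1)
        c = kt.ChainConformation(pts, spacing=1.0)
        c.stress = {"torque": np.zeros(n), "tension": np.zeros(n),
                    "unzip": np.zeros(n)}
        return c

    def test_no_stress_no_anomalies(self, sim_cfg):
        c = self._make_chain()
        c = kt.classify_anomalies(c, sim_cfg)
        assert c.anomalies == []

    def test_tensed_overwound_interval_is_plectoneme(self, sim_cfg):
        c = self._make_chain()
        c.stress["tension"][20:61] = 4.0  # above the several-pN threshold
        s12 = 40.0
        c.twist_register = [(20, 60, 2.5 * math.sqrt(s12 / sim_cfg.C))]
        c = kt.classify_anomalies(c, sim_cfg)
        assert [a["type"] for a in c.anomalies] == ["plectoneme"]

    def test_subthermal_twist_is_not_plectoneme(self, sim_cfg):
        c = self._make_chain()
        c.stress["tension"][20:61] = 4.0
        c.twist_register = [(20, 60, 0.2 * math.sqrt(40.0 / sim_cfg.C))]
        c = kt.classify_anomalies(c, sim_cfg)
        assert c.anomalies == []

    def test_unzipped_interval_is_bubble(self, sim_cfg):
        c = self._make_chain()
        c.stress["unzip"][70:76] = 12.0
        c = kt.classify_anomalies(c, sim_cfg)
        assert [a["type"] for a in c.anomalies] == ["bubble"]
        sep = c.anomalies[0]["metadata"]["strand_separation_nm"]
        assert 4.0 <= sep <= 5.0

    def test_anomalies_mutually_exclusive(self, sim_cfg):
        c = self._make_chain()
        c.stress["tension"][20:61] = 4.0
        c.twist_register = [(20, 60, 3.0)]
        c.stress["unzip"][30:35] = 12.0  # inside the plectoneme span
        c = kt.classify_anomalies(c, sim_cfg)
        assert [a["type"] for a in c.anomalies] == ["plectoneme"]


class TestEnergetics:
    def test_no_kinks_no_stored_energy(self, sim_cfg):
        c = kt.generate_wlc_2d(53.0, 450.0, 1.0, seed=1)
        assert kt.stored_energy_density(c, sim_cfg) == 0.0

    def test_ten_kinks_per_P_stores_70kT(self, sim_cfg):
        n = 450
        pts = np.stack([np.arange(n + 1.0), np.zeros(n + 1)], axis=1)
        c = kt.ChainConformation(pts, spacing=1.0)
        n_kinks = int(round(10 * 450.0 / 53.0))
        c.kinks = [(i, 90.0, 35.0) for i in range(1, n_kinks + 1)]
        e = kt.stored_energy_density(c, sim_cfg)
        assert e == pytest.approx(10 * 7.0, rel=0.01)
        # ~two orders of magnitude above the ~kT per P baseline
        assert round(math.log10(e / 1.0)) == 2

    def test_open_bp_probability_conversion(self):
        val = kt.open_bp_probability_per_persistence()
        assert val == pytest.approx(1.5e-3, rel=0.1)
        assert kt.open_bp_probability_per_persistence(0.0) == 0.0
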