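"""Generator correctness: Poisson statistics, docking, rendering, determinism."""

import logging

import numpy as np
import pytest

from vpikit import binding_models as bm
from vpikit import synthetic_data as sd


class TestProteinSurface:
    def test_zero_density_is_empty(self, small_config):
        surf = sd.simulate_protein_surface(0.0, small_config)
        assert surf.n == 0

    def test_negative_density_rejected(self, small_config):
        with pytest.raises(ValueError, match="density"):
            sd.simulate_protein_surface(-0.1, small_config)

    def test_seed_determinism(self, small_config):
        a = sd.simulate_protein_surface(0.5, small_config)
        b = sd.simulate_protein_surface(0.5, small_config)
        np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(a.multiplicity, b.multiplicity)

    def test_poisson_moments(self):
        # mean ~ rho*A and variance/mean within [0.8, 1.2] over 200 seeds
        cfg = sd.SimulationConfig(field_size=100.0, seed=0)
        rng = np.random.default_rng(123)
        counts = np.array(
            [sd.simulate_protein_surface(1.0, cfg, rng=rng).n for _ in range(200)]
        )
        area = cfg.area_um2
        assert counts.mean() == pytest.approx(area, rel=0.02)
        assert 0.8 <= counts.var(ddof=1) / counts.mean() <= 1.2

    def test_points_inside_field(self, small_config, rng):
        surf = sd.simulate_protein_surface(2.0, small_config, rng=rng)
        w, h = small_config.field_dims
        assert surf.points[:, 0].min() >= 0 and surf.points[:, 0].max() <= w
        assert surf.points[:, 1].min() >= 0 and surf.points[:, 1].max() <= h

    def test_dimer_fraction(self, rng):
        cfg = sd.SimulationConfig(field_size=100.0, seed=0)
        surf = sd.simulate_protein_surface(1.0, cfg, dimer_fraction=0.5, rng=rng)
        frac2 = (surf.multiplicity == 2).mean()
        assert frac2 == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(surf.n))


class TestPairingAndDocking:
    def test_isolated_fraction_matches_poisson_prediction(self):
        # singles fraction over many fields ~ exp(-rho*pi*d^2)
        cfg = sd.SimulationConfig(field_size=51.2, seed=0)
        rho, d = 1.0, 0.1
        rng = np.random.default_rng(99)
        singles = total = 0
        for _ in range(30):
            surf = sd.simulate_protein_surface(rho, cfg, rng=rng)
            pairs, single_idx = sd.pair_sites(surf.points, d)
            singles += len(single_idx)
            total += surf.n
        p_hat = singles / total
        p_theory = np.exp(-rho * np.pi * d**2)
        se = np.sqrt(p_theory * (1 - p_theory) / total)
        # greedy leftovers of triplet cliques add O(lambda^2) singles
        assert abs(p_hat - p_theory) < 3 * se + 1e-3

    def test_no_vesicles_without_concentration(self, small_config, rng):
        surf = sd.simulate_protein_surface(1.0, small_config, rng=rng)
        field = sd.simulate_vesicle_binding(
            surf, bm.LangmuirParams(K_d=0.25), 0.0, small_config, rng=rng
        )
        assert field.n == 0

    def test_half_saturation_occupancy(self, rng):
        cfg = sd.SimulationConfig(field_size=100.0, seed=0)
        surf = sd.simulate_protein_surface(1.0, cfg, rng=rng)
        # V = K_d (in pM), alpha = 1: each site occupied w.p. 1/2
        field = sd.simulate_vesicle_binding(
            surf, bm.LangmuirParams(K_d=0.25, alpha=1.0), 250.0, cfg, rng=rng
        )
        frac = field.n / surf.n
        assert frac == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(surf.n))

    def test_bound_count_matches_analytic_site_model(self):
        # MC mean bound count tracks alpha*(s1*occ1 + s2*occ2)*area
        cfg = sd.SimulationConfig(field_size=51.2, seed=0)
        model = bm.CooperativeParams(K_d1=130.0, K_d2=0.09, d=0.1, alpha=1.0)
        V = 90.0  # pM = K_d2: pair sites half occupied
        rng = np.random.default_rng(5)
        rho = 2.0
        counts = []
        for _ in range(40):
            surf = sd.simulate_protein_surface(rho, cfg, rng=rng)
            counts.append(sd.simulate_vesicle_binding(surf, model, V, cfg, rng=rng).n)
        s1, s2 = bm.site_densities(rho, model.d)
        occ1 = V / (V + model.K_d1 * 1e3)
        occ2 = V / (V + model.K_d2 * 1e3)
        expected = (s1 * occ1 + s2 * occ2) * cfg.area_um2
        se = np.sqrt(expected / 40)  # ~Poisson scale
        assert np.mean(counts) == pytest.approx(expected, abs=4 * se)

    def test_vesicles_near_sites(self, small_config, rng):
        surf = sd.simulate_protein_surface(2.0, small_config, rng=rng)
        model = bm.CooperativeParams(K_d1=1.0, K_d2=0.001, d=0.1, alpha=1.0)
        field = sd.simulate_vesicle_binding(surf, model, 100.0, small_config, rng=rng)
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(surf.points).query(field.bound_positions)
        # site centroids lie within d/2 of a member protein
        assert dist.max() <= model.d / 2 + 1e-9

    def test_unsupported_model_rejected(self, small_config, rng):
        surf = sd.simulate_protein_surface(0.1, small_config, rng=rng)
        with pytest.raises(TypeError, match="LangmuirParams"):
            sd.simulate_vesicle_binding(surf, bm.HillParams(1, 1, 1), 1.0, small_config, rng=rng)


class TestRendering:
    def test_offset_only_when_dark(self):
        cfg = sd.SimulationConfig(
            field_size=5.0, seed=1, read_noise_sd=0.0, camera_offset=100.0, frames=2
        )
        stack = sd.render_image_stack({"g": (np.empty((0, 2)), np.empty(0))}, cfg)
        np.testing.assert_array_equal(stack.channel("g"), 100.0)

    def test_flux_conservation(self):
        cfg = sd.SimulationConfig(
            field_size=10.0, seed=1, read_noise_sd=0.0, camera_offset=0.0,
            frames=1, shot_noise=False,
        )
        pts = np.array([[5.0, 5.0], [3.0, 7.0]])
        stack = sd.render_image_stack({"g": (pts, np.array([500.0, 1000.0]))}, cfg)
        assert stack.channel("g").sum() == pytest.approx(1500.0, rel=1e-3)

    def test_crosstalk_mixes_before_noise(self):
        beta = 0.05
        cfg = sd.SimulationConfig(
            field_size=10.0, seed=1, read_noise_sd=0.0, camera_offset=0.0,
            frames=1, shot_noise=False,
            crosstalk_matrix=np.array([[1.0, beta], [0.0, 1.0]]),
        )
        pts = np.array([[5.0, 5.0]])
        stack = sd.render_image_stack(
            {"a": (pts, np.array([1000.0])), "b": (np.empty((0, 2)), np.empty(0))}, cfg
        )
        assert stack.channel("b").sum() == pytest.approx(beta * 1000.0, rel=1e-3)
        assert stack.channel("a").sum() == pytest.approx(1000.0, rel=1e-3)

    def test_emitters_outside_field_rejected(self, small_config):
        with pytest.raises(ValueError, match="outside"):
            sd.render_image_stack(
                {"g": (np.array([[30.0, 5.0]]), np.array([100.0]))}, small_config
            )

    def test_undersampled_psf_warns(self, caplog):
        cfg = sd.SimulationConfig(field_size=5.0, seed=0, pixel_size=0.6, psf_sigma=0.13)
        with caplog.at_level(logging.WARNING):
            sd.render_image_stack({"g": (np.empty((0, 2)), np.empty(0))}, cfg)
        assert any("undersampled" in r.message for r in caplog.records)

    def test_seed_determinism(self, small_config):
        pts = np.array([[5.0, 5.0]])
        a = sd.render_image_stack({"g": (pts, np.array([500.0]))}, small_config)
        b = sd.render_image_stack({"g": (pts, np.array([500.0]))}, small_config)
        np.testing.assert_array_equal(a.channel("g"), b.channel("g"))


class TestBleachTraces:
    def test_single_fluorophore_single_step(self):
        truth = sd.BleachTraceTruth(n_fluorophores=1, step_size=10.0, bleach_rate=0.5,
                                    frames=100, frame_interval=0.1)
        trace = sd.simulate_bleach_trace(truth, 0.0, rng=3)
        levels = np.unique(trace)
        assert set(levels) == {0.0, 10.0}
        assert trace[0] == 10.0 and trace[-1] == 0.0
        # exactly one downward transition
        assert (np.diff(trace) < 0).sum() == 1

    def test_initial_level_counts_fluorophores(self):
        truth = sd.BleachTraceTruth(n_fluorophores=3, step_size=7.0, bleach_rate=0.01,
                                    frames=50, frame_interval=0.1)
        trace = sd.simulate_bleach_trace(truth, 0.0, rng=4)
        assert trace[0] == pytest.approx(21.0)

    def test_first_step_time_order_statistic(self):
        # for n=2 fluorophores at rate r, the first bleach time ~ Exp(2r)
        r = 0.5
        truth = sd.BleachTraceTruth(n_fluorophores=2, step_size=1.0, bleach_rate=r,
                                    frames=200, frame_interval=0.1)
        rng = np.random.default_rng(11)
        first_times = []
        for _ in range(10_000):
            trace = sd.simulate_bleach_trace(truth, 0.0, rng=rng)
            drops = np.nonzero(np.diff(trace) < 0)[0]
            first_times.append((drops[0] + 1) * truth.frame_interval)
        mean_expected = 1.0 / (2 * r)  # = 1 s
        se = mean_expected / np.sqrt(10_000)
        # frame quantisation subtracts up to half a frame interval
        assert np.mean(first_times) == pytest.approx(
            mean_expected + truth.frame_interval / 2, abs=4 * se + 0.02
        )


class TestTimecourse:
    def test_zero_start_and_plateau(self):
        kin = bm.KineticParams(k_on=1e-3, k_off=1e-3, N_eq=0.4)
        curve = sd.simulate_binding_timecourse(kin, 3.3, np.array([0.0, 1e5]))
        assert curve.y_mean[0] == 0.0
        assert curve.y_mean[-1] == pytest.approx(0.4, rel=1e-4)

    def test_half_rise(self):
        kin = bm.KineticParams(k_on=0.0, k_off=0.02, N_eq=1.0)
        t_half = np.log(2) / 0.02
        curve = sd.simulate_binding_timecourse(kin, 0.0, np.array([t_half / 10, t_half]))
        assert curve.y_mean[-1] == pytest.approx(0.5, rel=1e-9)

    def test_equilibrium_from_model(self):
        kin = bm.KineticParams(k_on=0.0, k_off=1.0, N_eq=0.0)
        model = bm.LangmuirParams(K_d=0.25, alpha=1.0)
        curve = sd.simulate_binding_timecourse(
            kin, 250.0, np.array([1e4]), equilibrium=model, rho=2.0
        )
        assert curve.y_mean[0] == pytest.approx(1.0)  # rho/2 at half saturation

    def test_times_validated(self):
        kin = bm.KineticParams(k_on=0.0, k_off=1.0, N_eq=1.0)
        with pytest.raises(ValueError):
            sd.simulate_binding_timecourse(kin, 0.0, np.array([1.0, 0.5]))


class TestFixtures:
    def test_unknown_scenario(self, tmp_path):
        with pytest.raises(ValueError, match="unknown scenario"):
            sd.generate_fixture_dataset("no-such-thing", 0, tmp_path)

    def test_manifest_checksums_deterministic(self, tmp_path):
        m1 = sd.generate_fixture_dataset("colocalization-slb", 7, tmp_path / "a")
        m2 = sd.generate_fixture_dataset("colocalization-slb", 7, tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_u937_truth_is_simple_langmuir(self, tmp_path):
        m = sd.generate_fixture_dataset("u937-like-linear", 3, tmp_path)
        assert m["truth"]["model"] == "LangmuirParams"
        assert m["truth"]["params"]["K_d"] == 0.25

    def test_calibration_ladder_spans_densities(self):
        d = sd.CALIBRATION_DENSITIES
        assert len(d) >= 6
        assert min(d) == 0.01 and max(d) == 40.0
        assert sum(1 for x in d if x <= 1.0) >= 3
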