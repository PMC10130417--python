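"""Crosstalk correction, spot matching, enrichment and per-class statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpikit import binding_models as bm
from vpikit import colocalization as cl
from vpikit import spot_analysis as sa
from vpikit import synthetic_data as sd
from vpikit.imagestack import ImageStack


def _pure_species_stack(channel_names, native, seed, beta_matrix, photons=2000.0):
    cfg = sd.SimulationConfig(
        field_size=25.6, seed=seed, crosstalk_matrix=beta_matrix,
        photons_per_fluorophore=photons,
    )
    surf = sd.simulate_protein_surface(0.15, cfg)
    emitters = {
        ch: (surf.points, surf.emitter_photons(cfg)) if ch == native
        else (np.empty((0, 2)), np.empty(0))
        for ch in channel_names
    }
    return sd.render_image_stack(emitters, cfg)


class TestCrosstalk:
    BETA = np.array([[1.0, 0.05], [0.0, 1.0]])

    def test_null_crosstalk_recovered(self):
        eye = np.eye(2)
        stacks = {
            "green": _pure_species_stack(("green", "red"), "green", 1, eye),
            "red": _pure_species_stack(("green", "red"), "red", 2, eye),
        }
        m = cl.estimate_crosstalk(stacks)
        assert abs(m.beta("green", "red")) < 0.005
        assert abs(m.beta("red", "green")) < 0.005

    def test_five_percent_bleed_recovered(self):
        stacks = {
            "green": _pure_species_stack(("green", "red"), "green", 3, self.BETA),
            "red": _pure_species_stack(("green", "red"), "red", 4, self.BETA),
        }
        m = cl.estimate_crosstalk(stacks)
        assert m.beta("green", "red") == pytest.approx(0.05, abs=0.01)

    def test_channel_order_transposes(self):
        stacks = {
            "green": _pure_species_stack(("green", "red"), "green", 3, self.BETA),
            "red": _pure_species_stack(("green", "red"), "red", 4, self.BETA),
        }
        m1 = cl.estimate_crosstalk(stacks)
        m2 = cl.estimate_crosstalk(dict(reversed(list(stacks.items()))))
        assert m2.beta("green", "red") == pytest.approx(m1.beta("green", "red"), abs=1e-12)
        assert m2.channels == tuple(reversed(m1.channels))

    def test_insufficient_spots_rejected(self):
        cfg = sd.SimulationConfig(field_size=10.0, seed=5, photons_per_fluorophore=2000.0)
        pts = np.array([[5.0, 5.0]])
        stack = sd.render_image_stack(
            {"green": (pts, np.array([2000.0])), "red": (np.empty((0, 2)), np.empty(0))}, cfg
        )
        with pytest.raises(ValueError, match="insufficient"):
            cl.estimate_crosstalk({"green": stack})

    def test_identity_correction_is_noop(self):
        stack = _pure_species_stack(("green", "red"), "green", 6, np.eye(2))
        m = cl.CrosstalkMatrix(("green", "red"), np.eye(2))
        corrected = cl.correct_crosstalk(stack, m, background={"green": 0.0, "red": 0.0})
        for ch in stack.channel_names:
            np.testing.assert_allclose(corrected.channel(ch), stack.channel(ch))

    def test_mix_then_unmix_restores_noiseless_images(self):
        beta = np.array([[1.0, 0.07], [0.03, 1.0]])
        base = dict(field_size=12.8, seed=7, read_noise_sd=0.0, camera_offset=0.0,
                    frames=1, shot_noise=False, photons_per_fluorophore=1.0)
        pts_a = np.array([[3.0, 3.0], [9.0, 4.0]])
        pts_b = np.array([[6.0, 8.0]])
        emitters = {"a": (pts_a, np.array([900.0, 1200.0])), "b": (pts_b, np.array([700.0]))}
        clean = sd.render_image_stack(emitters, sd.SimulationConfig(**base))
        mixed = sd.render_image_stack(
            emitters, sd.SimulationConfig(**base, crosstalk_matrix=beta)
        )
        m = cl.CrosstalkMatrix(("a", "b"), beta)
        fixed = cl.correct_crosstalk(mixed, m, background={"a": 0.0, "b": 0.0})
        for ch in ("a", "b"):
            np.testing.assert_allclose(
                fixed.channel(ch), clean.channel(ch), atol=1e-3 * 1200
            )

    @settings(max_examples=25, deadline=None)
    @given(
        b12=st.floats(min_value=0.0, max_value=0.49),
        b21=st.floats(min_value=0.0, max_value=0.49),
    )
    def test_unmixing_exactness_property(self, b12, b21):
        # correct_crosstalk ∘ mix = identity for any invertible matrix, β<0.5
        rng = np.random.default_rng(17)
        beta = np.array([[1.0, b12], [b21, 1.0]])
        true = rng.uniform(0, 100, (2, 1, 8, 8))
        mixed = np.tensordot(beta.T, true, axes=1)
        stack = ImageStack(channels={"a": mixed[0], "b": mixed[1]}, pixel_size=0.108)
        m = cl.CrosstalkMatrix(("a", "b"), beta)
        fixed = cl.correct_crosstalk(stack, m, background={"a": 0.0, "b": 0.0})
        np.testing.assert_allclose(fixed.channel("a"), true[0], atol=1e-9)
        np.testing.assert_allclose(fixed.channel("b"), true[1], atol=1e-9)

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            cl.CrosstalkMatrix(("a", "b"), np.array([[1.0, 1.2], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            cl.CrosstalkMatrix(("a", "b"), np.array([[0.9, 0.0], [0.0, 1.0]]))


class TestMatchSpots:
    def test_identical_lists_fully_matched(self, rng):
        pts = rng.uniform(0, 50, (40, 2))
        res = cl.match_spots(pts, pts.copy(), 0.216)
        assert res.fraction_A_coloc == 1.0 and res.fraction_B_coloc == 1.0
        assert res.n_matched == 40

    def test_distant_lists_unmatched(self, rng):
        a = rng.uniform(0, 10, (20, 2))
        b = a + 50.0  # shifted entirely outside the original field
        res = cl.match_spots(a, b, 0.216)
        assert res.n_matched == 0

    def test_matching_symmetric_in_count(self, rng):
        a = rng.uniform(0, 30, (50, 2))
        b = rng.uniform(0, 30, (80, 2))
        r_ab = cl.match_spots(a, b, 0.5)
        r_ba = cl.match_spots(b, a, 0.5)
        assert r_ab.n_matched == r_ba.n_matched

    def test_one_to_one(self, rng):
        # two A spots near one B spot: only one may match
        a = np.array([[1.0, 1.0], [1.05, 1.0]])
        b = np.array([[1.02, 1.0]])
        res = cl.match_spots(a, b, 0.216)
        assert res.n_matched == 1

    def test_chance_fraction_law(self):
        rng = np.random.default_rng(23)
        area = 200.0 * 200.0
        n_a = rng.poisson(0.05 * area)
        n_b = rng.poisson(0.7 * area)
        a = rng.uniform(0, 200, (n_a, 2))
        b = rng.uniform(0, 200, (n_b, 2))
        res = cl.match_spots(a, b, 0.216, field_area_um2=area)
        p = res.chance_fraction
        se = np.sqrt(p * (1 - p) / n_a)
        assert abs(res.fraction_A_coloc - p) < 3 * se


class TestEnrichmentAndClasses:
    def test_fold_arithmetic(self):
        assert cl.enrichment_fold(0.41, 0.10)["fold"] == pytest.approx(4.1)
        assert cl.enrichment_fold(0.2, 0.2)["fold"] == 1.0

    def test_fold_ci_excludes_unity_for_specific_capture(self, rng):
        target = rng.random(400) < 0.45
        control = rng.random(400) < 0.10
        res = cl.enrichment_fold(target, control, seed=4)
        lo, hi = res["ci95"]
        assert res["fold"] > 1 and lo > 1.0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            cl.enrichment_fold(0.4, 0.0)

    def test_vesicle_bound_fraction_degenerate_cases(self, rng):
        a_only = rng.uniform(0, 20, (30, 2))
        both = rng.uniform(0, 20, (30, 2))
        out = cl.vesicle_bound_fraction(np.empty((0, 2)), {"A_only": a_only, "A+B": both})
        assert out == {"A_only": 0.0, "A+B": 0.0}
        out = cl.vesicle_bound_fraction(both, {"A_only": a_only + 50, "A+B": both})
        assert out["A+B"] == 1.0 and out["A_only"] == 0.0

    def test_pair_sites_capture_preferentially(self):
        # K_d2/K_d1 = 1e-3: occupancy of paired sites dwarfs single sites
        cfg = sd.SimulationConfig(field_size=51.2, seed=9)
        model = bm.CooperativeParams(K_d1=100.0, K_d2=0.1, d=0.1, alpha=1.0)
        rng = np.random.default_rng(31)
        surf = sd.simulate_protein_surface(5.0, cfg, rng=rng)
        pairs, singles = sd.pair_sites(surf.points, model.d)
        field = sd.simulate_vesicle_binding(surf, model, 500.0, cfg, rng=rng)
        classes = {
            "single": surf.points[singles],
            "paired": (surf.points[pairs[:, 0]] + surf.points[pairs[:, 1]]) / 2,
        }
        out = cl.vesicle_bound_fraction(field.bound_positions, classes, 0.05)
        assert out["paired"] >= 5 * max(out["single"], 1e-3)

    def test_ratiometric_ratios(self):
        assert cl.ratiometric_bound_fraction(0.07)["ratio"] == 14
        assert cl.ratiometric_bound_fraction(0.5)["ratio"] == 2
        assert cl.ratiometric_bound_fraction(1.0)["ratio"] == 1
        with pytest.raises(ValueError):
            cl.ratiometric_bound_fraction(0.0)

    def test_intensity_by_class_requires_two_classes(self, rng):
        vals = rng.normal(100, 10, 60)
        with pytest.raises(ValueError, match="2 classes"):
            cl.intensity_by_class(vals, ["x"] * 60)

    def test_intensity_shift_detected(self, rng):
        a = rng.normal(100, 15, 100)
        b = 1.5 * rng.normal(100, 15, 100)
        vals = np.concatenate([a, b])
        labels = ["A"] * 100 + ["B"] * 100
        res = cl.intensity_by_class(vals, labels, seed=5)
        assert res["p_value"] < 0.01

    def test_intensity_null_p_values_not_degenerate(self, rng):
        # identical classes: permutation p-values roughly uniform
        ps = []
        for seed in range(20):
            vals = rng.normal(100, 15, 120)
            labels = (["A", "B"] * 60)[:120]
            ps.append(cl.intensity_by_class(vals, labels, n_permutations=400, seed=seed)["p_value"])
        assert 0.25 < np.mean(ps) < 0.75
        assert min(ps) > 0.001
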