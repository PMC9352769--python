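"""Generator contracts: counts, placement, rendering, reference configs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage, stats as sps

from matiss.config import CampaignConfig, Gradient, ImagingGeometry, SizeModel
from matiss.errors import ConfigurationError, UnknownCampaignError
from matiss.shapes import shape_patch
from matiss.synthetic import (
    draw_ground_truth,
    draw_particle_count,
    fit_gradient,
    inject_macroscopic_object,
    place_particles,
    reference_config,
    render_window,
    simulate_window,
    stratified_config,
)


class TestParticleCounts:
    def test_zero_density_gives_zero(self, tiny_config):
        cfg = tiny_config.with_(coarse_density=0.0)
        rng = np.random.default_rng(0)
        assert draw_particle_count(cfg, "coarse", 64.0, rng) == 0

    def test_poisson_mean_density_2(self, tiny_config):
        # density 2 /mm2 on 64 mm2: sample mean over 1e4 replicates within 3 SE of 128
        cfg = tiny_config.with_(coarse_density=2.0)
        rng = np.random.default_rng(1)
        counts = [draw_particle_count(cfg, "coarse", 64.0, rng) for _ in range(10_000)]
        se = np.sqrt(128 / 10_000)
        assert abs(np.mean(counts) - 128.0) < 3 * se

    def test_low_density_campaign_mean_count(self, tiny_config):
        # 0.36 /mm2 over an 8x8 mm window: ~23 expected particles
        cfg = tiny_config.with_(coarse_density=0.36)
        rng = np.random.default_rng(2)
        counts = [draw_particle_count(cfg, "coarse", 64.0, rng) for _ in range(4000)]
        se = np.sqrt(23.04 / 4000)
        assert abs(np.mean(counts) - 23.04) < 3 * se

    def test_negative_density_rejected(self, tiny_config):
        with pytest.raises(ConfigurationError):
            tiny_config.with_(fine_density=-1.0)


class TestPlacement:
    def test_uniform_y_not_rejected(self, tiny_config):
        rng = np.random.default_rng(3)
        tbl = place_particles(tiny_config, 3000, rng, "coarse")
        p = sps.kstest(tbl.y_um / tiny_config.window_um, "uniform").pvalue
        assert p > 0.01

    def test_positions_inside_window(self, tiny_config):
        rng = np.random.default_rng(4)
        tbl = place_particles(tiny_config, 2000, rng, "fine")
        w = tiny_config.window_um
        assert ((tbl.x_um >= 0) & (tbl.x_um < w)).all()
        assert ((tbl.y_um >= 0) & (tbl.y_um < w)).all()

    @pytest.mark.parametrize("strength,decreasing", [(2.0, True), (-2.0, False)])
    def test_exponential_gradient_bin_monotonicity(self, strength, decreasing):
        # expected counts across y-bins are monotone in the gradient direction
        g = Gradient("exponential", strength)
        edges = np.linspace(0, 1, 9)
        masses = np.diff(
            [0]
            + [
                (-np.expm1(-strength * e)) / (-np.expm1(-strength))
                for e in edges[1:]
            ]
        )
        diffs = np.diff(masses)
        assert (diffs < 0).all() if decreasing else (diffs > 0).all()
        # and sampled positions carry the right sign
        y = g.sample_y(5000, 8000.0, np.random.default_rng(5))
        near = (y < 4000).sum()
        assert (near > 2500) == decreasing

    def test_gradient_recovery_within_3se(self):
        g = Gradient("exponential", 1.5)
        y = g.sample_y(2000, 8000.0, np.random.default_rng(6))
        s_hat, se = fit_gradient(y, 8000.0)
        assert abs(s_hat - 1.5) < 3 * se

    def test_ground_truth_class_conservation(self, tiny_config):
        rng = np.random.default_rng(7)
        truth = draw_ground_truth(tiny_config.with_(macro_rate=2.0), rng)
        counts = truth.size_class.value_counts()
        assert counts.sum() == len(truth)
        assert set(counts.index) <= {"fine", "coarse", "macroscopic"}

    def test_areas_respect_class_bounds(self, tiny_config):
        rng = np.random.default_rng(8)
        truth = draw_ground_truth(tiny_config, rng)
        fine = truth[truth.size_class == "fine"].area_um2
        coarse = truth[truth.size_class == "coarse"].area_um2
        assert ((fine >= 0.5) & (fine < 50)).all()
        assert ((coarse >= 50) & (coarse < 1500)).all()


class TestShapeRendering:
    @pytest.mark.parametrize(
        "family",
        [
            "coccus",
            "dividing_coccus_with_halo",
            "hexagonal_disc",
            "fiber",
            "angular_crystal",
            "parallelepiped_aggregate",
        ],
    )
    @pytest.mark.parametrize("area_px", [25.0, 120.0, 600.0])
    def test_patch_area_calibration(self, family, area_px):
        # coverage-weighted (rendered) area tracks the nominal area per
        # particle; the half-coverage mask tracks it in the mean
        rng = np.random.default_rng(9)
        mask_errs = []
        for _ in range(8):
            patch = shape_patch(family, area_px, rng)
            assert abs(patch.area_px - area_px) / area_px < 0.04
            mask_errs.append(((patch.cov >= 0.5).sum() - area_px) / area_px)
        if family != "fiber" or area_px >= 100:
            # a half-coverage mask is only meaningful for shapes wider
            # than ~2 px; thinner fibers are partially resolved by design
            assert abs(np.mean(mask_errs)) < 0.05

    def test_halo_not_counted_in_area(self):
        rng = np.random.default_rng(10)
        patch = shape_patch("dividing_coccus_with_halo", 100.0, rng)
        assert patch.halo is not None
        # the halo annulus never reaches the particle interior
        assert (patch.halo[patch.cov >= 1.0] == 0).all()

    def test_render_empty_truth_is_pure_background(self, tiny_config):
        rng = np.random.default_rng(11)
        empty = pd.DataFrame(columns=["id", "x_um", "y_um", "area_um2", "shape", "size_class"])
        stack = render_window(empty, "high", tiny_config, rng)
        blue = stack.frames[..., 2].astype(float)
        bg = tiny_config.rendering.background_high
        assert abs(blue.mean() - bg) < 0.5
        assert abs(blue.std() - tiny_config.noise_sd) < 0.3

    def test_single_disc_rendered_area(self, tiny_config):
        # a 155 um2 disc renders as exactly one dark region whose
        # mid-contrast pixel area tracks 155 um2 / pixel_size^2
        cfg = tiny_config.with_(noise_sd=0.0)
        px = cfg.imaging_low.pixel_size_um
        nominal_px = 155.0 / px**2
        mid = (cfg.rendering.background_low + cfg.rendering.particle_level_low) / 2
        errs = []
        for k, (x, y) in enumerate([(500, 500), (803, 1204), (1501, 301), (901, 1707)]):
            truth = pd.DataFrame(
                [{"id": 0, "x_um": float(x), "y_um": float(y), "area_um2": 155.0,
                  "shape": "coccus", "size_class": "coarse"}]
            )
            stack = render_window(truth, "low", cfg, np.random.default_rng(12 + k))
            blue = stack.frames[..., 2].astype(float).min(axis=0)  # tiles partition
            lab, n = ndimage.label(blue < mid)
            areas = np.bincount(lab.ravel())[1:]
            areas = areas[areas > 0]
            assert len(areas) == 1
            errs.append((areas[0] - nominal_px) / nominal_px)
            assert abs(errs[-1]) < 0.10
        assert abs(np.mean(errs)) < 0.05

    def test_seed_contract_same_truth_different_noise(self, tiny_config):
        truth = pd.DataFrame(
            [{"id": 0, "x_um": 300.0, "y_um": 300.0, "area_um2": 100.0,
              "shape": "coccus", "size_class": "coarse"}]
        )
        s1 = render_window(truth, "low", tiny_config, np.random.default_rng(1))
        s2 = render_window(truth, "low", tiny_config, np.random.default_rng(2))
        s1b = render_window(truth, "low", tiny_config, np.random.default_rng(1))
        assert not np.array_equal(s1.frames, s2.frames)
        assert np.array_equal(s1.frames, s1b.frames)

    def test_simulated_window_bit_identical_under_seed(self, tiny_config):
        a = simulate_window(tiny_config, "high", np.random.default_rng(99))
        b = simulate_window(tiny_config, "high", np.random.default_rng(99))
        assert np.array_equal(a.stack.frames, b.stack.frames)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_coarse_pixel_size_rejected_at_high_zoom(self, tiny_config):
        bad = tiny_config.with_(
            imaging_high=ImagingGeometry(2.0, (512, 512), (1, 1))
        )
        with pytest.raises(ConfigurationError):
            simulate_window(bad, "high", np.random.default_rng(0))


class TestMacroscopicInjection:
    def test_zero_rate_is_identity(self, tiny_config):
        sim = simulate_window(tiny_config, "high", np.random.default_rng(13))
        out, affected, truth = inject_macroscopic_object(
            sim.stack, tiny_config.with_(macro_rate=0.0), np.random.default_rng(14)
        )
        assert out is sim.stack
        assert affected == [] and len(truth) == 0

    def test_injected_object_bookkeeping(self, tiny_config):
        cfg = tiny_config.with_(macro_rate=3.0)
        sim = simulate_window(tiny_config, "high", np.random.default_rng(15))
        out, affected, truth = inject_macroscopic_object(
            sim.stack, cfg, np.random.default_rng(16)
        )
        assert len(truth) >= 1
        assert (truth.size_class == "macroscopic").all()
        assert (truth.area_um2 > 1500).all()
        assert len(affected) >= 1
        # affected frames are consistent with the frame-origin map: each
        # affected frame's footprint is within a penumbra radius of an object
        r, c = out.frame_shape
        px = out.pixel_size_um
        for f in affected:
            ox, oy = out.frame_origins[f]
            cx = np.clip(truth.x_um, ox, ox + c * px)
            cy = np.clip(truth.y_um, oy, oy + r * px)
            dist = np.hypot(cx - truth.x_um, cy - truth.y_um)
            reach = cfg.rendering.penumbra_radius_factor * np.sqrt(truth.area_um2 / np.pi)
            assert (dist <= reach).any()


class TestReferenceConfigs:
    def test_printed_centerlines(self):
        assert reference_config("MATISS-1", 193).coarse_density == pytest.approx(2.45)
        assert reference_config("MATISS-2", 95).fine_density == pytest.approx(3.82)
        assert reference_config("MATISS-2.5", 365).fine_density == pytest.approx(1.02)
        assert reference_config("MATISS-2", 354).exposure_days == 354

    def test_unknown_pair_raises(self):
        with pytest.raises(UnknownCampaignError):
            reference_config("MATISS-3", 10)

    def test_occupancy_rates(self):
        assert reference_config("MATISS-1", 193).occupancy_rate == 1.0
        assert reference_config("MATISS-2.5", 365).occupancy_rate == 0.35

    def test_stratified_signs(self):
        cfg = stratified_config()
        assert cfg.gradient_coarse.strength > 0  # toward the aperture
        assert cfg.gradient_fine.strength < 0

    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_shape_mix_must_sum_to_one(self, p):
        with pytest.raises(ConfigurationError):
            CampaignConfig(
                name="x", exposure_days=1, occupancy_rate=0.5,
                coarse_density=1.0, fine_density=1.0,
                shape_mix_fine={"coccus": p},
            )


class TestSizeModel:
    def test_support_clipping_is_exact(self):
        m = SizeModel("lognormal", 155.0, 0.35, 50.0, 1500.0)
        draws = m.sample(5000, np.random.default_rng(17))
        assert draws.min() >= 50.0 and draws.max() < 1500.0

    def test_mode_parameterisation(self):
        # histogram peak of a large sample sits at the configured mode
        m = SizeModel("lognormal", 155.0, 0.35, 50.0, 1500.0)
        draws = m.sample(200_000, np.random.default_rng(18))
        hist, edges = np.histogram(draws, bins=np.arange(50, 1500, 25.0))
        peak = (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2
        assert abs(peak - 155.0) <= 25.0
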