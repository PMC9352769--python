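"""Measurement-chain contracts: thresholds, rejection, two-pass segmentation."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from matiss.config import SegmentationConfig
from matiss.errors import AllFramesRejectedError, FormatError, InputError
from matiss.frames import ChannelStack
from matiss.segmentation import (
    compute_stack_threshold,
    extract_channel,
    first_pass_segment,
    match_detections,
    refine_particle,
    reject_shadow_frames,
    run_segmentation,
)
from matiss.synthetic import inject_macroscopic_object, render_window, simulate_window
from tests.conftest import make_stack


def _channel_stack(frames, zoom="high", px=0.35):
    frames = np.asarray(frames, dtype=np.uint8)
    n, r, c = frames.shape
    origins = np.column_stack([np.zeros(n), np.arange(n) * r * px])
    return ChannelStack(frames=frames, zoom=zoom, pixel_size_um=px,
                        frame_origins=origins, frame_indices=np.arange(n))


class TestChannelExtraction:
    def test_known_channel_constants(self):
        frame = np.zeros((1, 16, 16, 3), dtype=np.uint8)
        frame[..., 0], frame[..., 1], frame[..., 2] = 30, 60, 90
        stack = make_stack(np.zeros((1, 16, 16), dtype=np.uint8))
        stack.frames = frame
        assert (extract_channel(stack, "blue").frames == 90).all()
        assert (extract_channel(stack, "gray").frames == 60).all()

    def test_pure_blue_frame(self):
        frame = np.zeros((1, 8, 8, 3), dtype=np.uint8)
        frame[..., 2] = 210
        stack = make_stack(np.zeros((1, 8, 8), dtype=np.uint8))
        stack.frames = frame
        assert (extract_channel(stack, "blue").frames == 210).all()
        assert (extract_channel(stack, "gray").frames == 70).all()

    def test_12bit_rescaled_to_working_depth(self):
        vals = np.full((1, 8, 8), 3200, dtype=np.uint16)  # 3200 >> 4 = 200
        rgb = np.repeat(vals[..., None], 3, axis=-1)
        stack = make_stack(np.zeros((1, 8, 8), dtype=np.uint8))
        stack.frames = rgb
        stack.bit_depth = 12
        assert (extract_channel(stack, "blue").frames == 200).all()

    def test_non_stack_input_rejected(self):
        with pytest.raises(FormatError):
            extract_channel(np.zeros((4, 4)), "blue")


class TestStackThreshold:
    def test_constant_stack(self):
        assert compute_stack_threshold(np.full((3, 8, 8), 100, np.uint8), 2.0) == 100.0

    def test_two_frame_hand_example(self):
        # per-frame SDs 4 and 6, overall median 80, k=2 -> 90
        f1 = np.full((4, 4), 80, float); f1[:2] = 76; f1[2:] = 84
        f2 = np.full((4, 4), 80, float); f2[:2] = 74; f2[2:] = 86
        stack = np.stack([f1, f2])
        assert compute_stack_threshold(stack, 2.0) == pytest.approx(90.0)

    def test_gaussian_background(self):
        rng = np.random.default_rng(0)
        frames = np.clip(rng.normal(200, 5, (4, 200, 200)), 0, 255)
        thr = compute_stack_threshold(np.round(frames).astype(np.uint8), 2.0)
        assert 209 <= thr <= 211

    def test_empty_stack_rejected(self):
        with pytest.raises(InputError):
            compute_stack_threshold(np.empty((0, 4, 4), np.uint8), 2.0)

    @given(
        st.integers(1, 4),
        st.integers(0, 255),
        st.floats(-3, 3),
        st.integers(0, 10_000),
    )
    def test_formula_exactness_against_brute_force(self, n_frames, base, k, seed):
        # median + k * mean(per-frame population SD), checked by plain-python arithmetic
        rng = np.random.default_rng(seed)
        frames = rng.integers(
            max(base - 40, 0), min(base + 40, 255) + 1, size=(n_frames, 6, 6)
        ).astype(np.uint8)
        got = compute_stack_threshold(frames, k)
        all_pixels = sorted(int(v) for f in frames for v in f.ravel())
        med = statistics.median(all_pixels)
        sds = [statistics.pstdev([int(v) for v in f.ravel()]) for f in frames]
        expected = med + k * (sum(sds) / len(sds))
        assert math.isclose(got, expected, abs_tol=1e-9)


class TestShadowRejection:
    def test_clean_stack_keeps_everything(self, tiny_config):
        sim = simulate_window(tiny_config, "high", np.random.default_rng(20))
        cs = extract_channel(sim.stack, "blue")
        retained, rejected = reject_shadow_frames(cs, SegmentationConfig())
        assert rejected == []
        assert retained.n_frames == sim.stack.n_frames

    def test_rejection_covers_injected_shadows(self, tiny_config):
        from matiss.config import ImagingGeometry, SizeModel

        base = tiny_config.with_(
            imaging_high=ImagingGeometry(0.35, (512, 512), (6, 6)),
            size_model_macro=SizeModel("lognormal", 5000.0, 0.2, 1500.0, 20000.0),
        )
        cfg = base.with_(macro_rate=2.0)
        sim = simulate_window(base, "high", np.random.default_rng(21))
        stack, affected, _ = inject_macroscopic_object(
            sim.stack, cfg, np.random.default_rng(22)
        )
        if not affected:
            pytest.skip("no shadowed frame drawn")  # Poisson draw can be empty
        cs = extract_channel(stack, "blue")
        _, rejected = reject_shadow_frames(cs, SegmentationConfig())
        assert set(affected) <= set(rejected)

    def test_fraction_one_never_rejects(self):
        frames = np.full((3, 32, 32), 200, np.uint8)
        frames[0] = 40  # even an all-dark frame survives at the bound
        cfg = SegmentationConfig(reject_dark_fraction=1.0)
        _, rejected = reject_shadow_frames(_channel_stack(frames), cfg)
        assert rejected == []

    def test_all_rejected_is_signalled(self):
        rng = np.random.default_rng(23)
        frames = np.clip(rng.normal(200, 5, (3, 64, 64)), 0, 255).astype(np.uint8)
        frames[:, :, :13] = 10  # every frame carries a 20% shadow band
        with pytest.raises(AllFramesRejectedError):
            reject_shadow_frames(_channel_stack(frames), SegmentationConfig())

    def test_rejection_preserves_retained_pixels(self):
        rng = np.random.default_rng(24)
        frames = np.clip(rng.normal(200, 5, (4, 64, 64)), 0, 255).astype(np.uint8)
        frames[1, :, :] = 20
        cs = _channel_stack(frames)
        retained, rejected = reject_shadow_frames(
            cs, SegmentationConfig(reject_dilate_frames=0)
        )
        assert rejected == [1]
        assert np.array_equal(retained.frames, frames[[0, 2, 3]])


class TestFirstPass:
    def test_blank_frame_empty_table(self):
        frames = np.full((2, 64, 64), 200, np.uint8)
        det = first_pass_segment(_channel_stack(frames), 75.0, SegmentationConfig())
        assert det.empty

    def test_single_disc_centroid_within_one_pixel(self, tiny_config):
        truth = pd.DataFrame(
            [{"id": 0, "x_um": 400.0, "y_um": 700.0, "area_um2": 155.0,
              "shape": "coccus", "size_class": "coarse"}]
        )
        stack = render_window(truth, "low", tiny_config, np.random.default_rng(25))
        cs = extract_channel(stack, "blue")
        det = first_pass_segment(cs, 75.0, SegmentationConfig())
        assert len(det) == 1
        px = tiny_config.imaging_low.pixel_size_um
        assert abs(det.x_um.iloc[0] - 400.0) < px
        assert abs(det.y_um.iloc[0] - 700.0) < px

    def test_corner_touching_discs_connectivity(self):
        img = np.full((32, 32), 200, np.uint8)
        img[8:12, 8:12] = 10   # square A
        img[12:16, 12:16] = 10  # square B touching A corner-to-corner
        cs = _channel_stack(img[None])
        det8 = first_pass_segment(cs, 75.0, SegmentationConfig(connectivity=8))
        det4 = first_pass_segment(cs, 75.0, SegmentationConfig(connectivity=4))
        assert len(det8) == 1
        assert len(det4) == 2

    @given(st.integers(0, 2**31 - 1), st.integers(40, 220))
    def test_threshold_monotonicity(self, seed, thr):
        # raising the threshold never decreases the sub-threshold pixel count
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        assert (img < thr).sum() <= (img < thr + 10).sum()


class TestRefinement:
    def _disc_crop(self, bg=140.0, level=10.0, radius=6.0, size=41, noise=0.0, ramp=0.0):
        rng = np.random.default_rng(26)
        y, x = np.mgrid[0:size, 0:size]
        r = np.hypot(x - size // 2, y - size // 2)
        cov = np.clip(radius + 0.5 - r, 0, 1)
        crop = bg + (level - bg) * cov + ramp * (x - size // 2)
        if noise:
            crop = crop + rng.normal(0, noise, crop.shape)
        return np.clip(crop, 0, 255)

    def test_refined_area_consistent_on_uniform_background(self):
        crop = self._disc_crop(noise=2.0)
        cfg = SegmentationConfig()
        first_mask = crop < 75.0
        ref = refine_particle(crop, cfg, 75.0, first_mask=first_mask)
        assert ref.ok
        first_area = first_mask.sum()
        assert abs(ref.area_px - first_area) / first_area < 0.05

    def test_refinement_beats_global_threshold_on_ramp(self):
        # background ramp drags a tongue of pixels under the global threshold;
        # the crop-local threshold recovers the disc area
        size, radius = 61, 6.0
        y, x = np.mgrid[0:size, 0:size]
        bg = 50.0 + 1.5 * x  # 50 -> 140 across the crop, crosses 75 at x=17
        r = np.hypot(x - 40, y - size // 2)
        cov = np.clip(radius + 0.5 - r, 0, 1)
        crop = np.clip(bg + (10.0 - bg) * cov, 0, 255)
        true_area = np.pi * radius**2
        first_mask = crop < 75.0
        first_area = first_mask.sum()
        assert first_area > 1.2 * true_area  # global threshold fails badly
        ref = refine_particle(
            crop, SegmentationConfig(), 75.0, center_rc=(size // 2, 40),
            first_mask=first_mask,
        )
        assert abs(ref.area_px - true_area) / true_area < 0.10

    def test_circular_mask_elongation_is_one(self):
        ref = refine_particle(self._disc_crop(radius=8.0), SegmentationConfig(), 75.0)
        assert ref.elongation == pytest.approx(1.0, abs=0.05)

    def test_refinement_idempotent(self):
        crop = self._disc_crop(noise=2.0)
        cfg = SegmentationConfig()
        ref1 = refine_particle(crop, cfg, 75.0)
        ref2 = refine_particle(crop, cfg, 75.0,
                               center_rc=tuple(np.round(ref1.centroid_rc).astype(int)))
        assert abs(ref2.area_px - ref1.area_px) < 1

    def test_lost_particle_is_flagged_not_dropped(self):
        flat = np.full((21, 21), 200.0)
        ref = refine_particle(flat, SegmentationConfig(), 190.0)
        assert not ref.ok
        assert ref.area_px == 0


class TestEndToEnd:
    def test_empty_window_empty_table(self, tiny_config):
        cfg = tiny_config.with_(coarse_density=0.0, fine_density=0.0)
        sim = simulate_window(cfg, "high", np.random.default_rng(27))
        det, log = run_segmentation(sim.stack)
        assert det.empty
        assert log["n_detections"] == 0

    def test_same_stack_twice_identical(self, tiny_config):
        sim = simulate_window(tiny_config, "high", np.random.default_rng(28))
        det1, _ = run_segmentation(sim.stack)
        det2, _ = run_segmentation(sim.stack)
        pd.testing.assert_frame_equal(det1, det2)

    def test_log_reports_stage_counts(self, tiny_config):
        sim = simulate_window(tiny_config, "high", np.random.default_rng(29))
        det, log = run_segmentation(sim.stack)
        assert log["n_frames"] == sim.stack.n_frames
        assert log["n_detections"] == len(det)
        assert log["retained_area_mm2"] > 0


class TestMatching:
    def _truth(self, xy):
        return pd.DataFrame(
            {"id": range(len(xy)), "x_um": [p[0] for p in xy],
             "y_um": [p[1] for p in xy], "area_um2": 10.0}
        )

    def test_perfect_detection(self):
        truth = self._truth([(10, 10), (50, 50)])
        det = truth.rename(columns={})[["x_um", "y_um", "area_um2"]]
        res = match_detections(truth, det, radius_um=2.0)
        assert res.precision == 1.0 and res.recall == 1.0

    def test_no_detections_zero_recall(self):
        truth = self._truth([(10, 10)])
        det = pd.DataFrame(columns=["x_um", "y_um", "area_um2"])
        res = match_detections(truth, det, radius_um=2.0)
        assert res.recall == 0.0

    def test_shifted_past_radius_unmatched(self):
        truth = self._truth([(10, 10), (50, 50)])
        det = truth[["x_um", "y_um", "area_um2"]].copy()
        det["x_um"] += 5.0
        res = match_detections(truth, det, radius_um=5.0)  # shift is exactly radius
        assert res.n_matched == 0

    def test_one_to_one_greedy(self):
        truth = self._truth([(0, 0)])
        det = pd.DataFrame({"x_um": [0.5, 0.1], "y_um": [0.0, 0.0], "area_um2": 10.0})
        res = match_detections(truth, det, radius_um=2.0)
        assert res.n_matched == 1
        assert res.matches.det_index.iloc[0] == 1  # nearest wins
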