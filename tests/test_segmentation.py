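"""Segmentation: normalization stats, shape contract, training behaviour,
IoU and the report score."""

import numpy as np
import pytest

from fundusfocus import generate_fundus
from fundusfocus.exceptions import (
    DegenerateStatsError,
    MaskValidationError,
    ParameterError,
    ShapeMismatchError,
)
from fundusfocus.fusion import FundusImage
from fundusfocus.segmentation import (
    NormalizationStats,
    SegTrainConfig,
    SegmentationModelSpec,
    SegmentationSample,
    build_retina_unet,
    compute_iou,
    compute_lesion_score,
    compute_normalization_stats,
    normalize_image,
    predict_mask,
    resize_mask,
    split_train_val,
    train_segmentation,
)
from fundusfocus.synthetic import SyntheticFundusConfig


def const_image(value, h=8, w=8):
    return FundusImage(pixels=np.full((h, w, 3), value, np.uint8))


class TestNormalizationStats:
    def test_constant_dataset_raises_degenerate_error(self):
        with pytest.raises(DegenerateStatsError):
            compute_normalization_stats([const_image(7)])

    def test_two_constant_images_closed_form(self):
        stats = compute_normalization_stats([const_image(10), const_image(30)])
        assert stats.mean == pytest.approx((20.0, 20.0, 20.0))
        assert stats.std == pytest.approx((10.0, 10.0, 10.0))

    def test_matches_two_pass_naive_loop_to_8_decimals(self):
        rng = np.random.default_rng(0)
        imgs = [rng.integers(0, 256, (5, 4, 3)).astype(np.uint8) for _ in range(3)]
        stats = compute_normalization_stats(imgs)
        # naive per-pixel loop
        for c in range(3):
            vals = [float(im[y, x, c]) for im in imgs for y in range(5) for x in range(4)]
            mean = sum(vals) / len(vals)
            rms = (sum((v - mean) ** 2 for v in vals) / len(vals)) ** 0.5
            assert stats.mean[c] == pytest.approx(mean, abs=1e-8)
            assert stats.std[c] == pytest.approx(rms, abs=1e-8)

    def test_zero_std_rejected_at_construction(self):
        with pytest.raises(DegenerateStatsError):
            NormalizationStats(mean=(0, 0, 0), std=(1, 0, 1))


class TestNormalizeImage:
    def test_image_equal_to_mean_maps_to_zero(self):
        stats = NormalizationStats(mean=(10, 10, 10), std=(2, 2, 2))
        out = normalize_image(const_image(10, 16, 16), stats, size=16)
        assert np.allclose(out, 0.0)

    def test_unit_stats_identity_without_resize(self):
        stats = NormalizationStats(mean=(0, 0, 0), std=(1, 1, 1))
        img = const_image(37, 16, 16)
        out = normalize_image(img, stats, size=16)
        assert np.allclose(out, 37.0)

    def test_single_pixel_hand_arithmetic(self):
        stats = NormalizationStats(mean=(100, 50, 25), std=(50, 25, 5))
        px = np.zeros((16, 16, 3), np.uint8)
        px[3, 4] = (200, 100, 30)
        out = normalize_image(FundusImage(pixels=px), stats, size=16)
        assert out[3, 4] == pytest.approx([2.0, 2.0, 1.0], abs=1e-6)


class TestShapeContract:
    def test_quarter_width_shapes_scale_channels_only(self):
        spec = SegmentationModelSpec(width_multiplier=0.25, input_size=256)
        model = build_retina_unet(spec, seed=0)
        model.forward(np.zeros((1, 3, 256, 256), np.float32), train=False)
        s = model.checkpoint_shapes
        assert s["stem"] == (16, 128, 128)
        assert s["pooled"] == (16, 64, 64)
        assert s["encoder_out"] == (128, 8, 8)
        assert s["decoder_first"] == (64, 16, 16)
        assert s["decoder_last"] == (4, 256, 256)
        assert s["head"] == (1, 256, 256)

    def test_output_is_probability_for_zero_input(self):
        spec = SegmentationModelSpec(width_multiplier=0.125, input_size=64)
        model = build_retina_unet(spec, seed=0)
        out = model.forward(np.zeros((2, 3, 64, 64), np.float32), train=False)
        assert out.shape == (2, 1, 64, 64)
        assert np.isfinite(out).all() and (out >= 0).all() and (out <= 1).all()

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ParameterError):
            SegmentationModelSpec(width_multiplier=1.5)


class TestIoU:
    def test_identical_masks_give_one(self):
        m = np.eye(4, dtype=np.uint8)
        assert compute_iou(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.array([[1, 0], [0, 0]])
        b = np.array([[0, 0], [0, 1]])
        assert compute_iou(a, b) == 0.0

    def test_partial_overlap_counting_oracle(self):
        a = np.array([[1, 1]])
        b = np.array([[0, 1]])
        # union has 2 pixels, intersection 1
        assert compute_iou(a, b) == pytest.approx(1 / 2)
        a2 = np.array([[1, 1], [0, 0]])
        b2 = np.array([[0, 1], [1, 0]])
        assert compute_iou(a2, b2) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3))
        assert compute_iou(z, z) == 1.0

    def test_symmetry_on_random_masks(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.integers(0, 2, (6, 6))
            b = rng.integers(0, 2, (6, 6))
            assert compute_iou(a, b) == compute_iou(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            compute_iou(np.zeros((2, 2)), np.zeros((3, 3)))


class TestLesionScore:
    @pytest.mark.parametrize(
        "tr, va, expected",
        [(0.944777, 0.668727, 0.779147), (0.697246, 0.420536, 0.531220)],
    )
    def test_reference_report_cells(self, tr, va, expected):
        assert compute_lesion_score(tr, va) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("x", [0.0, 0.25, 0.5, 0.987654, 1.0])
    def test_convex_combination_fixed_point(self, x):
        assert compute_lesion_score(x, x) == pytest.approx(x, abs=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            compute_lesion_score(1.2, 0.5)


def make_disc_samples(n, size=64, seed=100):
    cfg = SyntheticFundusConfig(size=size)
    samples = []
    for i in range(n):
        img, stack = generate_fundus(cfg, seed=seed + i)
        img.patient_id = f"P{i}"
        samples.append(
            SegmentationSample(
                image=img, target=stack.plane("optic disc"), patient_id=f"P{i}"
            )
        )
    return samples


class TestTraining:
    def test_patient_disjoint_split(self):
        samples = make_disc_samples(20, size=64)
        train, val = split_train_val(samples, seed=0)
        assert not ({s.patient_id for s in train} & {s.patient_id for s in val})
        assert len(val) == 4

    def test_refuses_all_negative_dataset(self):
        samples = make_disc_samples(5, size=64)
        for s in samples:
            s.target = np.zeros_like(s.target)
        spec = SegmentationModelSpec(
            target_class="drusen", input_size=64, width_multiplier=0.125
        )
        with pytest.raises(MaskValidationError, match="drusen"):
            train_segmentation(
                build_retina_unet(spec), samples, SegTrainConfig(max_epochs=1)
            )

    def test_same_seed_reproduces_loss_log(self):
        samples = make_disc_samples(10, size=64)
        logs = []
        for _ in range(2):
            spec = SegmentationModelSpec(input_size=64, width_multiplier=0.1)
            model = build_retina_unet(spec, seed=3)
            _, log = train_segmentation(
                model, samples, SegTrainConfig(seed=5, max_epochs=2, batch_size=4)
            )
            logs.append(log)
        assert logs[0] == logs[1]

    def test_recovers_bright_disc_and_fails_null_control(self):
        """The disc task is learnable (val IoU >= 0.7); with targets
        statistically independent of the images (random-position disks),
        validation IoU collapses toward the foreground prevalence."""
        from skimage.draw import disk as draw_disk

        samples = make_disc_samples(50, size=64)
        spec = SegmentationModelSpec(
            target_class="optic disc", input_size=64, width_multiplier=0.125
        )
        model = build_retina_unet(spec, seed=0)
        stats = compute_normalization_stats([s.image for s in samples])
        model, _ = train_segmentation(
            model, samples, SegTrainConfig(seed=0, max_epochs=40, patience=8),
            stats=stats,
        )
        _, val = split_train_val(samples, seed=0)
        ious = [
            compute_iou(
                predict_mask(model, s.image, stats), resize_mask(s.target, 64)
            )
            for s in val
        ]
        assert np.mean(ious) >= 0.7

        rng = np.random.default_rng(12)
        null_samples = []
        for s in samples:
            target = np.zeros((64, 64), np.uint8)
            rr, cc = draw_disk(
                (rng.integers(12, 52), rng.integers(12, 52)), 7, shape=(64, 64)
            )
            target[rr, cc] = 1
            null_samples.append(
                SegmentationSample(
                    image=s.image, target=target, patient_id=s.patient_id
                )
            )
        null_model = build_retina_unet(spec, seed=0)
        null_model, _ = train_segmentation(
            null_model,
            null_samples,
            SegTrainConfig(seed=0, max_epochs=15, patience=5),
            stats=stats,
        )
        _, nval = split_train_val(null_samples, seed=0)
        null_ious = [
            compute_iou(
                predict_mask(null_model, s.image, stats), resize_mask(s.target, 64)
            )
            for s in nval
        ]
        # prevalence of a radius-7 disk in a 64x64 frame is ~3.7%
        assert np.mean(null_ious) < 0.3
        assert np.mean(null_ious) < np.mean(ious)
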