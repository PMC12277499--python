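"""Segmentation backend: preprocessing, augmentation, architecture shape,
training dynamics and evaluation."""

import numpy as np
import pytest

import petquant as pq
from petquant.grids import BinaryMask, ScalarVolume, VolumeGrid
from petquant.segmentation import (
    IntensityAtlasBaseline,
    SegmentationConfig,
    build_model,
    desk_config,
    evaluate,
    evaluate_label_volumes,
    preprocess_ct,
    train,
)
from petquant.segmentation.data import make_phantom_dataset
from petquant.segmentation.preprocess import augment


@pytest.fixture(scope="module")
def tiny_config():
    return desk_config(seed=0)


@pytest.fixture(scope="module")
def tiny_dataset(tiny_config):
    return make_phantom_dataset(3, tiny_config, seed=7)


@pytest.fixture(scope="module")
def tiny_model(tiny_config):
    return build_model(tiny_config)


# ------------------------------------------------------------- preprocessing


@pytest.mark.parametrize("hu, expected", [(-175.0, 0.0), (250.0, 1.0), (37.5, 0.5), (-500.0, 0.0), (900.0, 1.0)])
def test_hu_window_normalization(hu, expected, tiny_config):
    grid = VolumeGrid((8, 8, 8), tuple(tiny_config.target_spacing))
    ct = ScalarVolume(grid, np.full(grid.dims, hu), "CT")
    out = preprocess_ct(ct, tiny_config)
    assert out.values == pytest.approx(expected)


def test_preprocess_resamples_to_target_spacing():
    cfg = SegmentationConfig()  # 1.5 x 1.5 x 2.0 mm
    grid = VolumeGrid((16, 16, 16), (3.0, 3.0, 4.0))
    ct = ScalarVolume(grid, np.zeros(grid.dims), "CT")
    out = preprocess_ct(ct, cfg)
    assert out.grid.spacing == pytest.approx(cfg.target_spacing)
    assert out.grid.dims == (32, 32, 32)  # same physical extent


# -------------------------------------------------------------- augmentation


def test_augment_with_zero_probabilities_is_identity(tiny_dataset):
    vol, lab = tiny_dataset[0]
    cfg = desk_config(flip_prob=0.0, rotate_prob=0.0, intensity_shift_prob=0.0)
    v2, l2 = augment(vol, lab, cfg, seed=3)
    assert np.array_equal(v2, vol) and np.array_equal(l2, lab)


def test_forced_flip_twice_is_identity(tiny_dataset):
    vol, lab = tiny_dataset[0]
    cfg = desk_config(flip_prob=0.0, rotate_prob=0.0, intensity_shift_prob=0.0)
    v1, l1 = augment(vol, lab, cfg, seed=0, force_flip_axes=(1,))
    v2, l2 = augment(v1, l1, cfg, seed=0, force_flip_axes=(1,))
    assert np.array_equal(v2, vol) and np.array_equal(l2, lab)


def test_augment_preserves_voxelwise_correspondence(tiny_dataset):
    """Rotation/flip move volume and labels identically: the set of (value,
    label) pairs is preserved voxel for voxel."""
    vol, lab = tiny_dataset[0]
    cfg = desk_config(intensity_shift_prob=0.0)
    v2, l2 = augment(vol, lab, cfg, seed=5, force_flip_axes=(0,), force_rotate_axes=(2,))
    for cls in range(6):
        assert sorted(v2[l2 == cls]) == pytest.approx(sorted(vol[lab == cls]))


def test_augment_deterministic_per_seed(tiny_dataset):
    vol, lab = tiny_dataset[0]
    cfg = desk_config()
    out1 = augment(vol, lab, cfg, seed=9)
    out2 = augment(vol, lab, cfg, seed=9)
    assert np.array_equal(out1[0], out2[0]) and np.array_equal(out1[1], out2[1])


def test_intensity_shift_touches_volume_only(tiny_dataset):
    vol, lab = tiny_dataset[0]
    cfg = desk_config(flip_prob=0.0, rotate_prob=0.0, intensity_shift_prob=1.0)
    v2, l2 = augment(vol, lab, cfg, seed=1)
    assert np.array_equal(l2, lab)
    shift = np.unique(np.round(v2 - vol, 12))
    assert len(shift) == 1 and abs(shift[0]) <= cfg.intensity_shift_offset


# ----------------------------------------------------------------- the model


def test_stage_resolutions_halve_and_channels_double(tiny_model):
    rows = tiny_model.describe()
    res = [r["token_resolution"] for r in rows]
    ch = [r["channels"] for r in rows]
    assert res == [16, 8, 4, 2, 1]
    assert ch == [12, 24, 48, 96, 192]
    default = build_model(SegmentationConfig())
    assert [r["channels"] for r in default.describe()] == [48, 96, 192, 384, 768]


def test_forward_shape_and_softmax_validity(tiny_model, tiny_dataset):
    x = tiny_dataset[0][0]
    probs = tiny_model.forward(x)
    assert probs.shape == x.shape + (6,)
    assert np.abs(probs.sum(axis=-1) - 1.0).max() < 1e-6
    assert np.isfinite(probs).all()


def test_features_deterministic_per_seed(tiny_config, tiny_dataset):
    x = tiny_dataset[0][0]
    a = build_model(tiny_config).forward_features(x)
    b = build_model(tiny_config).forward_features(x)
    c = build_model(desk_config(seed=1)).forward_features(x)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_incompatible_input_shape_names_constraint(tiny_model):
    with pytest.raises(ValueError, match="patch_size"):
        tiny_model.forward(np.zeros((30, 30, 30)))


def test_incompatible_crop_config_rejected():
    with pytest.raises(ValueError, match="divisible"):
        SegmentationConfig(crop_size=50)


# ------------------------------------------------------------------ training


def test_zero_iterations_leave_model_unchanged(tiny_config, tiny_dataset):
    model = build_model(tiny_config)
    before = model.head_W.copy()
    hist = train(model, tiny_dataset, desk_config(iterations=0))
    assert np.array_equal(model.head_W, before)
    assert hist.loss == []


def test_empty_dataset_rejected(tiny_model, tiny_config):
    with pytest.raises(ValueError, match="empty"):
        train(tiny_model, [], tiny_config)


def test_overfit_three_phantoms(tiny_config, tiny_dataset):
    """Readout training on three phantoms reaches mean foreground dice >= 0.95
    within 300 iterations, with a non-increasing smoothed loss curve."""
    model = build_model(tiny_config)
    hist = train(model, tiny_dataset, tiny_config)
    assert len(hist.loss) == 300
    assert hist.dice[-1] >= 0.95
    window = 20
    ma = np.convolve(hist.loss, np.ones(window) / window, mode="valid")
    assert np.all(np.diff(ma) <= 1e-6)


def test_atlas_baseline_separates_phantom_organs(tiny_dataset):
    baseline = IntensityAtlasBaseline(n_classes=6).fit(tiny_dataset)
    vol, lab = tiny_dataset[0]
    score = evaluate_label_volumes(baseline.predict_labels(vol), lab, n_classes=6)
    assert score > 0.6  # left/right breasts share intensity; atlas cannot split them


# ---------------------------------------------------------------- evaluation


def test_evaluate_oracle_cases():
    grid = VolumeGrid((8, 8, 8), (1.0, 1.0, 1.0))

    def cube(lo, hi):
        v = np.zeros(grid.dims, bool)
        v[lo:hi, lo:hi, lo:hi] = True
        return BinaryMask(grid, v)

    full = {"a": cube(0, 4), "b": cube(4, 8)}
    assert evaluate(full, full) == 1.0
    empty = {"a": cube(0, 0), "b": cube(0, 0)}
    assert evaluate(empty, full) == 0.0
    # half-overlap construction on one organ, perfect on the other
    v = np.zeros(grid.dims, bool)
    v[0:4, 0:4, 2:6] = True
    half = {"a": BinaryMask(grid, v), "b": cube(4, 8)}
    assert evaluate(half, full) == pytest.approx((0.5 + 1.0) / 2)


def test_evaluate_requires_matching_organ_sets():
    grid = VolumeGrid((4, 4, 4), (1.0, 1.0, 1.0))
    m = BinaryMask(grid, np.ones(grid.dims, bool))
    with pytest.raises(ValueError, match="differ"):
        evaluate({"a": m}, {"b": m})
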