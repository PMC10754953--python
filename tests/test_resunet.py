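"""Residual U-Net: architecture contracts, loss, sampling and training."""

import numpy as np
import pytest

from vemseg.nn.tensor import Tensor
from vemseg.phantom import make_sparse_labels
from vemseg.resunet import (ModelSpec, TrainConfig, build_model, dice_loss,
                            load_checkpoint, sample_batch, save_checkpoint, train)
from vemseg.stack_io import SparseLabelSet, equalize_stack


def test_forward_shape_and_probability_range():
    model = build_model(ModelSpec(base_filters=2, in_size=(64, 64)), seed=0)
    rng = np.random.default_rng(0)
    out = model.forward(Tensor(rng.normal(size=(2, 1, 64, 64)).astype(np.float32)))
    assert out.shape == (2, 1, 64, 64)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0
    # arbitrary (large) inputs still map into [0,1]
    wild = model.forward(Tensor((1000 * rng.normal(size=(1, 1, 64, 64))).astype(np.float32)))
    assert wild.data.min() >= 0.0 and wild.data.max() <= 1.0


def test_bridge_resolution_is_one_sixteenth():
    model = build_model(ModelSpec(base_filters=1, in_size=(512, 512)), seed=0)
    br = model.bridge_features(Tensor(np.zeros((1, 1, 512, 512), np.float32)))
    assert br.shape[2:] == (32, 32)


def test_in_size_divisibility_enforced():
    with pytest.raises(ValueError):
        build_model(ModelSpec(base_filters=2, in_size=(100, 100)))


def test_parameter_count_scales_quadratically_with_width():
    n8 = build_model(ModelSpec(base_filters=8, in_size=(64, 64))).parameter_count()
    n16 = build_model(ModelSpec(base_filters=16, in_size=(64, 64))).parameter_count()
    assert 3.5 < n16 / n8 < 4.5  # conv-dominated


def test_dual_head_output():
    model = build_model(ModelSpec(base_filters=2, in_size=(32, 32), heads=2), seed=0)
    out = model.forward(Tensor(np.zeros((1, 1, 32, 32), np.float32)))
    assert out.shape == (1, 2, 32, 32)


def test_dice_loss_closed_forms():
    rng = np.random.default_rng(0)
    target = (rng.random((2, 1, 16, 16)) > 0.5).astype(np.float32)
    eps = 1.0
    perfect = dice_loss(Tensor(target), target)
    assert float(perfect.data) <= eps / (target.sum() + eps)
    inverted = dice_loss(Tensor(1.0 - target), target)
    assert float(inverted.data) > 0.99 - eps / target.size
    # uniform 0.5 prediction on a half-foreground target: soft Dice with the
    # squared denominator gives (2*0.25N + eps)/(0.75N + eps)
    n = 16 * 16
    half = np.zeros((1, 1, 16, 16), np.float32)
    half[..., :8, :] = 1.0
    got = float(dice_loss(Tensor(np.full_like(half, 0.5)), half).data)
    expect = 1.0 - (2 * 0.25 * n + eps) / (0.75 * n + eps)
    assert got == pytest.approx(expect, abs=1e-6)
    assert abs(expect - 1 / 3) < 0.01


def _fake_nucleolus_labels(rng, n_slices=6, hw=128, blob=12):
    labels = {}
    for z in range(n_slices):
        img = np.zeros((hw, hw), dtype=np.uint16)
        for _ in range(3):
            r, c = rng.integers(0, hw - blob, 2)
            img[r:r + blob, c:c + blob] = 1  # 144 px ≥ the 100 px constraint
        labels[z] = img
    return SparseLabelSet(slice_indices=list(range(n_slices)), labels=labels,
                          class_name="nucleolus")


def test_nucleolus_batch_constraint_holds_over_many_batches():
    rng = np.random.default_rng(5)
    labels = _fake_nucleolus_labels(rng)
    images = rng.integers(0, 255, size=(6, 128, 128)).astype(np.uint8)
    cfg = TrainConfig(tile_px=64, context_px=64, batch_size=5,
                      nucleolus_min_px=100, nucleolus_min_tiles=4)
    for _ in range(200):
        tiles, targets = sample_batch(images, labels, cfg, rng)
        assert tiles.shape == (5, 1, 64, 64)
        rich = sum(int(t.sum()) >= 100 for t in targets[:, 0])
        assert rich >= 4


def test_nucleolus_constraint_unsatisfiable_raises():
    rng = np.random.default_rng(6)
    labels = _fake_nucleolus_labels(rng, blob=4)  # 16 px blobs: constraint can fail
    labels = SparseLabelSet(slice_indices=[0],
                            labels={0: np.zeros((128, 128), np.uint16)},
                            class_name="nucleolus")
    images = np.zeros((1, 128, 128), np.uint8)
    cfg = TrainConfig(tile_px=64, context_px=64)
    with pytest.raises(RuntimeError, match="nucleolus_min_px"):
        sample_batch(images, labels, cfg, rng)


def test_sample_batch_deterministic_under_seed():
    rng_a = np.random.default_rng(7)
    rng_b = np.random.default_rng(7)
    labels = _fake_nucleolus_labels(np.random.default_rng(1))
    images = np.random.default_rng(2).integers(0, 255, (6, 128, 128)).astype(np.uint8)
    cfg = TrainConfig(tile_px=64, context_px=64)
    for _ in range(5):
        ta, ya = sample_batch(images, labels, cfg, rng_a)
        tb, yb = sample_batch(images, labels, cfg, rng_b)
        assert np.array_equal(ta, tb) and np.array_equal(ya, yb)


def test_context_downsampling_tile_geometry():
    rng = np.random.default_rng(8)
    labels = _fake_nucleolus_labels(rng, hw=256)
    images = rng.integers(0, 255, (6, 256, 256)).astype(np.uint8)
    cfg = TrainConfig(tile_px=64, context_px=256)  # 4x context, downsampled
    tiles, targets = sample_batch(images, labels, cfg, rng)
    assert tiles.shape == (5, 1, 64, 64) and targets.shape == (5, 1, 64, 64)


def test_train_zero_updates_keeps_weights(phantom_small):
    _, stack, truth = phantom_small
    labels = make_sparse_labels(truth, 16, class_name="nucleus")
    model = build_model(ModelSpec(base_filters=2, in_size=(64, 64)), seed=3)
    before = [p.data.copy() for p in model.parameters()]
    model, trace = train(model, stack.voxels, labels,
                         TrainConfig(updates=0, tile_px=64, context_px=64))
    assert trace["raw"] == []
    for p, b in zip(model.parameters(), before):
        assert np.array_equal(p.data, b)


def test_training_descends_on_phantom_nucleus(phantom_small):
    _, stack, truth = phantom_small
    eq = equalize_stack(stack)
    labels = make_sparse_labels(truth, 16, class_name="nucleus")
    cfg = TrainConfig(updates=50, tile_px=64, context_px=64, seed=0)
    model = build_model(ModelSpec(base_filters=4, in_size=(64, 64)), seed=0)
    model, trace = train(model, eq.voxels, labels, cfg)
    assert len(trace["raw"]) == 50
    assert trace["smoothed"][-1] < trace["raw"][0]


def test_checkpoint_round_trip_bit_identical(tmp_path, phantom_small):
    _, stack, _ = phantom_small
    model = build_model(ModelSpec(base_filters=2, in_size=(64, 64)), seed=9)
    tile = stack.voxels[10, :64, :64]
    before = model.predict(tile)
    save_checkpoint(model, tmp_path / "m.npz", TrainConfig())
    reloaded = load_checkpoint(tmp_path / "m.npz")
    after = reloaded.predict(tile)
    assert np.array_equal(before, after)


def test_flip_equivariance_of_flip_augmented_training(phantom_small):
    """A model trained with flip augmentation should respond consistently to
    flipped inputs (loose smoke test, not exact symmetry)."""
    _, stack, truth = phantom_small
    eq = equalize_stack(stack)
    labels = make_sparse_labels(truth, 16, class_name="nucleus")
    cfg = TrainConfig(updates=120, tile_px=64, context_px=64, seed=1)
    model = build_model(ModelSpec(base_filters=4, in_size=(64, 64)), seed=1)
    model, _ = train(model, eq.voxels, labels, cfg)
    tile = eq.voxels[32, 32:96, 32:96]
    p = model.predict(tile)[0]
    p_flip = model.predict(tile[::-1].copy())[0][::-1]
    agree = np.mean((p >= 0.5) == (p_flip >= 0.5))
    assert agree > 0.9
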