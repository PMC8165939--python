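import numpy as np
import pytest

import deltasphere as ds
from deltasphere.classification import (
    AugmentConfig,
    CropDataset,
    CropSpec,
    ModelConfig,
    SplitSpec,
    augment,
    crop_on_centroid,
    load_model,
    save_model,
)
from deltasphere.delta import SpheroidMask


def _mask_at(cr, cc, shape=(64, 64)):
    arr = np.zeros(shape, dtype=bool)
    arr[cr, cc] = True
    return SpheroidMask(mask=arr, timepoint=2, centroid=(float(cr), float(cc)), area_px=1, empty=False)


def _separable_dataset(n=200, size=48, n_wells=10, seed=0):
    """Bright disk vs bright cross: classes separable by construction."""
    rng = np.random.default_rng(seed)
    imgs, labels, wells, tps = [], [], [], []
    for i in range(n):
        im = np.zeros((size, size), np.float32)
        if i % 2 == 0:
            rr, cc = np.mgrid[0:size, 0:size]
            im[(rr - size // 2) ** 2 + (cc - size // 2) ** 2 <= (size // 5) ** 2] = 1.0
        else:
            b = size // 2
            im[b - 4 : b + 4, :] = 1.0
            im[:, b - 4 : b + 4] = 1.0
        imgs.append(im + rng.normal(0, 0.05, (size, size)).astype(np.float32))
        labels.append(i % 2)
        wells.append(f"W{i % n_wells:02d}")
        tps.append(i // n_wells + 2)
    return CropDataset(
        images=np.stack(imgs),
        labels=np.array(labels),
        wells=np.array(wells),
        timepoints=np.array(tps),
        classes=["disk", "cross"],
    )


class TestCropOnCentroid:
    def test_interior_crop_is_pure_subwindow(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 255, (100, 100), dtype=np.uint8)
        spec = CropSpec(output_size=40)
        out = crop_on_centroid(frame, _mask_at(50, 50, (100, 100)), spec)
        assert out.shape == (40, 40)
        assert np.allclose(out, frame[30:70, 30:70] / 255.0)

    def test_near_edge_crop_pads_left_columns(self):
        frame = np.full((100, 100), 200, dtype=np.uint8)
        spec = CropSpec(output_size=64, pad_value=0.0)
        out = crop_on_centroid(frame, _mask_at(50, 5, (100, 100)), spec)
        assert (out[:, :27] == 0.0).all()  # columns left of the frame edge
        assert np.allclose(out[:, 27:], 200 / 255.0)

    def test_constant_frame_rescaled_by_dtype_range(self):
        frame = np.full((80, 80), 51, dtype=np.uint8)
        out = crop_on_centroid(frame, _mask_at(40, 40, (80, 80)), CropSpec(output_size=32))
        assert np.allclose(out, 51 / 255.0)

    def test_empty_mask_falls_back_to_centre(self):
        frame = np.zeros((60, 60), np.uint8)
        frame[30, 30] = 255
        m = SpheroidMask(mask=np.zeros((60, 60), bool), timepoint=2, centroid=None, area_px=0, empty=True)
        out = crop_on_centroid(frame, m, CropSpec(output_size=32))
        assert out[16, 16] > 0.99

    def test_too_small_output_rejected(self):
        with pytest.raises(ValueError, match="32"):
            CropSpec(output_size=16)


class TestSplitByWell:
    def _layout(self, n_per_group=9):
        conds = {f"R{i:02d}": "round" for i in range(n_per_group)}
        conds.update({f"B{i:02d}": "branched" for i in range(n_per_group)})
        return ds.PlateLayout(conds)

    def _dataset(self, layout, tps=5):
        wells = sorted(layout.wells)
        n = len(wells) * tps
        return CropDataset(
            images=np.zeros((n, 8, 8), np.float32),
            labels=np.array([0 if layout.condition_of(w) == "round" else 1 for w in wells for _ in range(tps)]),
            wells=np.array([w for w in wells for _ in range(tps)]),
            timepoints=np.array([t + 2 for _ in wells for t in range(tps)]),
            classes=["round", "branched"],
        )

    def test_holds_out_complete_wells(self):
        layout = self._layout()
        dataset = self._dataset(layout)
        train, eval_ = ds.split_by_well(dataset, layout, SplitSpec(4, seed=0))
        eval_wells = set(eval_.wells.tolist())
        assert len(eval_wells) == 8
        assert sum(w.startswith("R") for w in eval_wells) == 4
        # every held-out well brings all of its timepoints
        assert len(eval_) == 8 * 5

    def test_disjoint_and_deterministic(self):
        layout = self._layout()
        dataset = self._dataset(layout)
        a_train, a_eval = ds.split_by_well(dataset, layout, SplitSpec(4, seed=7))
        b_train, b_eval = ds.split_by_well(dataset, layout, SplitSpec(4, seed=7))
        assert set(a_train.wells) & set(a_eval.wells) == set()
        assert set(a_eval.wells) == set(b_eval.wells)

    def test_too_few_wells_rejected(self):
        layout = self._layout(n_per_group=4)
        dataset = self._dataset(layout)
        with pytest.raises(ValueError, match="hold out"):
            ds.split_by_well(dataset, layout, SplitSpec(4, seed=0))


class TestAugment:
    def test_disabled_is_identity(self):
        rng = np.random.default_rng(0)
        im = rng.normal(size=(32, 32)).astype(np.float32)
        out = augment(im, rng, AugmentConfig(flip=False, random_crop=False))
        assert np.array_equal(out, im)

    def test_flip_is_involution(self):
        rng = np.random.default_rng(1)
        im = rng.normal(size=(16, 16)).astype(np.float32)
        assert np.array_equal(im[:, ::-1][:, ::-1], im)
        assert np.array_equal(im[::-1, :][::-1, :], im)

    def test_flip_only_output_is_a_flip_variant(self):
        rng = np.random.default_rng(2)
        im = rng.normal(size=(16, 16)).astype(np.float32)
        out = augment(im, np.random.default_rng(3), AugmentConfig(flip=True, random_crop=False))
        variants = [im, im[:, ::-1], im[::-1, :], im[::-1, ::-1]]
        assert any(np.array_equal(out, v) for v in variants)

    @pytest.mark.parametrize("cfg", [AugmentConfig(), AugmentConfig(flip=False), AugmentConfig(random_crop=False)])
    def test_shape_preserved(self, cfg):
        rng = np.random.default_rng(4)
        im = rng.normal(size=(48, 48)).astype(np.float32)
        assert augment(im, rng, cfg).shape == im.shape


@pytest.fixture(scope="module")
def fitted():
    dataset = _separable_dataset()
    layout = ds.PlateLayout(
        {f"W{i:02d}": ("disk" if i % 2 == 0 else "cross") for i in range(10)}
    )
    train_ds, eval_ds = ds.split_by_well(dataset, layout, SplitSpec(2, seed=0))
    model, ckpts = ds.train(train_ds, ModelConfig(epochs=5, seed=1, input_size=48))
    return model, ckpts, train_ds, eval_ds


class TestTrainEvaluate:
    def test_separable_fixture_learned(self, fitted):
        model, _, train_ds, _ = fitted
        probs = model.predict_proba(train_ds.images)
        assert (probs.argmax(1) == train_ds.labels).mean() >= 0.95

    def test_softmax_outputs_sum_to_one(self, fitted):
        model, _, _, eval_ds = fitted
        probs = model.predict_proba(eval_ds.images)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all() and (probs <= 1).all()

    def test_first_batch_loss_near_ln2(self):
        from deltasphere._nn import SmallCNN

        dataset = _separable_dataset(seed=5)
        net = SmallCNN(n_classes=2, seed=0)
        probs = net.forward(dataset.images[:32, None, :, :], train=False)
        y = dataset.labels[:32]
        loss = -np.log(probs[np.arange(32), y]).mean()
        assert loss == pytest.approx(np.log(2), abs=0.15)

    def test_same_seed_identical_weights(self):
        dataset = _separable_dataset(n=60)
        cfg = ModelConfig(epochs=1, seed=3, input_size=48)
        m1, _ = ds.train(dataset, cfg)
        m2, _ = ds.train(dataset, cfg)
        for k, v in m1.net.parameters().items():
            assert np.array_equal(v, m2.net.parameters()[k])

    def test_single_class_rejected(self):
        dataset = _separable_dataset(n=40)
        sub = dataset.subset(np.where(dataset.labels == 0)[0])
        with pytest.raises(ValueError, match="single class"):
            ds.train(sub, ModelConfig(epochs=1, input_size=48))

    def test_checkpoints_recorded(self):
        dataset = _separable_dataset(n=64)
        _, ckpts = ds.train(dataset, ModelConfig(epochs=2, checkpoint_every=2, input_size=48))
        steps = [s for s, _ in ckpts]
        assert steps == sorted(steps) and len(ckpts) >= 2

    def test_evaluate_on_good_model_scores_high(self, fitted):
        model, _, _, eval_ds = fitted
        preds, curve = ds.evaluate(model, eval_ds)
        assert (curve.accuracy >= 0).all() and (curve.accuracy <= 1).all()
        assert curve.accuracy.mean() >= 0.9  # held-out wells, same distribution
        assert len(preds) == len(eval_ds)

    def test_evaluate_rejects_train_eval_overlap(self, fitted):
        model, _, train_ds, _ = fitted
        with pytest.raises(ValueError, match="overlap"):
            ds.evaluate(model, train_ds)

    def test_label_permuted_eval_sits_at_chance(self, fitted):
        from scipy.stats import binom

        model, _, _, eval_ds = fitted
        rng = np.random.default_rng(0)
        permuted = CropDataset(
            images=eval_ds.images,
            labels=rng.permutation(eval_ds.labels),
            wells=eval_ds.wells,
            timepoints=eval_ds.timepoints,
            classes=eval_ds.classes,
        )
        _, curve = ds.evaluate(model, permuted)
        n = (eval_ds.timepoints == eval_ds.timepoints[0]).sum()
        lo, hi = binom.interval(0.95, int(n), 0.5)
        assert lo / n <= curve.accuracy.mean() <= hi / n

    def test_rolling_mean_of_constant_curve(self):
        curve = ds.AccuracyCurve(timepoints=np.arange(2, 30), accuracy=np.full(28, 0.75))
        assert np.allclose(curve.rolling, 0.75)
        assert len(curve.rolling) == 28

    def test_save_load_round_trip(self, fitted, tmp_path):
        model, _, _, eval_ds = fitted
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert back.classes == model.classes and back.train_wells == model.train_wells
        assert np.allclose(back.predict_proba(eval_ds.images), model.predict_proba(eval_ds.images))
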