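"""Network architectures, cropping, the demosaicking pipeline contract
and short training runs."""

import numpy as np
import pytest

from hsdemosaic import (
    LossConfig,
    NetworkSpec,
    SceneSpec,
    SupervisedDemosaicker,
    TrainConfig,
    UnsupervisedDemosaicker,
    build_network,
    canonical_pattern,
    degrade,
    demosaick,
    linear_demosaick,
    make_dataset,
    override_snapshot_pixels,
    random_divisible_crop,
)
from hsdemosaic.autodiff import Tensor


@pytest.fixture(scope="module")
def small_dataset():
    return make_dataset(
        SceneSpec(X=32, Y=32), canonical_pattern(4), n_train=3, n_test=2, seed=5
    )


class TestArchitectures:
    @pytest.mark.parametrize("arch", ["edsr", "unet", "res2unet"])
    def test_identity_at_initialisation(self, rng, arch):
        """Zero-init tail + global skip: untrained nets are the identity."""
        net = build_network(NetworkSpec(architecture=arch, n_bands=16, width=8, depth=1), 3)
        x = rng.random((1, 16, 16, 16)).astype(np.float32)
        out = net(Tensor(x))
        assert np.allclose(out.data, x, atol=1e-6)

    @pytest.mark.parametrize("arch", ["edsr", "unet", "res2unet"])
    def test_shape_preserved(self, rng, arch):
        net = build_network(NetworkSpec(architecture=arch, n_bands=4, width=8, depth=2), 0)
        x = rng.random((2, 4, 8, 12)).astype(np.float32)
        assert net(Tensor(x)).shape == (2, 4, 8, 12)

    def test_state_roundtrip(self, rng):
        spec = NetworkSpec(architecture="edsr", n_bands=4, width=8, depth=1)
        a = build_network(spec, 1)
        b = build_network(spec, 2)
        b.load_state_arrays(a.state_arrays())
        x = Tensor(rng.random((1, 4, 8, 8)))
        assert np.array_equal(a(x).data, b(x).data)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(architecture="transformer")


class TestRandomDivisibleCrop:
    def test_origins_aligned_and_uniform(self):
        rng = np.random.default_rng(0)
        seen = {}
        for _ in range(400):
            x0, y0, h, w = random_divisible_crop((8, 8), 4, 4, rng)
            assert (x0 % 4, y0 % 4, h, w) == (0, 0, 4, 4)
            seen[(x0, y0)] = seen.get((x0, y0), 0) + 1
        assert set(seen) == {(0, 0), (0, 4), (4, 0), (4, 4)}
        assert min(seen.values()) > 400 / 4 * 0.6  # roughly uniform

    def test_full_size_crop_forced_origin(self):
        rng = np.random.default_rng(0)
        assert random_divisible_crop((12, 16), 4, (12, 16), rng) == (0, 0, 12, 16)

    def test_period_one_is_plain_crop(self):
        rng = np.random.default_rng(1)
        x0, y0, h, w = random_divisible_crop((10, 10), 1, 3, rng)
        assert 0 <= x0 <= 7 and 0 <= y0 <= 7 and (h, w) == (3, 3)

    def test_indivisible_crop_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            random_divisible_crop((16, 16), 4, 6, np.random.default_rng(0))

    def test_oversized_crop_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            random_divisible_crop((8, 8), 4, 12, np.random.default_rng(0))

    def test_crops_preserve_mosaic_phase(self, rng, pattern4):
        """A divisible crop of a snapshot is the degradation of the same
        crop of the cube: the MSFA alignment survives."""
        cube = rng.random((16, 16, 16))
        snap = degrade(cube, pattern4)
        g = np.random.default_rng(7)
        for _ in range(10):
            x0, y0, h, w = random_divisible_crop(snap.shape, 4, 8, g)
            crop_snap = snap[x0 : x0 + h, y0 : y0 + w]
            assert np.array_equal(
                degrade(cube[x0 : x0 + h, y0 : y0 + w], pattern4), crop_snap
            )


class TestDemosaickPipeline:
    def test_identity_model_equals_overridden_baseline(self, rng, pattern4):
        snap = rng.random((16, 16))
        net = build_network(NetworkSpec(n_bands=16, width=8, depth=1), 0)
        out = demosaick(snap, pattern4, net)
        base = override_snapshot_pixels(linear_demosaick(snap, pattern4), snap, pattern4)
        assert np.allclose(out, base, atol=1e-6)

    def test_hard_constraint_any_model(self, rng, pattern4):
        net = build_network(NetworkSpec(n_bands=16, width=8, depth=1), 11)
        for p in net.parameters():  # arbitrary non-identity weights
            p.data = p.data + rng.normal(0, 0.05, p.data.shape).astype(p.data.dtype)
        for _ in range(5):
            snap = rng.random((16, 16))
            out = demosaick(snap, pattern4, net)
            assert np.array_equal(degrade(out, pattern4), snap)

    def test_no_model_gives_overridden_linear(self, rng, pattern4):
        snap = rng.random((8, 8))
        out = demosaick(snap, pattern4, None)
        assert np.array_equal(degrade(out, pattern4), snap)


class TestTraining:
    def test_zero_lambdas_leave_parameters_unchanged(self, small_dataset):
        cfg = LossConfig(lambda_tik=0.0, lambda_tv=0.0, lambda_rho=0.0)
        model = UnsupervisedDemosaicker(
            small_dataset.train_snapshots,
            small_dataset.pattern,
            small_dataset.responses,
            network=NetworkSpec(n_bands=16, width=8, depth=1),
            loss_config=cfg,
        )
        res = model.fit(steps=3, seed=0, crop_size=16)
        ref = build_network(NetworkSpec(n_bands=16, width=8, depth=1),
                            np.random.default_rng(0))
        for got, exp in zip(res.network.parameters(), ref.parameters()):
            assert np.array_equal(got.data, exp.data)

    def test_unsupervised_loss_decreases(self, small_dataset):
        model = UnsupervisedDemosaicker(
            small_dataset.train_snapshots,
            small_dataset.pattern,
            small_dataset.responses,
            network=NetworkSpec(n_bands=16, width=8, depth=1),
        )
        res = model.fit(steps=120, seed=0, crop_size=16)
        hist = res.history["total"]
        assert hist.iloc[-20:].mean() < hist.iloc[:20].mean()
        assert set(res.history.columns) >= {
            "step", "total", "tikhonov", "tv", "gradient_consistency",
        }

    def test_supervised_loss_decreases(self, small_dataset):
        model = SupervisedDemosaicker(
            list(small_dataset.test_pairs),
            small_dataset.pattern,
            network=NetworkSpec(n_bands=16, width=8, depth=1),
        )
        res = model.fit(steps=200, seed=0, crop_size=16, lr=1e-3)
        hist = res.history["mrae"]
        assert hist.iloc[-30:].mean() < hist.iloc[:30].mean()

    def test_bit_identical_histories_under_seed(self, small_dataset):
        def run():
            model = UnsupervisedDemosaicker(
                small_dataset.train_snapshots,
                small_dataset.pattern,
                small_dataset.responses,
                network=NetworkSpec(n_bands=16, width=8, depth=1),
            )
            return model.fit(steps=10, seed=42, crop_size=16)

        a, b = run(), run()
        assert a.history.equals(b.history)
        for pa, pb in zip(a.network.parameters(), b.network.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_keep_best_restores_lowest_loss_parameters(self, small_dataset):
        model = SupervisedDemosaicker(
            list(small_dataset.test_pairs),
            small_dataset.pattern,
            network=NetworkSpec(n_bands=16, width=8, depth=1),
        )
        res = model.fit(steps=30, seed=3, crop_size=16, lr=1e-2, keep_best=True)
        best_step = int(res.history["total"].idxmin())
        # refit without keep_best up to the best step: parameters must match
        ref = model.fit(steps=best_step, seed=3, crop_size=16, lr=1e-2)
        for a, b in zip(res.network.parameters(), ref.network.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_empty_training_set_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="at least one"):
            UnsupervisedDemosaicker(
                [], small_dataset.pattern, small_dataset.responses
            )

    def test_supervised_shape_mismatch_rejected(self, small_dataset, rng):
        snap, truth = small_dataset.test_pairs[0]
        with pytest.raises(ValueError, match="inconsistent"):
            SupervisedDemosaicker(
                [(snap, truth[:, :, :8])], small_dataset.pattern
            )

    def test_result_summary_and_checkpoint_roundtrip(self, tmp_path, small_dataset):
        model = UnsupervisedDemosaicker(
            small_dataset.train_snapshots,
            small_dataset.pattern,
            small_dataset.responses,
            network=NetworkSpec(n_bands=16, width=8, depth=1),
        )
        res = model.fit(steps=4, seed=1, crop_size=16)
        text = res.summary()
        assert "unsupervised" in text and "seed:          1" in text
        res.save(tmp_path / "ckpt.npz")
        from hsdemosaic import DemosaickingResult

        back = DemosaickingResult.load(tmp_path / "ckpt.npz")
        snap = small_dataset.test_pairs[0][0]
        assert np.array_equal(res.demosaick(snap), back.demosaick(snap))
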