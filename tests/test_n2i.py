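"""Noise2Inverse training pairs, training behaviour, and averaged inference."""

import numpy as np
import pytest

import n2ibone as nb
from n2ibone.n2i import (
    N2IHyperparams,
    Noise2InverseDenoiser,
    _reflect,
    denoise,
    make_training_pairs,
)
from n2ibone.recon import SubReconSet


def make_srs(k: int, nz: int = 6, size: int = 16, seed: int = 0,
             base: np.ndarray | None = None, noise: float = 0.0) -> SubReconSet:
    rng = np.random.default_rng(seed)
    if base is None:
        base = rng.random((nz, size, size))
    vols = [base + noise * rng.standard_normal(base.shape) for _ in range(k)]
    angles = np.linspace(0, np.pi, 12, endpoint=False)
    return SubReconSet(K=k, subrecons=vols, source_angle_sets=np.array_split(angles, k))


class TestMakeTrainingPairs:
    def test_pair_count_is_k_times_slices(self):
        srs = make_srs(2, nz=10)
        assert len(make_training_pairs(srs, slab=3)) == 20
        srs3 = make_srs(3, nz=10)
        assert len(make_training_pairs(srs3, slab=3)) == 30

    def test_single_ordering_flag_halves_pairs(self):
        srs = make_srs(2, nz=10)
        assert len(make_training_pairs(srs, slab=3, both_orderings=False)) == 10

    def test_k3_identical_subvolumes_input_center_equals_target(self):
        base = np.random.default_rng(1).random((6, 8, 8))
        srs = make_srs(3, base=base, noise=0.0)
        ts = make_training_pairs(srs, slab=3)
        half = 3 // 2
        assert np.allclose(ts.inputs[:, half], ts.targets)

    def test_slab_reflection_at_first_slice(self):
        # slab 5 centered on slice 0 reads slices 2, 1, 0, 1, 2
        assert [_reflect(0 + o, 10) for o in range(-2, 3)] == [2, 1, 0, 1, 2]
        srs = make_srs(2, nz=6)
        ts = make_training_pairs(srs, slab=5)
        a = srs.subrecons[0]  # first assignment is A→B, so inputs come from A
        assert np.allclose(ts.inputs[0], a[[2, 1, 0, 1, 2]])

    def test_even_slab_rejected(self):
        with pytest.raises(ValueError):
            make_training_pairs(make_srs(2), slab=4)

    def test_k_below_two_rejected(self):
        srs = make_srs(2)
        srs.K = 1  # forged object
        with pytest.raises(ValueError):
            make_training_pairs(srs, slab=3)


class TestTraining:
    def test_identical_noiseless_subrecons_reach_tiny_loss(self):
        # with input == target the network must approximate the identity
        base = np.random.default_rng(2).random((6, 16, 16))
        srs = make_srs(2, base=base, noise=0.0)
        est = Noise2InverseDenoiser(
            depth=6, slab=3, epochs=100, batch_size=6, seed=0, learning_rate=3e-2
        )
        est.fit(srs)
        final = est.training_log_[-1]["train_loss"]
        # losses are in normalized units: input variance is 1
        assert final <= 1e-4 * 1.0

    def test_same_seed_reproduces_training_log(self):
        srs = make_srs(2, noise=0.05, seed=3)
        kw = dict(depth=4, slab=3, epochs=3, batch_size=4, seed=11)
        log1 = Noise2InverseDenoiser(**kw).fit(srs).training_log_
        log2 = Noise2InverseDenoiser(**kw).fit(srs).training_log_
        assert log1 == log2

    def test_empty_dataset_rejected(self):
        from n2ibone.n2i import TrainingSet

        empty = TrainingSet(
            inputs=np.zeros((0, 3, 4, 4)),
            targets=np.zeros((0, 4, 4)),
            slice_index=np.zeros(0, dtype=int),
            volume_index=np.zeros(0, dtype=int),
        )
        with pytest.raises(ValueError):
            Noise2InverseDenoiser(depth=2, slab=3).fit(empty)

    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            N2IHyperparams(slab=4)
        with pytest.raises(ValueError):
            N2IHyperparams(val_fraction=1.5)
        with pytest.raises(ValueError):
            N2IHyperparams(learning_rate=0.0)


class _IdentityStub:
    def predict_volume(self, volume):
        return volume.copy()


class TestDenoise:
    def test_identity_stub_on_equal_subrecons_returns_them(self):
        base = np.random.default_rng(0).random((4, 8, 8))
        srs = make_srs(2, base=base, noise=0.0)
        out = denoise(_IdentityStub(), srs)
        assert np.allclose(out, base)

    def test_identity_stub_averages_the_two_subrecons(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((4, 8, 8)), rng.random((4, 8, 8))
        angles = np.linspace(0, np.pi, 8, endpoint=False)
        srs = SubReconSet(K=2, subrecons=[a, b],
                          source_angle_sets=[angles[::2], angles[1::2]])
        out = denoise(_IdentityStub(), srs)
        assert np.allclose(out, (a + b) / 2)

    def test_output_invariant_to_subrecon_order(self):
        rng = np.random.default_rng(2)
        vols = [rng.random((4, 8, 8)) for _ in range(3)]
        angles = np.linspace(0, np.pi, 9, endpoint=False)
        srs = SubReconSet(K=3, subrecons=vols,
                          source_angle_sets=[angles[0::3], angles[1::3], angles[2::3]])
        srs_rev = SubReconSet(K=3, subrecons=vols[::-1],
                              source_angle_sets=[angles[2::3], angles[1::3], angles[0::3]])
        stub = _IdentityStub()
        assert np.allclose(denoise(stub, srs), denoise(stub, srs_rev))

    def test_transform_requires_fit(self):
        with pytest.raises(RuntimeError):
            Noise2InverseDenoiser().transform(make_srs(2))


class TestDenoisingEfficacy:
    def test_denoised_beats_sub_reconstructions_at_fixed_seed(self):
        # the N2I premise: with independent noise per split, the averaged
        # network output is closer to the clean signal than the noisy inputs
        rng = np.random.default_rng(5)
        nz, size = 8, 24
        clean = np.zeros((nz, size, size))
        clean[:, 8:16, 8:16] = 1.0
        clean += rng.random((1, size, size)) * 0.2
        srs = make_srs(2, base=clean, noise=0.3, seed=6)
        est = Noise2InverseDenoiser(depth=8, slab=3, epochs=25, batch_size=8, seed=1)
        est.fit(srs)
        out = est.transform(srs)
        mse_out = np.mean((out - clean) ** 2)
        mse_sub = np.mean([np.mean((v - clean) ** 2) for v in srs.subrecons])
        assert mse_out < mse_sub

    def test_validation_loss_decreases(self):
        rng = np.random.default_rng(7)
        clean = rng.random((8, 24, 24))
        srs = make_srs(2, base=clean, noise=0.3, seed=8)
        est = Noise2InverseDenoiser(depth=8, slab=3, epochs=15, batch_size=8, seed=2)
        est.fit(srs)
        assert est.training_log_[est.best_epoch_]["val_loss"] < est.training_log_[0]["val_loss"]


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        est = Noise2InverseDenoiser(depth=7, epochs=3)
        params = est.get_params()
        est2 = Noise2InverseDenoiser(**params)
        assert est2.get_params() == params
        est2.set_params(depth=9)
        assert est2.depth == 9

    def test_save_load_round_trip(self, tmp_path):
        srs = make_srs(2, noise=0.05, seed=9)
        est = Noise2InverseDenoiser(depth=4, slab=3, epochs=2, batch_size=4, seed=3)
        est.fit(srs)
        path = tmp_path / "model.pkl"
        est.save(path)
        loaded = Noise2InverseDenoiser.load(path)
        assert np.allclose(loaded.transform(srs), est.transform(srs))
        assert loaded.best_epoch_ == est.best_epoch_
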