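"""Self-supervised Noise2Inverse training and averaged inference.

The projection set of a scan is split into K parts with statistically
independent noise; each part is reconstructed separately and a network is
trained to predict one sub-reconstruction from (the mean of) the others.
Because the noise in input and target is independent, the minimum
mean-squared-error predictor is the common noise-free reconstruction, so the
trained network denoises without any clean reference.  At inference the K
leave-one-out predictions are averaged.

``Noise2InverseDenoiser`` is an sklearn-style estimator (``fit`` on one or
more :class:`~n2ibone.recon.SubReconSet`, ``transform`` to denoise); the
module-level ``train``/``denoise`` functions are thin wrappers over it.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .msdnet import MSDNet
from .recon import SubReconSet

__all__ = [
    "N2IHyperparams",
    "TrainingSet",
    "make_training_pairs",
    "Noise2InverseDenoiser",
    "train",
    "denoise",
]


@dataclass(frozen=True)
class N2IHyperparams:
    """Training configuration; defaults follow the reference protocol except
    for depth, where 20 layers is the desk-scale default (the full-scale
    network used 100)."""

    depth: int = 20
    learning_rate: float = 1e-3
    slab: int = 5
    batch_size: int = 12
    epochs: int = 100
    val_fraction: float = 0.20
    seed: int = 0
    both_orderings: bool = True
    dilations: tuple[int, ...] = tuple(range(1, 11))

    def __post_init__(self) -> None:
        if self.slab < 1 or self.slab % 2 == 0:
            raise ValueError("slab must be odd and ≥ 1")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainingSet:
    """(input slab, target slice) pairs from one or more scans.

    ``inputs``: (n_pairs, slab, H, W); ``targets``: (n_pairs, H, W);
    ``slice_index`` and ``volume_index`` locate each target for the
    contiguous-block validation split.
    """

    inputs: np.ndarray
    targets: np.ndarray
    slice_index: np.ndarray
    volume_index: np.ndarray

    def __len__(self) -> int:
        return len(self.targets)


def _reflect(i: int, n: int) -> int:
    """Reflect slice index i into [0, n) without repeating the edge."""
    if n == 1:
        return 0
    period = 2 * n - 2
    i = abs(i) % period
    return i if i < n else period - i


def _slab(vol: np.ndarray, center: int, slab: int) -> np.ndarray:
    half = slab // 2
    idx = [_reflect(center + o, vol.shape[0]) for o in range(-half, half + 1)]
    return vol[idx]


def make_training_pairs(
    srs: SubReconSet, slab: int = 5, both_orderings: bool = True, volume_index: int = 0
) -> TrainingSet:
    """Build the N2I self-supervised dataset from K sub-reconstructions.

    For K = 2 both orderings (A→B and B→A) are emitted by default; for K > 2
    each of the K leave-one-out assignments is emitted with input = mean of
    the other K−1 sub-reconstructions.  Inputs are slabs of ``slab`` adjacent
    slices centered on the target slice, with indices reflected at the volume
    boundary (slab 5 at slice 0 reads slices 2, 1, 0, 1, 2).
    """
    if srs.K < 2:
        raise ValueError("Noise2Inverse needs K ≥ 2")
    if slab % 2 == 0:
        raise ValueError("slab must be odd")
    nz = srs.n_slices
    if nz < 1:
        raise ValueError("empty sub-reconstructions")
    assignments: list[tuple[np.ndarray, np.ndarray]] = []
    if srs.K == 2:
        a, b = srs.subrecons
        assignments.append((a, b))
        if both_orderings:
            assignments.append((b, a))
    else:
        for j in range(srs.K):
            others = [srs.subrecons[i] for i in range(srs.K) if i != j]
            assignments.append((np.mean(others, axis=0), srs.subrecons[j]))
    inputs, targets, s_idx = [], [], []
    for inp_vol, tgt_vol in assignments:
        for z in range(nz):
            inputs.append(_slab(inp_vol, z, slab))
            targets.append(tgt_vol[z])
            s_idx.append(z)
    return TrainingSet(
        inputs=np.stack(inputs),
        targets=np.stack(targets),
        slice_index=np.array(s_idx),
        volume_index=np.full(len(s_idx), volume_index),
    )


def concat_training_sets(sets: list[TrainingSet]) -> TrainingSet:
    return TrainingSet(
        inputs=np.concatenate([s.inputs for s in sets]),
        targets=np.concatenate([s.targets for s in sets]),
        slice_index=np.concatenate([s.slice_index for s in sets]),
        volume_index=np.concatenate([s.volume_index for s in sets]),
    )


class Noise2InverseDenoiser(BaseEstimator):
    """Sklearn-style Noise2Inverse denoiser around a NumPy MSD network.

    Parameters mirror :class:`N2IHyperparams`.  After ``fit`` the estimator
    carries ``net_`` (best-validation weights), ``training_log_`` (per-epoch
    train/val MSE, epoch 0 being the untrained network), ``best_epoch_``,
    and the input normalization ``shift_``/``scale_`` so inference is
    self-contained.
    """

    def __init__(
        self,
        depth: int = 20,
        learning_rate: float = 1e-3,
        slab: int = 5,
        batch_size: int = 12,
        epochs: int = 100,
        val_fraction: float = 0.20,
        seed: int = 0,
        both_orderings: bool = True,
        dilations: tuple[int, ...] = tuple(range(1, 11)),
    ) -> None:
        self.depth = depth
        self.learning_rate = learning_rate
        self.slab = slab
        self.batch_size = batch_size
        self.epochs = epochs
        self.val_fraction = val_fraction
        self.seed = seed
        self.both_orderings = both_orderings
        self.dilations = dilations

    # ------------------------------------------------------------------ fit
    def fit(self, X: SubReconSet | list[SubReconSet] | TrainingSet, y=None):
        """Train on one scan, several scans (joint training), or a
        pre-built :class:`TrainingSet`."""
        hp = N2IHyperparams(
            depth=self.depth,
            learning_rate=self.learning_rate,
            slab=self.slab,
            batch_size=self.batch_size,
            epochs=self.epochs,
            val_fraction=self.val_fraction,
            seed=self.seed,
            both_orderings=self.both_orderings,
            dilations=tuple(self.dilations),
        )
        if isinstance(X, TrainingSet):
            ts = X
        elif isinstance(X, SubReconSet):
            ts = make_training_pairs(X, hp.slab, hp.both_orderings)
        else:
            ts = concat_training_sets(
                [make_training_pairs(s, hp.slab, hp.both_orderings, volume_index=i)
                 for i, s in enumerate(X)]
            )
        if len(ts) == 0:
            raise ValueError("empty training dataset")

        # contiguous trailing slice blocks per volume form the validation set,
        # limiting leakage between adjacent (highly correlated) slices
        val_mask = np.zeros(len(ts), dtype=bool)
        for v in np.unique(ts.volume_index):
            in_vol = ts.volume_index == v
            nz = int(ts.slice_index[in_vol].max()) + 1
            n_val = max(1, int(round(hp.val_fraction * nz))) if nz > 1 else 0
            val_mask |= in_vol & (ts.slice_index >= nz - n_val)
        if not (~val_mask).any():
            raise ValueError("validation split left no training pairs")

        self.shift_ = float(ts.inputs[~val_mask].mean())
        self.scale_ = float(ts.inputs[~val_mask].std())
        if self.scale_ == 0:
            self.scale_ = 1.0
        xin = (ts.inputs - self.shift_) / self.scale_
        tgt = (ts.targets - self.shift_) / self.scale_

        rng = np.random.default_rng(hp.seed)
        net = MSDNet(hp.depth, hp.slab, hp.dilations, seed=hp.seed)
        tr_idx = np.flatnonzero(~val_mask)
        va_idx = np.flatnonzero(val_mask)
        if len(va_idx) == 0:  # single-slice volumes: validate on the data itself
            va_idx = tr_idx

        def eval_loss(idx):
            losses, counts = [], []
            for k in range(0, len(idx), hp.batch_size):
                sel = idx[k : k + hp.batch_size]
                pred = net.forward(xin[sel])
                losses.append(float(np.mean((pred - tgt[sel]) ** 2)) * len(sel))
                counts.append(len(sel))
            return float(np.sum(losses) / np.sum(counts))

        log = [{"epoch": 0, "train_loss": eval_loss(tr_idx), "val_loss": eval_loss(va_idx)}]
        best = {"epoch": 0, "val": log[0]["val_loss"], "weights": net.get_weights()}
        for epoch in range(1, hp.epochs + 1):
            order = rng.permutation(tr_idx)
            batch_losses = []
            for k in range(0, len(order), hp.batch_size):
                sel = order[k : k + hp.batch_size]
                pred, cache = net.forward(xin[sel], keep_cache=True)
                err = pred - tgt[sel]
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "reduce the learning rate"
                    )
                grads = net.backward(cache, 2.0 * err / err.size)
                net.adam_step(grads, hp.learning_rate)
                batch_losses.append(loss)
            val = eval_loss(va_idx)
            log.append(
                {"epoch": epoch, "train_loss": float(np.mean(batch_losses)), "val_loss": val}
            )
            if val < best["val"]:
                best = {"epoch": epoch, "val": val, "weights": net.get_weights()}
        net.set_weights(best["weights"])
        self.net_ = net
        self.hyperparams_ = hp
        self.training_log_ = log
        self.best_epoch_ = best["epoch"]
        return self

    # ------------------------------------------------------------- inference
    def predict_volume(self, volume: np.ndarray) -> np.ndarray:
        """Apply the network slice-wise to one volume (nz, H, W)."""
        self._check_fitted()
        nz = volume.shape[0]
        out = np.empty_like(volume, dtype=np.float64)
        bs = max(1, self.batch_size)
        slabs = np.stack([_slab(volume, z, self.hyperparams_.slab) for z in range(nz)])
        slabs = (slabs - self.shift_) / self.scale_
        for k in range(0, nz, bs):
            out[k : k + bs] = self.net_.forward(slabs[k : k + bs])
        return out * self.scale_ + self.shift_

    def transform(self, srs: SubReconSet) -> np.ndarray:
        """Denoise a scan: average the K leave-one-out network outputs."""
        self._check_fitted()
        return denoise(self, srs)

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("denoiser is not fitted")

    # ----------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        self._check_fitted()
        payload = {
            "params": self.get_params(),
            "weights": self.net_.get_weights(),
            "shift": self.shift_,
            "scale": self.scale_,
            "training_log": self.training_log_,
            "best_epoch": self.best_epoch_,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "Noise2InverseDenoiser":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        est = cls(**payload["params"])
        est.hyperparams_ = N2IHyperparams(**{
            k: payload["params"][k] for k in (
                "depth", "learning_rate", "slab", "batch_size", "epochs",
                "val_fraction", "seed", "both_orderings",
            )
        } | {"dilations": tuple(payload["params"]["dilations"])})
        est.net_ = MSDNet(est.depth, est.slab, tuple(est.dilations), seed=est.seed)
        est.net_.set_weights(payload["weights"])
        est.shift_ = payload["shift"]
        est.scale_ = payload["scale"]
        est.training_log_ = payload["training_log"]
        est.best_epoch_ = payload["best_epoch"]
        return est


def train(dataset: SubReconSet | list[SubReconSet] | TrainingSet,
          hp: N2IHyperparams | None = None) -> Noise2InverseDenoiser:
    """Train a Noise2Inverse denoiser; returns the fitted estimator."""
    hp = hp or N2IHyperparams()
    est = Noise2InverseDenoiser(**asdict(hp))
    return est.fit(dataset)


def denoise(model, srs: SubReconSet) -> np.ndarray:
    """Averaged N2I inference.

    ``model`` is anything exposing ``predict_volume(volume) -> volume``.  For
    each j the input is the mean of all sub-reconstructions except j (for
    K = 2 this is simply the other sub-reconstruction); the K outputs are
    averaged, so the result is invariant to the order of the sub-
    reconstructions.
    """
    outs = []
    for j in range(srs.K):
        others = [srs.subrecons[i] for i in range(srs.K) if i != j]
        inp = others[0] if len(others) == 1 else np.mean(others, axis=0)
        if inp.shape != srs.shape:
            raise ValueError("sub-reconstruction shape mismatch")
        outs.append(model.predict_volume(inp))
    return np.mean(outs, axis=0)
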