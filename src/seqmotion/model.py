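"""Sequence-embedding to motion regressor.

The network maps an L x d per-residue embedding matrix to K motion tensors
of shape L x 3: a per-residue linear layer, two 1-dimensional convolutional
layers (filter sizes 15 and 31, length-preserving symmetric zero padding)
and K parallel linear heads, linked by leaky-rectifier activations and
dropout.  Being fully convolutional it handles any sequence length and
preserves it throughout.

The implementation is pure NumPy with hand-written backpropagation and an
Adam optimiser: the loss transformation (permutation, rotation, scaling) is
recomputed on every forward pass and held constant for differentiation, so
the gradient of the invariant loss with respect to the network output has
the simple closed form implemented in :mod:`seqmotion.alignment`.  Batches
pad sequences on the right; activations beyond each sample's true length
are zeroed after every layer so that a padded batch reproduces single-
sequence outputs exactly and padded rows never contribute to the loss.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

__all__ = ["EmbeddingMatrix", "ModelConfig", "MotionModel", "build_model",
           "train", "predict", "load_embeddings", "save_embeddings",
           "save_checkpoint", "load_checkpoint"]


class ConfigError(ValueError):
    pass


@dataclass
class EmbeddingMatrix:
    """An L x d per-residue embedding of opaque provenance."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("embedding must be a 2-D (L x d) matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite entries in embedding "
                             f"{self.protein_id!r}")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class ModelConfig:
    """Hyperparameters.

    Defaults follow the reference training setup: filter sizes (15, 31),
    80% dropout, leaky-rectifier activations, Adam at learning rate 1e-2,
    batch size 64, 500 epochs, K = 3 output motions.  ``hidden`` (the
    channel width between the first linear layer and the convolution
    stack) is a free choice, default 256.
    """

    d: int = 1024
    K: int = 3
    hidden: int = 256
    conv_filter_sizes: tuple = (15, 31)
    dropout: float = 0.8
    negative_slope: float = 0.01
    lr: float = 1e-2
    batch_size: int = 64
    epochs: int = 500
    seed: int = 0

    def __post_init__(self):
        self.conv_filter_sizes = tuple(int(k) for k in self.conv_filter_sizes)
        if self.d < 1 or self.K < 1 or self.hidden < 1:
            raise ConfigError("dimensions must be positive")
        if any(k % 2 == 0 or k < 1 for k in self.conv_filter_sizes):
            raise ConfigError("filter sizes must be odd (length-preserving)")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout rate must be in [0, 1)")


def _init_linear(rng, fan_in, shape):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class MotionModel:
    """The convolutional regressor; parameters live in ``self.params``."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, h, K = config.d, config.hidden, config.K
        k1, k2 = config.conv_filter_sizes
        self.params = {
            "W0": _init_linear(rng, d, (d, h)),
            "b0": _init_linear(rng, d, (h,)),
            "Wc1": _init_linear(rng, k1 * h, (k1, h, h)),
            "bc1": _init_linear(rng, k1 * h, (h,)),
            "Wc2": _init_linear(rng, k2 * h, (k2, h, h)),
            "bc2": _init_linear(rng, k2 * h, (h,)),
            "Wh": _init_linear(rng, h, (K, h, 3)),
            "bh": _init_linear(rng, h, (K, 3)),
        }

    # ------------------------------------------------------------------
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- layer primitives ----------------------------------------------
    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple:
        """'Same'-padded 1D convolution along axis 1.

        x: (B, L, Cin); w: (k, Cin, Cout).  Returns (y, windows) with the
        im2col windows kept for the backward pass.
        """
        k = w.shape[0]
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        # win: (B, L, Cin, k) -> align to (B, L, k, Cin)
        win = win.transpose(0, 1, 3, 2)
        y = np.einsum("blkc,kco->blo", win, w) + b
        return y, win

    @staticmethod
    def _conv_backward(dy, win, w, x_shape):
        k = w.shape[0]
        p = k // 2
        dw = np.einsum("blkc,blo->kco", win, dy)
        db = dy.sum(axis=(0, 1))
        B, L, Cin = x_shape
        dxp = np.zeros((B, L + 2 * p, Cin))
        dcols = np.einsum("blo,kco->blkc", dy, w)
        for t in range(k):
            dxp[:, t:t + L, :] += dcols[:, :, t, :]
        return dxp[:, p:p + L, :], dw, db

    def _leaky(self, x):
        a = self.config.negative_slope
        return np.where(x >= 0, x, a * x)

    def _leaky_backward(self, dy, x):
        a = self.config.negative_slope
        return np.where(x >= 0, dy, a * dy)

    # -- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, lengths=None, train: bool = False,
                rng: Optional[np.random.Generator] = None,
                cache: Optional[dict] = None) -> np.ndarray:
        """Map a (B, L, d) batch to (B, L, K, 3) motion tensors.

        ``lengths`` gives each sample's true length; activations beyond it
        are zeroed after every layer so padding is inert.  With
        ``train=True`` inverted dropout is applied after each activation.
        """
        p = self.params
        cfg = self.config
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        B, L, d = x.shape
        if d != cfg.d:
            raise ValueError(f"embedding dim {d} != model dim {cfg.d}")
        if lengths is None:
            lengths = np.full(B, L, dtype=int)
        mask = (np.arange(L)[None, :] < np.asarray(lengths)[:, None])
        m = mask[:, :, None].astype(float)

        def drop(a):
            if not train or cfg.dropout == 0.0:
                return a, None
            keep = (rng.random(a.shape) >= cfg.dropout)
            return a * keep / (1.0 - cfg.dropout), keep

        z0 = (x @ p["W0"] + p["b0"]) * m
        a0 = self._leaky(z0) * m
        d0, k0 = drop(a0)
        z1, win1 = self._conv(d0, p["Wc1"], p["bc1"])
        z1 *= m
        a1 = self._leaky(z1) * m
        d1, kk1 = drop(a1)
        z2, win2 = self._conv(d1, p["Wc2"], p["bc2"])
        z2 *= m
        a2 = self._leaky(z2) * m
        d2, kk2 = drop(a2)
        out = np.einsum("blh,kho->blko", d2, p["Wh"]) + p["bh"]
        out = out * m[:, :, :, None]
        if cache is not None:
            cache.update(x=x, m=m, z0=z0, d0=d0, k0=k0, win1=win1, z1=z1,
                         d1=d1, kk1=kk1, win2=win2, z2=z2, d2=d2, kk2=kk2)
        return out

    def backward(self, dout: np.ndarray, cache: dict) -> dict:
        """Parameter gradients for a batch given d(loss)/d(output)."""
        p = self.params
        cfg = self.config
        m = cache["m"]
        dout = dout * m[:, :, :, None]
        d2 = cache["d2"]
        grads = {}
        grads["Wh"] = np.einsum("blh,blko->kho", d2, dout)
        grads["bh"] = dout.sum(axis=(0, 1))
        dd2 = np.einsum("blko,kho->blh", dout, p["Wh"])

        def drop_back(dy, keep):
            if keep is None:
                return dy
            return dy * keep / (1.0 - cfg.dropout)

        da2 = drop_back(dd2, cache["kk2"]) * m
        dz2 = self._leaky_backward(da2, cache["z2"]) * m
        dd1, grads["Wc2"], grads["bc2"] = self._conv_backward(
            dz2, cache["win2"], p["Wc2"], cache["d1"].shape)
        da1 = drop_back(dd1, cache["kk1"]) * m
        dz1 = self._leaky_backward(da1, cache["z1"]) * m
        dd0, grads["Wc1"], grads["bc1"] = self._conv_backward(
            dz1, cache["win1"], p["Wc1"], cache["d0"].shape)
        da0 = drop_back(dd0, cache["k0"]) * m
        dz0 = self._leaky_backward(da0, cache["z0"]) * m
        grads["W0"] = np.einsum("bld,blh->dh", cache["x"], dz0)
        grads["b0"] = dz0.sum(axis=(0, 1))
        return grads


def build_model(config: ModelConfig) -> MotionModel:
    """Construct a model; two builds with the same seed are identical."""
    return MotionModel(config)


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sample_fields(sample):
    emb = sample["embedding"]
    motions = sample["motions"]
    weights = np.asarray(sample["weights"], dtype=float)
    return emb.values, motions.vectors, weights


def _batch_loss_and_grad(model, batch, train_rng=None, train=True):
    """Mean invariant loss over a batch, plus parameter gradients."""
    from .alignment import loss_gradient, training_loss

    xs, gts, ws = zip(*(_sample_fields(s) for s in batch))
    lengths = np.array([x.shape[0] for x in xs])
    B, Lmax = len(xs), int(lengths.max())
    d = xs[0].shape[1]
    xb = np.zeros((B, Lmax, d))
    for i, x in enumerate(xs):
        xb[i, : x.shape[0]] = x
    cache = {} if train else None
    out = model.forward(xb, lengths, train=train, rng=train_rng, cache=cache)
    total = 0.0
    dout = np.zeros_like(out)
    for i, (gt, w) in enumerate(zip(gts, ws)):
        L = lengths[i]
        pred = out[i, :L]
        if not np.all(np.isfinite(pred)):
            raise RuntimeError(
                f"non-finite prediction for sample "
                f"{batch[i].get('protein_id', i)}; try a lower learning rate")
        loss, res = training_loss(gt, pred, w)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss for sample {batch[i].get('protein_id', i)}; "
                "try a lower learning rate")
        total += loss
        g_aligned = np.einsum("ab,ikb->ika", res.rotation,
                              gt[:, res.permutation, :])
        dout[i, :L] = loss_gradient(g_aligned, pred, w, res.scalings)
    total /= B
    dout /= B
    if not train:
        return total, None
    grads = model.backward(dout, cache)
    return total, grads


def evaluate_loss(model, dataset) -> float:
    """Mean invariant loss over a dataset in eval mode (no dropout)."""
    if not dataset:
        return float("nan")
    total = 0.0
    for sample in dataset:
        loss, _ = _batch_loss_and_grad(model, [sample], train=False)
        total += loss
    return total / len(dataset)


def train(model: MotionModel, dataset, config: Optional[ModelConfig] = None,
          val_dataset=None, verbose: bool = False) -> dict:
    """Minimise the invariant loss with Adam; keep the best checkpoint.

    ``dataset`` is a list of samples with keys ``embedding`` (an
    EmbeddingMatrix), ``motions`` (a ground-truth MotionSet) and
    ``weights``; augmented collections simply contribute several samples
    sharing one embedding.  The model is left holding the parameters of
    the epoch with the lowest validation loss (training loss when no
    validation set is given).  Per-epoch train/validation losses are
    recorded in eval mode (dropout off).
    """
    if not dataset:
        raise ValueError("empty training dataset")
    cfg = config or model.config
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(model.params, cfg.lr)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        for start in range(0, len(dataset), cfg.batch_size):
            batch = [dataset[i] for i in order[start:start + cfg.batch_size]]
            _, grads = _batch_loss_and_grad(model, batch, train_rng=rng,
                                            train=True)
            opt.step(model.params, grads)
        tr = evaluate_loss(model, dataset)
        vl = evaluate_loss(model, val_dataset) if val_dataset else float("nan")
        history["train_loss"].append(tr)
        history["val_loss"].append(vl)
        crit = vl if val_dataset else tr
        if crit < best[0]:
            best = (crit, copy.deepcopy(model.params))
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}  train {tr:.4f}  val {vl:.4f}")
    if best[1] is not None:
        model.params = best[1]
    return history


def predict(model: MotionModel, embedding: EmbeddingMatrix):
    """Predicted MotionSet (arbitrary orientation, no normalisation imposed)."""
    from .motions import MotionSet

    out = model.forward(embedding.values[None],
                        lengths=[embedding.L], train=False)
    return MotionSet(vectors=out[0], eigenvalues=None, is_normalised=False,
                     source="predicted", protein_id=embedding.protein_id)


def predict_batch(model: MotionModel, embeddings):
    """Batched prediction with padding; outputs match one-by-one prediction."""
    from .motions import MotionSet

    lengths = [e.L for e in embeddings]
    Lmax = max(lengths)
    xb = np.zeros((len(embeddings), Lmax, model.config.d))
    for i, e in enumerate(embeddings):
        xb[i, : e.L] = e.values
    out = model.forward(xb, lengths, train=False)
    return [MotionSet(vectors=out[i, :lengths[i]], source="predicted",
                      protein_id=e.protein_id)
            for i, e in enumerate(embeddings)]


# ---------------------------------------------------------------------------
# embeddings and checkpoints on disk


def save_embeddings(embeddings, path) -> None:
    """Write embeddings to an ``.npz`` container keyed by protein id."""
    ids = [e.protein_id for e in embeddings]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    np.savez(path, **{e.protein_id: e.values for e in embeddings})


def load_embeddings(path, manifest=None) -> list:
    """Load embeddings from an ``.npz`` container keyed by protein id.

    ``manifest`` may map protein id to expected length L; mismatches raise
    with the offending protein named.  All matrices must share d.
    """
    data = np.load(path)
    out = [EmbeddingMatrix(protein_id=key, values=data[key])
           for key in data.files]
    dims = {e.d for e in out}
    if len(dims) > 1:
        raise ValueError(f"ragged embedding dimensions: {sorted(dims)}")
    if manifest is not None:
        for e in out:
            expected = manifest.get(e.protein_id)
            if expected is not None and expected != e.L:
                raise ValueError(
                    f"embedding length mismatch for {e.protein_id!r}: "
                    f"manifest says {expected}, file has {e.L}")
    return out


def save_checkpoint(model: MotionModel, path, history=None) -> None:
    payload = {f"param_{k}": v for k, v in model.params.items()}
    meta = {"config": asdict(model.config), "history": history or {}}
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple:
    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"]).decode())
    cfg = meta["config"]
    cfg["conv_filter_sizes"] = tuple(cfg["conv_filter_sizes"])
    model = MotionModel(ModelConfig(**cfg))
    for k in model.params:
        model.params[k] = data[f"param_{k}"]
    return model, meta.get("history", {})
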