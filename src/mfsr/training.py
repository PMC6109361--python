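"""Euclidean-loss stochastic gradient descent on patch pairs.

The loss over a minibatch of B patch pairs is ``(1/(2B)) * sum ||pred -
target||^2`` (so the gradient w.r.t. the prediction is ``(pred -
target)/B``), optimised with momentum SGD at a single global learning rate.
Validation tracks PSNR on full held-out slices, matching how convergence
curves are usually plotted for this task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mfsr.degrade import PatchSet, SlicePair
from mfsr.errors import DataError, TrainingDivergence
from mfsr.metrics import MetricSpec, psnr
from mfsr.network import NetworkParams, backward_batch, forward, forward_batch

__all__ = [
    "TrainSpec",
    "TrainTrace",
    "euclidean_loss",
    "batch_order",
    "train",
    "validation_psnr",
    "convergence_iteration",
]


@dataclass(frozen=True)
class TrainSpec:
    learning_rate: float = 0.001
    batch_size: int = 32
    momentum: float = 0.9
    max_iterations: int = 2000
    val_interval: int = 100
    seed: int = 0
    loss_convention: str = "half-mean-over-batch"
    precision: str = "float32"  # minibatch compute dtype; updates stay float64

    def __post_init__(self):
        if self.precision not in ("float32", "float64"):
            raise DataError("precision must be 'float32' or 'float64'")
        if self.learning_rate <= 0:
            raise DataError("learning rate must be > 0")
        if self.batch_size < 1:
            raise DataError("batch size must be >= 1")
        if self.max_iterations < 0:
            raise DataError("max iterations must be >= 0")
        if self.val_interval < 1:
            raise DataError("validation interval must be >= 1")


@dataclass
class TrainTrace:
    """Per-iteration loss plus periodic validation PSNR."""

    loss: np.ndarray  # (n_iterations,)
    val_iterations: np.ndarray  # iteration index of each validation point
    val_psnr: np.ndarray
    seed: int
    n_iterations: int
    batch_hash: str = ""

    def __post_init__(self):
        self.loss = np.asarray(self.loss, dtype=float)
        self.val_iterations = np.asarray(self.val_iterations, dtype=int)
        self.val_psnr = np.asarray(self.val_psnr, dtype=float)
        if len(self.loss) != self.n_iterations:
            raise DataError("trace length inconsistent with iteration count")
        if len(self.val_iterations) != len(self.val_psnr):
            raise DataError("validation series lengths differ")
        if self.n_iterations and not np.isfinite(self.loss).all():
            raise DataError("trace contains non-finite losses")

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"iteration": np.arange(self.n_iterations), "loss": self.loss})
        val = pd.DataFrame({"iteration": self.val_iterations, "val_psnr": self.val_psnr})
        df.merge(val, on="iteration", how="left").to_csv(path, index=False)


def euclidean_loss(pred: np.ndarray, target: np.ndarray):
    """Return ``(loss, dloss/dpred)`` under the 1/(2B) convention."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise DataError(f"shape mismatch {pred.shape} vs {target.shape}")
    B = pred.shape[0]
    diff = pred - target
    loss = float(np.sum(diff**2) / (2 * B))
    return loss, diff / B


def batch_order(n_samples: int, batch_size: int, n_iterations: int, seed: int) -> np.ndarray:
    """The deterministic minibatch index sequence ``(n_iterations, batch_size)``.

    Samples are drawn by seeded epoch-wise shuffling without replacement
    inside each epoch; the sequence depends only on the arguments, so two
    networks trained with the same data, seed and budget see identical
    batches.
    """
    rng = np.random.default_rng(seed)
    order = np.empty((n_iterations, batch_size), dtype=np.int64)
    perm = np.array([], dtype=np.int64)
    pos = 0
    for it in range(n_iterations):
        take = []
        need = batch_size
        while need > 0:
            if pos >= len(perm):
                perm = rng.permutation(n_samples)
                pos = 0
            grab = min(need, len(perm) - pos)
            take.append(perm[pos : pos + grab])
            pos += grab
            need -= grab
        order[it] = np.concatenate(take)
    return order


def validation_psnr(params: NetworkParams, val: list[SlicePair]) -> float:
    """Mean masked PSNR of the network's reconstructions of held-out slices."""
    vals = []
    for pair in val:
        recon = np.clip(forward(params, pair.lr), 0.0, 1.0)
        vals.append(psnr(pair.hr, recon, MetricSpec(mask=pair.mask)))
    return float(np.mean(vals))


def train(
    params: NetworkParams,
    data: PatchSet,
    val: list[SlicePair],
    spec: TrainSpec,
    checkpoint_dir=None,
    checkpoint_interval: int | None = None,
) -> tuple[NetworkParams, TrainTrace]:
    """Momentum-SGD training; returns updated parameters and the full trace.

    The input ``params`` object is left untouched.  Deterministic given the
    seed on a fixed platform (floating-point reduction order can differ
    across BLAS builds; bit-stability is only guaranteed per platform).
    Aborts with :class:`TrainingDivergence` if the loss goes non-finite.
    With ``checkpoint_dir``/``checkpoint_interval`` set, parameters are
    checkpointed every N iterations as ``iter_<n>.npz``.
    """
    if len(data) == 0:
        raise DataError("empty patch set")
    params = params.copy()
    layers = params.layers()
    velocity = [
        {"W": np.zeros_like(p.W), "b": np.zeros_like(p.b)} for p in layers
    ]

    order = batch_order(len(data), spec.batch_size, spec.max_iterations, spec.seed)
    import hashlib

    bhash = hashlib.sha256(order.tobytes()).hexdigest()[:16]

    losses = np.empty(spec.max_iterations)
    val_iters: list[int] = []
    val_psnrs: list[float] = []
    dtype = np.float32 if spec.precision == "float32" else np.float64
    x_all = data.lr[:, None, :, :].astype(dtype)
    y_all = data.hr[:, None, :, :].astype(dtype)

    for it in range(spec.max_iterations):
        idx = order[it]
        xb, yb = x_all[idx], y_all[idx]
        # overflow here is the divergence signal, detected on the loss below
        with np.errstate(over="ignore", invalid="ignore"):
            pred, cache = forward_batch(params, xb, need_cache=True)
            loss, dpred = euclidean_loss(pred, yb)
        if not np.isfinite(loss):
            raise TrainingDivergence(it)
        losses[it] = loss
        grads = backward_batch(params, cache, dpred)
        for p, g, v in zip(layers, grads.layers(), velocity):
            v["W"] = spec.momentum * v["W"] - spec.learning_rate * g.W
            v["b"] = spec.momentum * v["b"] - spec.learning_rate * g.b
            p.W = p.W + v["W"]
            p.b = p.b + v["b"]
        if val and (it + 1) % spec.val_interval == 0:
            val_iters.append(it + 1)
            val_psnrs.append(validation_psnr(params, val))
        if checkpoint_dir is not None and checkpoint_interval \
                and (it + 1) % checkpoint_interval == 0:
            from pathlib import Path

            from mfsr.network import save_params

            out = Path(checkpoint_dir)
            out.mkdir(parents=True, exist_ok=True)
            save_params(params, out / f"iter_{it + 1:06d}.npz")

    trace = TrainTrace(
        loss=losses,
        val_iterations=np.asarray(val_iters),
        val_psnr=np.asarray(val_psnrs),
        seed=spec.seed,
        n_iterations=spec.max_iterations,
        batch_hash=bhash,
    )
    return params, trace


def convergence_iteration(trace_or_series, epsilon: float = 0.01) -> int:
    """Earliest validation index reaching ``(1 - epsilon)`` of the plateau.

    The plateau is the mean of the last 10 % of the validation series (at
    least one point).  Returns the series length if the threshold is never
    reached.
    """
    if isinstance(trace_or_series, TrainTrace):
        series = trace_or_series.val_psnr
    else:
        series = np.asarray(trace_or_series, dtype=float)
    if series.size == 0:
        raise DataError("empty validation series")
    k = max(1, series.size // 10)
    plateau = float(series[-k:].mean())
    threshold = (1.0 - epsilon) * plateau
    hits = np.nonzero(series >= threshold)[0]
    return int(hits[0]) if hits.size else int(series.size)
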