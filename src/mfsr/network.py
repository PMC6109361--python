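"""Multi-scale fusion networks: declarative specs, parameters, forward and
backward evaluation.

A fusion unit has one main path (conv + ReLU) and J >= 0 sub-paths; the unit
output is the elementwise sum of the main-path output and every sub-path
output.  Sub-path layers are conv + ReLU except the final layer of each
sub-path, which omits the ReLU so the fused contribution is unbounded; no
activation follows the fusion addition.  A network stacks fusion units and
ends with a single-kernel reconstruction convolution.

All convolutions are stride-1 with zero-padded same-size output, which makes
the addition of differently sized kernels well-defined and lets the network
run fully convolutionally on whole slices as well as 33x33 patches.

Everything is NumPy: the networks involved are small enough that an im2col
matmul implementation trains them in seconds to minutes on one CPU, and it
keeps the package free of a deep-learning framework dependency.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from mfsr.errors import DataError, SpecError

__all__ = [
    "ConvLayerSpec",
    "MFUSpec",
    "MFCNSpec",
    "LayerParams",
    "MFUParams",
    "NetworkParams",
    "baseline_spec",
    "plain_cnn_spec",
    "count_parameters",
    "build_network",
    "forward",
    "forward_mfu",
    "forward_batch",
    "conv_layer",
    "backward_batch",
    "zero_like_grads",
    "save_params",
    "load_params",
]


# ---------------------------------------------------------------------------
# declarative specs


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolution layer in ``s_k/n_k`` notation."""

    kernel_size: int
    n_kernels: int
    relu: bool = True

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 != 1:
            raise SpecError(f"kernel size must be odd >= 1, got {self.kernel_size}")
        if self.n_kernels < 1:
            raise SpecError(f"kernel count must be >= 1, got {self.n_kernels}")

    @classmethod
    def parse(cls, text: str, relu: bool = True) -> "ConvLayerSpec":
        """Parse the table notation, e.g. ``"9/32"``."""
        try:
            s, n = text.split("/")
            return cls(kernel_size=int(s), n_kernels=int(n), relu=relu)
        except (ValueError, AttributeError) as e:
            raise SpecError(f"cannot parse layer spec {text!r}") from e

    def notation(self) -> str:
        return f"{self.kernel_size}/{self.n_kernels}"


@dataclass(frozen=True)
class MFUSpec:
    """A fusion unit: main path conv+ReLU plus J sub-paths fused by addition.

    ``relu_before_fusion`` restores the ablated variant in which the final
    sub-path layer keeps its ReLU before the addition.
    """

    main: ConvLayerSpec
    subpaths: tuple[tuple[ConvLayerSpec, ...], ...] = ()
    relu_before_fusion: bool = False

    def __post_init__(self):
        object.__setattr__(self, "subpaths", tuple(tuple(sp) for sp in self.subpaths))
        for j, sp in enumerate(self.subpaths):
            if len(sp) == 0:
                raise SpecError(f"sub-path {j} is empty")
            if sp[-1].n_kernels != self.main.n_kernels:
                raise SpecError(
                    f"sub-path {j} ends with {sp[-1].n_kernels} kernels but the "
                    f"main path has {self.main.n_kernels}; fusion addition "
                    "requires equal channel counts"
                )

    @property
    def n_out(self) -> int:
        return self.main.n_kernels


@dataclass(frozen=True)
class MFCNSpec:
    """Ordered fusion units plus a single-kernel reconstruction layer."""

    units: tuple[MFUSpec, ...]
    recon: ConvLayerSpec = ConvLayerSpec(5, 1, relu=False)

    def __post_init__(self):
        object.__setattr__(self, "units", tuple(self.units))
        if len(self.units) < 1:
            raise SpecError("need at least one fusion unit")
        if self.recon.n_kernels != 1:
            raise SpecError("reconstruction layer must have exactly one kernel")
        if self.recon.relu:
            raise SpecError("reconstruction layer carries no activation")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def channel_chain(self) -> list[int]:
        """Channel counts entering each unit and the reconstruction layer."""
        chain = [1]
        for u in self.units:
            chain.append(u.n_out)
        return chain

    # ---- config-file round trip (table notation) ----

    def to_dict(self) -> dict:
        return {
            "units": [
                {
                    "main": u.main.notation(),
                    "subpaths": [[l.notation() for l in sp] for sp in u.subpaths],
                    **({"relu_before_fusion": True} if u.relu_before_fusion else {}),
                }
                for u in self.units
            ],
            "recon": self.recon.notation(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MFCNSpec":
        units = []
        for ud in d["units"]:
            main = ConvLayerSpec.parse(ud["main"], relu=True)
            subpaths = []
            for sp in ud.get("subpaths", []):
                layers = [ConvLayerSpec.parse(t, relu=True) for t in sp[:-1]]
                layers.append(ConvLayerSpec.parse(sp[-1], relu=False))
                subpaths.append(tuple(layers))
            units.append(MFUSpec(main=main, subpaths=tuple(subpaths),
                                 relu_before_fusion=ud.get("relu_before_fusion", False)))
        recon = ConvLayerSpec.parse(d["recon"], relu=False)
        return cls(units=tuple(units), recon=recon)

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def load(cls, path) -> "MFCNSpec":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


def mfu(main: str, *subpaths, relu_before_fusion: bool = False) -> MFUSpec:
    """Shorthand: ``mfu("9/32", ["1/32"])``."""
    sps = []
    for sp in subpaths:
        layers = [ConvLayerSpec.parse(t, relu=True) for t in sp[:-1]]
        layers.append(ConvLayerSpec.parse(sp[-1], relu=False))
        sps.append(tuple(layers))
    return MFUSpec(main=ConvLayerSpec.parse(main, relu=True), subpaths=tuple(sps),
                   relu_before_fusion=relu_before_fusion)


def baseline_spec() -> MFCNSpec:
    """The two-unit baseline: 9/32 + [1/32], 3/64 + [1/64], reconstruction 5/1."""
    return MFCNSpec(
        units=(mfu("9/32", ["1/32"]), mfu("3/64", ["1/64"])),
        recon=ConvLayerSpec(5, 1, relu=False),
    )


def plain_cnn_spec(spec: MFCNSpec) -> MFCNSpec:
    """Strip every sub-path: the plain stacked conv+ReLU counterpart."""
    return MFCNSpec(
        units=tuple(
            MFUSpec(main=u.main, subpaths=()) for u in spec.units
        ),
        recon=spec.recon,
    )


def _iter_layers(spec: MFCNSpec):
    """Yield (layer spec, input channels) over the whole network."""
    c_in = 1
    for u in spec.units:
        yield u.main, c_in
        for sp in u.subpaths:
            c = c_in
            for layer in sp:
                yield layer, c
                c = layer.n_kernels
        c_in = u.n_out
    yield spec.recon, c_in


def count_parameters(spec: MFCNSpec) -> int:
    """Total weights + biases: sum of ``s_k^2 * c_in * n_k + n_k``."""
    return sum(l.kernel_size**2 * c * l.n_kernels + l.n_kernels for l, c in _iter_layers(spec))


# ---------------------------------------------------------------------------
# parameters


@dataclass
class LayerParams:
    """Kernels ``W`` with shape (n_out, c_in, k, k) and biases ``b`` (n_out,)."""

    W: np.ndarray
    b: np.ndarray


@dataclass
class MFUParams:
    main: LayerParams
    subpaths: list[list[LayerParams]]


@dataclass
class NetworkParams:
    spec: MFCNSpec
    units: list[MFUParams]
    recon: LayerParams
    init: dict = field(default_factory=dict)

    def layers(self) -> list[LayerParams]:
        out = []
        for u in self.units:
            out.append(u.main)
            for sp in u.subpaths:
                out.extend(sp)
        out.append(self.recon)
        return out

    def n_parameters(self) -> int:
        return sum(p.W.size + p.b.size for p in self.layers())

    def copy(self) -> "NetworkParams":
        return copy.deepcopy(self)


def build_network(spec: MFCNSpec, seed: int, init_std: float = 0.001) -> NetworkParams:
    """Initialise kernels ~ Gaussian(0, ``init_std``), biases 0; seeded."""
    rng = np.random.default_rng(seed)

    def make(layer: ConvLayerSpec, c_in: int) -> LayerParams:
        W = rng.normal(0.0, init_std, (layer.n_kernels, c_in, layer.kernel_size, layer.kernel_size))
        return LayerParams(W=W, b=np.zeros(layer.n_kernels))

    units = []
    c_in = 1
    for u in spec.units:
        main = make(u.main, c_in)
        sps = []
        for sp in u.subpaths:
            c = c_in
            layers = []
            for layer in sp:
                layers.append(make(layer, c))
                c = layer.n_kernels
            sps.append(layers)
        units.append(MFUParams(main=main, subpaths=sps))
        c_in = u.n_out
    recon = make(spec.recon, c_in)
    return NetworkParams(
        spec=spec, units=units, recon=recon,
        init={"distribution": "gaussian", "std": init_std, "seed": seed},
    )


def save_params(params: NetworkParams, path) -> None:
    """Checkpoint parameters with the spec embedded."""
    arrays = {}
    for i, p in enumerate(params.layers()):
        arrays[f"W{i}"] = p.W
        arrays[f"b{i}"] = p.b
    np.savez(path, __spec__=json.dumps(params.spec.to_dict()),
             __init__=json.dumps(params.init), **arrays)


def load_params(path) -> NetworkParams:
    with np.load(path, allow_pickle=False) as z:
        spec = MFCNSpec.from_dict(json.loads(str(z["__spec__"])))
        init = json.loads(str(z["__init__"]))
        params = build_network(spec, seed=0)
        for i, p in enumerate(params.layers()):
            p.W = z[f"W{i}"]
            p.b = z[f"b{i}"]
        params.init = init
    return params


# ---------------------------------------------------------------------------
# convolution kernels (im2col)


#: below this many im2col columns (C * k * k) the materialised-columns route
#: is faster; above it the per-offset matmul route avoids a large copy
_IM2COL_MAX_COLS = 128


def _conv_forward(x: np.ndarray, p: LayerParams):
    """Same-padded stride-1 convolution (cross-correlation convention).

    Operates on channels-last activations ``(B, H, W, C)`` in the dtype of
    ``x`` (float32 for training speed, float64 for oracle-grade accuracy);
    kernels stay in ``(F, C, k, k)`` layout.  Small-column layers use
    materialised im2col columns, large ones a matmul per kernel offset.
    """
    B, H, W, C = x.shape
    F, Cw, k, _ = p.W.shape
    if C != Cw:
        raise SpecError(f"channel mismatch: input has {C}, layer expects {Cw}")
    Wl = p.W.astype(x.dtype, copy=False)
    bl = p.b.astype(x.dtype, copy=False)
    r = k // 2
    cols = None
    if r == 0:
        y = x.reshape(-1, C) @ Wl[:, :, 0, 0].T
        xp = x
    else:
        xp = np.pad(x, ((0, 0), (r, r), (r, r), (0, 0)))
        if C * k * k <= _IM2COL_MAX_COLS:
            win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
            cols = win.reshape(B * H * W, C * k * k)  # (C, k, k) flattened
            y = cols @ Wl.transpose(1, 2, 3, 0).reshape(C * k * k, F)
        else:
            y = np.zeros((B * H * W, F), dtype=x.dtype)
            for i in range(k):
                for j in range(k):
                    xv = xp[:, i : i + H, j : j + W, :].reshape(-1, C)
                    y += xv @ Wl[:, :, i, j].T
    y = (y + bl).reshape(B, H, W, F)
    return y, (xp, cols, x.shape, k)


def _conv_backward(dy: np.ndarray, p: LayerParams, cache, need_dx: bool = True):
    """Gradient of a same-padded convolution.

    Three routes, picked by column count: reuse cached input-side im2col
    columns when available; otherwise, when the *output*-side column count
    ``F * k * k`` is small, express both dx (correlation of dy with flipped
    kernels) and dW (correlation of the padded input with doubly padded dy)
    as dy-side im2col matmuls; else fall back to a matmul per offset.
    Returns ``(dx or None, layer gradients)``.
    """
    xp, cols, x_shape, k = cache
    B, H, W, C = x_shape
    F = p.W.shape[0]
    Wl = p.W.astype(dy.dtype, copy=False)
    r = k // 2
    dy_mat = dy.reshape(B * H * W, F)
    db = dy_mat.sum(axis=0)
    dW = np.empty(p.W.shape, dtype=dy.dtype)
    swv = np.lib.stride_tricks.sliding_window_view
    if r == 0:
        dW[:, :, 0, 0] = dy_mat.T @ xp.reshape(-1, C)
        dx = (dy_mat @ Wl[:, :, 0, 0]).reshape(x_shape) if need_dx else None
        return dx, LayerParams(W=dW, b=db)
    dx = None
    if cols is not None:
        dW[...] = (dy_mat.T @ cols).reshape(F, C, k, k)
        if need_dx:
            dcols = (dy_mat @ Wl.reshape(F, C * k * k)).reshape(B, H, W, C, k, k)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, i : i + H, j : j + W, :] += dcols[:, :, :, :, i, j]
            dx = dxp[:, r : r + H, r : r + W, :]
    elif F * k * k <= _IM2COL_MAX_COLS:
        dyp2 = np.pad(dy, ((0, 0), (2 * r, 2 * r), (2 * r, 2 * r), (0, 0)))
        cols2 = swv(dyp2, (k, k), axis=(1, 2)).reshape(-1, F * k * k)
        dWfl = (xp.reshape(-1, C).T @ cols2).reshape(C, F, k, k)
        dW[...] = dWfl.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        if need_dx:
            dyp = np.pad(dy, ((0, 0), (r, r), (r, r), (0, 0)))
            cols_dy = swv(dyp, (k, k), axis=(1, 2)).reshape(B * H * W, F * k * k)
            Wt = np.ascontiguousarray(
                Wl[:, :, ::-1, ::-1].transpose(0, 2, 3, 1)
            ).reshape(F * k * k, C)
            dx = (cols_dy @ Wt).reshape(B, H, W, C)
    else:
        dxp = np.zeros_like(xp) if need_dx else None
        for i in range(k):
            for j in range(k):
                xv = xp[:, i : i + H, j : j + W, :].reshape(-1, C)
                dW[:, :, i, j] = dy_mat.T @ xv
                if need_dx:
                    dxp[:, i : i + H, j : j + W, :] += (dy_mat @ Wl[:, :, i, j]).reshape(B, H, W, C)
        if need_dx:
            dx = dxp[:, r : r + H, r : r + W, :]
    return dx, LayerParams(W=dW, b=db)


# ---------------------------------------------------------------------------
# forward / backward over the full network


def _mfu_forward(x: np.ndarray, uspec: MFUSpec, uparams: MFUParams, need_cache: bool):
    caches = {"x_shape": x.shape}
    pre, main_cache = _conv_forward(x, uparams.main)
    main = np.maximum(pre, 0.0)
    caches["main"] = (main_cache, pre)
    out = main
    sub_caches = []
    for sp_spec, sp_params in zip(uspec.subpaths, uparams.subpaths):
        z = x
        layer_caches = []
        for li, (lspec, lparams) in enumerate(zip(sp_spec, sp_params)):
            zpre, c = _conv_forward(z, lparams)
            last = li == len(sp_spec) - 1
            apply_relu = lspec.relu or (last and uspec.relu_before_fusion)
            z = np.maximum(zpre, 0.0) if apply_relu else zpre
            layer_caches.append((c, zpre, apply_relu))
        out = out + z
        sub_caches.append(layer_caches)
    caches["subpaths"] = sub_caches
    return out, (caches if need_cache else None)


def _mfu_backward(dout: np.ndarray, uspec: MFUSpec, uparams: MFUParams, caches,
                  need_dx: bool = True):
    main_cache, pre = caches["main"]
    dmain = dout * (pre > 0)
    dx, gmain = _conv_backward(dmain, uparams.main, main_cache, need_dx=need_dx)
    gsubs = []
    for sp_params, layer_caches in zip(uparams.subpaths, caches["subpaths"]):
        dz = dout
        glayers = [None] * len(sp_params)
        for li in range(len(sp_params) - 1, -1, -1):
            c, zpre, applied_relu = layer_caches[li]
            if applied_relu:
                dz = dz * (zpre > 0)
            dz, g = _conv_backward(dz, sp_params[li], c,
                                   need_dx=need_dx or li > 0)
            glayers[li] = g
        if need_dx:
            dx = dx + dz
        gsubs.append(glayers)
    return dx, MFUParams(main=gmain, subpaths=gsubs)


def forward_batch(params: NetworkParams, x: np.ndarray, need_cache: bool = False):
    """Forward pass on a batch ``(B, 1, H, W)``; returns ``(y, cache)``.

    Computation runs in float32 when ``x`` is float32, float64 otherwise.
    """
    x = np.asarray(x)
    if x.dtype != np.float32:
        x = x.astype(np.float64, copy=False)
    if x.ndim != 4:
        raise DataError("expected a (B, C, H, W) batch")
    if not np.isfinite(x).all():
        raise DataError("non-finite input")
    x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # channels-last internally
    caches = []
    for uspec, uparams in zip(params.spec.units, params.units):
        x, c = _mfu_forward(x, uspec, uparams, need_cache)
        caches.append(c)
    y, recon_cache = _conv_forward(x, params.recon)
    caches.append(recon_cache)
    return y.transpose(0, 3, 1, 2), (caches if need_cache else None)


def backward_batch(params: NetworkParams, cache, dy: np.ndarray):
    """Backpropagate ``dy`` (gradient of loss w.r.t. output); returns grads
    shaped like ``params`` (as a :class:`NetworkParams`)."""
    dy = np.ascontiguousarray(np.asarray(dy).transpose(0, 2, 3, 1))
    *unit_caches, recon_cache = cache
    dx, grecon = _conv_backward(dy, params.recon, recon_cache)
    gunits: list[MFUParams | None] = [None] * len(params.units)
    for i in range(len(params.units) - 1, -1, -1):
        dx, g = _mfu_backward(dx, params.spec.units[i], params.units[i],
                              unit_caches[i], need_dx=i > 0)
        gunits[i] = g
    return NetworkParams(spec=params.spec, units=gunits, recon=grecon,
                         init={"gradient": True})


def zero_like_grads(params: NetworkParams) -> NetworkParams:
    g = params.copy()
    for p in g.layers():
        p.W = np.zeros_like(p.W)
        p.b = np.zeros_like(p.b)
    return g


def _as_batch(image: np.ndarray) -> tuple[np.ndarray, bool]:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image[None, None], True
    if image.ndim == 4:
        return image, False
    raise DataError("expected a 2D image or a (B, C, H, W) batch")


def forward_mfu(x: np.ndarray, uspec: MFUSpec, uparams: MFUParams) -> np.ndarray:
    """Evaluate one fusion unit.  Accepts (C, H, W) or (B, C, H, W)."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.ndim != 4:
        raise DataError("expected (C, H, W) or (B, C, H, W) feature maps")
    xl = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
    y, _ = _mfu_forward(xl, uspec, uparams, need_cache=False)
    y = y.transpose(0, 3, 1, 2)
    return y[0] if single else y


def conv_layer(x: np.ndarray, p: LayerParams) -> np.ndarray:
    """Single same-padded convolution on (C, H, W) or (B, C, H, W) input."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 3
    if single:
        x = x[None]
    y, _ = _conv_forward(np.ascontiguousarray(x.transpose(0, 2, 3, 1)), p)
    y = y.transpose(0, 3, 1, 2)
    return y[0] if single else y


def forward(params: NetworkParams, image: np.ndarray) -> np.ndarray:
    """Fully convolutional forward pass on a single-channel image.

    Accepts whole slices or patches of any size not smaller than the
    largest kernel; output spatial size equals input size.
    """
    xb, squeeze = _as_batch(image)
    kmax = max(l.kernel_size for l, _ in _iter_layers(params.spec))
    if min(xb.shape[2], xb.shape[3]) < kmax:
        raise DataError(
            f"image {xb.shape[2]}x{xb.shape[3]} smaller than the largest kernel ({kmax})"
        )
    y, _ = forward_batch(params, xb)
    return y[0, 0] if squeeze else y
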