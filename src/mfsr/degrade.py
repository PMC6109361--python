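"""Degradation model and patch-pair extraction.

A low-resolution slice is produced from a high-resolution one by blurring,
downsampling by an integer factor ``f`` and bicubic re-interpolation back
onto the HR grid (pre-upsampling convention): the degraded slice is at the
same time the bicubic-baseline reconstruction.  Training data are aligned
33x33 LR/HR patch pairs sampled at random mask locations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from mfsr.errors import DataError, SizingError
from mfsr.phantom import LabeledVolume

__all__ = [
    "DegradeSpec",
    "SlicePair",
    "PatchSet",
    "degrade_slice",
    "degrade_volume",
    "extract_patch_pairs",
    "build_patchset",
]

BLUR_KINDS = ("bicubic-antialias", "gaussian")


@dataclass(frozen=True)
class DegradeSpec:
    """Degradation operator parameters: ``f`` houses D, the blur houses S,
    ``noise_sigma`` houses e.  Interpolation is always bicubic."""

    factor: int = 3
    blur: str = "bicubic-antialias"
    gaussian_sigma: float | None = None
    noise_sigma: float = 0.0

    def __post_init__(self):
        if int(self.factor) != self.factor or self.factor < 1:
            raise DataError(f"upscale factor must be an integer >= 1, got {self.factor}")
        if self.blur not in BLUR_KINDS:
            raise DataError(f"blur must be one of {BLUR_KINDS}, got {self.blur!r}")
        if self.blur == "gaussian" and not (self.gaussian_sigma and self.gaussian_sigma > 0):
            raise DataError("gaussian blur requires gaussian_sigma > 0")
        if self.noise_sigma < 0:
            raise DataError("noise sigma must be >= 0")

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "blur": self.blur,
            "gaussian_sigma": self.gaussian_sigma,
            "noise_sigma": self.noise_sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DegradeSpec":
        return cls(**d)


@dataclass
class SlicePair:
    """An HR slice and its degraded counterpart resampled onto the HR grid."""

    hr: np.ndarray
    lr: np.ndarray
    mask: np.ndarray
    spec: DegradeSpec
    index: int = 0  # axial slice index in the source volume

    def __post_init__(self):
        self.hr = np.asarray(self.hr, dtype=np.float64)
        self.lr = np.asarray(self.lr, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if not (self.hr.shape == self.lr.shape == self.mask.shape):
            raise DataError("hr, lr and mask must share one shape")
        if self.lr.min() < -1e-9 or self.lr.max() > 1 + 1e-9:
            raise DataError("lr intensities must lie in [0, 1]")


@dataclass
class PatchSet:
    """Aligned LR/HR patch pairs with their source coordinates.

    ``coords`` rows are (slice index, centre row, centre col), 0-based.
    """

    lr: np.ndarray  # (m, p, p)
    hr: np.ndarray  # (m, p, p)
    coords: np.ndarray  # (m, 3) int
    patch_size: int
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lr = np.asarray(self.lr, dtype=np.float64)
        self.hr = np.asarray(self.hr, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        p = self.patch_size
        if self.lr.shape != self.hr.shape or self.lr.shape[1:] != (p, p):
            raise DataError("patch arrays must be (m, p, p) and aligned")
        if self.coords.shape != (len(self.lr), 3):
            raise DataError("coords must be (m, 3)")

    def __len__(self) -> int:
        return len(self.lr)

    @property
    def m(self) -> int:
        return len(self.lr)

    def save(self, path) -> None:
        """Write to an HDF5 container (two stacked arrays + coordinates)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("lr", data=self.lr)
            f.create_dataset("hr", data=self.hr)
            f.create_dataset("coords", data=self.coords)
            f.attrs["patch_size"] = self.patch_size
            f.attrs["seed"] = self.seed
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path) -> "PatchSet":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                lr=f["lr"][...],
                hr=f["hr"][...],
                coords=f["coords"][...],
                patch_size=int(f.attrs["patch_size"]),
                seed=int(f.attrs["seed"]),
                meta=json.loads(f.attrs.get("meta", "{}")),
            )

    @classmethod
    def concatenate(cls, sets: list["PatchSet"]) -> "PatchSet":
        if not sets:
            raise DataError("nothing to concatenate")
        p = sets[0].patch_size
        if any(s.patch_size != p for s in sets):
            raise DataError("patch sizes differ")
        return cls(
            lr=np.concatenate([s.lr for s in sets]),
            hr=np.concatenate([s.hr for s in sets]),
            coords=np.concatenate([s.coords for s in sets]),
            patch_size=p,
            seed=sets[0].seed,
            meta={"concatenated": len(sets)},
        )


def degrade_slice(
    hr: np.ndarray,
    mask: np.ndarray,
    spec: DegradeSpec,
    rng: np.random.Generator | None = None,
    index: int = 0,
) -> SlicePair:
    """Blur, downsample by ``spec.factor`` and bicubically re-upsample ``hr``.

    With ``factor == 1``, no blur and no noise the input is reproduced
    bit-for-bit.  Boundary handling: the resampling filters use reflective
    padding, so a constant image stays constant everywhere including the
    boundary.  ``rng`` is only consulted when ``noise_sigma > 0``.
    """
    hr = np.asarray(hr, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if hr.ndim != 2 or hr.shape != mask.shape:
        raise DataError("hr and mask must be 2D arrays of one shape")
    f = spec.factor
    if f > min(hr.shape):
        raise SizingError(f"factor {f} exceeds image dims {hr.shape}")

    if spec.blur == "gaussian":
        blurred = ndimage.gaussian_filter(hr, sigma=spec.gaussian_sigma, mode="reflect")
        down = blurred[::f, ::f]
    else:  # antialiased bicubic: blur implicit in the resampling filter
        if f == 1:
            down = hr
        else:
            lo_shape = (int(np.ceil(hr.shape[0] / f)), int(np.ceil(hr.shape[1] / f)))
            down = resize(hr, lo_shape, order=3, mode="reflect", anti_aliasing=True)

    if down.shape == hr.shape:
        lr = down.copy()
    else:
        lr = resize(down, hr.shape, order=3, mode="reflect", anti_aliasing=False)

    if spec.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        lr = lr + rng.normal(0.0, spec.noise_sigma, lr.shape)

    lr = np.clip(lr, 0.0, 1.0)
    return SlicePair(hr=hr, lr=lr, mask=mask, spec=spec, index=index)


def degrade_volume(
    vol: LabeledVolume, spec: DegradeSpec, seed: int | None = None
) -> list[SlicePair]:
    """One :class:`SlicePair` per axial slice intersecting the brain mask."""
    rng = np.random.default_rng(seed) if spec.noise_sigma > 0 else None
    pairs = []
    for k in range(vol.n_slices):
        hr, mask = vol.slice(k)
        if not mask.any():
            continue
        pairs.append(degrade_slice(hr, mask, spec, rng=rng, index=k))
    if not pairs:
        raise DataError("no axial slice intersects the mask")
    return pairs


def admissible_centers(mask: np.ndarray, patch_size: int) -> np.ndarray:
    """Centres whose patch lies fully inside the image and inside the mask."""
    r = patch_size // 2
    h, w = mask.shape
    ok = np.zeros_like(mask, dtype=bool)
    if h >= patch_size and w >= patch_size:
        ok[r : h - r, r : w - r] = True
    ok &= mask
    return np.argwhere(ok)


def extract_patch_pairs(
    pair: SlicePair,
    n_per_slice: int = 600,
    patch_size: int = 33,
    seed: int = 0,
) -> PatchSet:
    """Sample ``n_per_slice`` aligned LR/HR patch pairs from one slice.

    Centres are drawn uniformly, with replacement, among pixels that lie in
    the mask and whose ``patch_size`` x ``patch_size`` patch fits entirely
    inside the image.  Deterministic given ``seed``.
    """
    if patch_size % 2 != 1:
        raise DataError("patch size must be odd")
    if n_per_slice < 1:
        raise DataError("n_per_slice must be >= 1")
    centers = admissible_centers(pair.mask, patch_size)
    if len(centers) == 0:
        raise DataError(
            f"no admissible patch centre: mask has {int(pair.mask.sum())} pixels, "
            f"image {pair.mask.shape}, patch {patch_size}"
        )
    rng = np.random.default_rng(seed)
    picks = centers[rng.integers(0, len(centers), size=n_per_slice)]
    r = patch_size // 2
    lr = np.empty((n_per_slice, patch_size, patch_size))
    hr = np.empty_like(lr)
    coords = np.empty((n_per_slice, 3), dtype=np.int64)
    for i, (cr, cc) in enumerate(picks):
        lr[i] = pair.lr[cr - r : cr + r + 1, cc - r : cc + r + 1]
        hr[i] = pair.hr[cr - r : cr + r + 1, cc - r : cc + r + 1]
        coords[i] = (pair.index, cr, cc)
    return PatchSet(lr=lr, hr=hr, coords=coords, patch_size=patch_size, seed=seed,
                    meta={"n_per_slice": n_per_slice, "spec": pair.spec.to_dict()})


def build_patchset(
    pairs: list[SlicePair],
    n_per_slice: int = 600,
    patch_size: int = 33,
    seed: int = 0,
) -> PatchSet:
    """Patch pairs pooled over many slices, one seeded stream per slice."""
    ss = np.random.SeedSequence(seed)
    subsets = []
    for pair, child in zip(pairs, ss.spawn(len(pairs))):
        sub_seed = int(np.random.default_rng(child).integers(0, 2**31 - 1))
        subsets.append(extract_patch_pairs(pair, n_per_slice, patch_size, seed=sub_seed))
    out = PatchSet.concatenate(subsets)
    out.seed = seed
    return out
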