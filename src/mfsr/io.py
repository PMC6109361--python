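"""NIfTI volume I/O and image export helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from mfsr.errors import DataError
from mfsr.phantom import LabeledVolume

__all__ = ["read_volume", "write_volume", "export_slice_png", "mask_path_for"]


def mask_path_for(path) -> Path:
    """Companion mask path convention: ``foo.nii[.gz]`` -> ``foo_mask.nii[.gz]``."""
    p = Path(path)
    suffix = "".join(p.suffixes[-2:]) if p.name.endswith(".nii.gz") else p.suffix
    stem = p.name[: -len(suffix)]
    return p.with_name(f"{stem}_mask{suffix}")


def read_volume(path, mask_path=None) -> LabeledVolume:
    """Load a single-channel NIfTI volume (canonical orientation).

    Intensities are min-max normalized to [0, 1]; the original range is
    recorded in ``meta`` for metric rescaling.  The mask comes from
    ``mask_path``, else from the ``*_mask`` companion file, else from
    nonzero thresholding (with a warning when that yields the full frame).
    """
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DataError(f"unsupported NIfTI format: expected 3D, got {data.ndim}D")
    data = data.astype(np.float64)
    lo, hi = float(data.min()), float(data.max())
    norm = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)

    if mask_path is None:
        candidate = mask_path_for(path)
        mask_path = candidate if candidate.exists() else None
    if mask_path is not None:
        mimg = nib.as_closest_canonical(nib.load(str(mask_path)))
        mask = np.asanyarray(mimg.dataobj) > 0
        if mask.shape != norm.shape:
            raise DataError("mask shape differs from volume shape")
    else:
        mask = data > 0
        if mask.all():
            import warnings

            warnings.warn("volume has no zero background; using a full mask")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    labels = mask.astype(np.int32)
    return LabeledVolume(
        intensity=norm, labels=labels, mask=mask, spacing=spacing,
        meta={"source": str(path), "orig_min": lo, "orig_max": hi,
              "affine": img.affine.tolist()},
    )


def write_volume(vol: LabeledVolume, path, mask_path=None) -> None:
    """Write intensity and mask as NIfTI files with the recorded spacing."""
    affine = np.asarray(vol.meta["affine"]) if "affine" in vol.meta else np.diag(
        list(vol.spacing) + [1.0]
    )
    img = nib.Nifti1Image(vol.intensity.astype(np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    mimg = nib.Nifti1Image(vol.mask.astype(np.uint8), affine)
    mimg.header.set_zooms(vol.spacing)
    nib.save(mimg, str(mask_path if mask_path is not None else mask_path_for(path)))


def export_slice_png(images, path) -> None:
    """Write one image, or a horizontal triptych of images, as 8-bit PNG."""
    import imageio.v3 as iio

    if isinstance(images, (list, tuple)):
        sep = np.ones((images[0].shape[0], 2))
        panels = []
        for i, im in enumerate(images):
            panels.append(np.clip(im, 0, 1))
            if i < len(images) - 1:
                panels.append(sep)
        canvas = np.hstack(panels)
    else:
        canvas = np.clip(images, 0, 1)
    iio.imwrite(Path(path), (255 * canvas).astype(np.uint8))
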