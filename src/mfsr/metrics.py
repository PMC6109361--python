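"""Masked image-quality metrics: RMSE, SNR, PSNR and SSIM.

All metric functions take images normalized to [0, 1] and evaluate over a
binary region Ω carried by :class:`MetricSpec`.  RMSE and PSNR are reported
on a configurable intensity scale (default 0-255, the convention that makes
published bicubic RMSE and PSNR mutually consistent at R = 255); SNR is
scale-invariant.  PSNR defaults to the standard ``20*log10(R / RMSE)`` form;
a literal factor-10 variant is available behind a flag.  SSIM defaults to
the windowed form (11x11 Gaussian window, sigma 1.5) averaged over window
centres in Ω; a global single-statistic form is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from mfsr.errors import DataError

__all__ = [
    "MetricSpec",
    "MetricsReport",
    "rmse",
    "snr",
    "psnr",
    "psnr_from_rmse",
    "ssim",
    "evaluate_methods",
]


@dataclass(frozen=True)
class MetricSpec:
    """Evaluation region and scale conventions.

    ``mask`` is Ω (None = full frame).  ``intensity_scale`` multiplies the
    [0, 1] inputs before RMSE/PSNR/SSIM; ``r_mode`` selects the PSNR peak R:
    ``"fixed"`` uses ``r_value``, ``"lr-max"`` uses the maximum of the
    degraded (second) image on the metric scale.
    """

    mask: np.ndarray | None = None
    intensity_scale: float = 255.0
    r_mode: str = "fixed"
    r_value: float = 255.0
    psnr_form: str = "standard"  # "standard": 20*log10(R/RMSE); "literal": 10*log10
    ssim_mode: str = "windowed"  # or "global"
    ssim_window: int = 11
    ssim_sigma: float = 1.5
    dynamic_range: float = 255.0  # L in the SSIM constants
    k1: float = 0.01
    k2: float = 0.03

    def __post_init__(self):
        if self.r_mode not in ("fixed", "lr-max"):
            raise DataError(f"unknown r_mode {self.r_mode!r}")
        if self.psnr_form not in ("standard", "literal"):
            raise DataError(f"unknown psnr_form {self.psnr_form!r}")
        if self.ssim_mode not in ("windowed", "global"):
            raise DataError(f"unknown ssim_mode {self.ssim_mode!r}")
        if self.r_mode == "fixed" and self.r_value <= 0:
            raise DataError("R must be > 0")
        if self.k1 <= 0 or self.k2 <= 0:
            raise DataError("SSIM constants must be positive")
        if self.dynamic_range <= 0:
            raise DataError("dynamic range L must be > 0")
        if self.mask is not None and not np.asarray(self.mask).any():
            raise DataError("evaluation region is empty")

    def with_mask(self, mask: np.ndarray) -> "MetricSpec":
        return replace(self, mask=mask)


def _region(x: np.ndarray, spec: MetricSpec) -> np.ndarray:
    if spec.mask is None:
        return np.ones(x.shape, dtype=bool)
    m = np.asarray(spec.mask).astype(bool)
    if m.shape != x.shape:
        raise DataError(f"mask shape {m.shape} != image shape {x.shape}")
    if not m.any():
        raise DataError("evaluation region is empty")
    return m


def rmse(x: np.ndarray, y: np.ndarray, spec: MetricSpec = MetricSpec()) -> float:
    """Root-mean-square error over Ω, on the spec's intensity scale."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("shapes differ")
    m = _region(x, spec)
    d = (x[m] - y[m]) * spec.intensity_scale
    return float(np.sqrt(np.mean(d**2)))


def snr(x: np.ndarray, y: np.ndarray, spec: MetricSpec = MetricSpec()) -> float:
    """Signal-to-noise ratio 10*log10(sum x^2 / sum (x-y)^2) over Ω, in dB.

    ``x`` is the reference.  Returns ``inf`` when the residual vanishes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("shapes differ")
    m = _region(x, spec)
    sig = float(np.sum(x[m] ** 2))
    if sig == 0.0:
        raise DataError("reference has zero energy over the evaluation region")
    res = float(np.sum((x[m] - y[m]) ** 2))
    if res == 0.0:
        return float("inf")
    return float(10.0 * np.log10(sig / res))


def _peak(y: np.ndarray, spec: MetricSpec) -> float:
    if spec.r_mode == "fixed":
        return spec.r_value
    return float(np.asarray(y).max() * spec.intensity_scale)


def psnr_from_rmse(rmse_value: float, R: float = 255.0, form: str = "standard") -> float:
    """PSNR implied by an RMSE value: ``20*log10(R/RMSE)`` (standard form) or
    ``10*log10(R/RMSE)`` (literal form)."""
    if rmse_value == 0:
        return float("inf")
    factor = 20.0 if form == "standard" else 10.0
    return float(factor * np.log10(R / rmse_value))


def psnr(x: np.ndarray, y: np.ndarray, spec: MetricSpec = MetricSpec()) -> float:
    """Peak SNR over Ω in dB; ``inf`` at zero residual."""
    r = rmse(x, y, spec)
    return psnr_from_rmse(r, R=_peak(y, spec), form=spec.psnr_form)


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    r = size // 2
    g = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    w = np.outer(g, g)
    return w / w.sum()


def ssim(x: np.ndarray, y: np.ndarray, spec: MetricSpec = MetricSpec()) -> float:
    """Structural similarity with constants c1 = (k1 L)^2, c2 = (k2 L)^2.

    Windowed mode computes the local SSIM map with the spec's Gaussian
    window (reflective boundaries) and averages over pixels whose window
    centre lies in Ω; global mode evaluates the formula once from the
    statistics of the Ω pixels.
    """
    x = np.asarray(x, dtype=float) * spec.intensity_scale
    y = np.asarray(y, dtype=float) * spec.intensity_scale
    if x.shape != y.shape:
        raise DataError("shapes differ")
    L = spec.dynamic_range
    c1 = (spec.k1 * L) ** 2
    c2 = (spec.k2 * L) ** 2
    m = _region(x, spec)

    if spec.ssim_mode == "global":
        xs, ys = x[m], y[m]
        mx, my = xs.mean(), ys.mean()
        vx, vy = xs.var(), ys.var()
        cov = ((xs - mx) * (ys - my)).mean()
        val = ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
        return float(val)

    if min(x.shape) < spec.ssim_window:
        raise DataError(
            f"SSIM window {spec.ssim_window} larger than image {x.shape}"
        )
    w = _gaussian_window(spec.ssim_window, spec.ssim_sigma)

    def filt(a):
        return ndimage.correlate(a, w, mode="reflect")

    mx, my = filt(x), filt(y)
    vx = filt(x * x) - mx**2
    vy = filt(y * y) - my**2
    cov = filt(x * y) - mx * my
    num = (2 * mx * my + c1) * (2 * cov + c2)
    den = (mx**2 + my**2 + c1) * (vx + vy + c2)
    smap = num / den
    return float(smap[m].mean())


@dataclass
class MetricsReport:
    """Per-method, per-scale metric table with per-slice detail rows."""

    rows: pd.DataFrame  # columns: method, scale, slice, n_pixels, rmse, snr, psnr, ssim
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self):
        g = self.rows.groupby(["method", "scale"])
        # mask-weighted means across slices
        def agg(df):
            w = df["n_pixels"] / df["n_pixels"].sum()
            return pd.Series({k: float(np.sum(w * df[k])) for k in ("rmse", "snr", "psnr", "ssim")})
        self.summary = g.apply(agg, include_groups=False).reset_index()

    def row(self, method: str, scale: int | None = None) -> pd.Series:
        s = self.summary[self.summary["method"] == method]
        if scale is not None:
            s = s[s["scale"] == scale]
        if len(s) == 0:
            raise DataError(f"no results for method {method!r}")
        return s.iloc[0]

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.summary.to_json(path, orient="records", indent=2)

    def grid(self) -> pd.DataFrame:
        """Metric x scale x method grid (published-table shape)."""
        long = self.summary.melt(id_vars=["method", "scale"],
                                 value_vars=["rmse", "snr", "psnr", "ssim"],
                                 var_name="metric")
        return long.pivot_table(index=["metric", "scale"], columns="method",
                                values="value", sort=False)


def evaluate_methods(
    hr,
    reconstructions: dict,
    spec: MetricSpec = MetricSpec(),
    masks=None,
    scale: int = 0,
) -> MetricsReport:
    """Evaluate every method's reconstruction(s) against ``hr``.

    ``hr`` may be a single 2D image or a list of slices; each method maps to
    an image or an equal-length list.  ``masks`` overrides the spec mask
    per slice.  Raises naming the method if one is missing an output.
    """
    hr_list = hr if isinstance(hr, (list, tuple)) else [hr]
    if masks is not None and not isinstance(masks, (list, tuple)):
        masks = [masks]
    records = []
    for method, recon in reconstructions.items():
        rec_list = recon if isinstance(recon, (list, tuple)) else [recon]
        if len(rec_list) != len(hr_list):
            raise DataError(
                f"method {method!r}: {len(rec_list)} outputs for {len(hr_list)} slices"
            )
        for i, (h, r) in enumerate(zip(hr_list, rec_list)):
            if r is None:
                raise DataError(f"method {method!r} is missing output for slice {i}")
            sspec = spec.with_mask(masks[i]) if masks is not None else spec
            m = _region(np.asarray(h), sspec)
            records.append({
                "method": method, "scale": scale, "slice": i,
                "n_pixels": int(m.sum()),
                "rmse": rmse(h, r, sspec),
                "snr": snr(h, r, sspec),
                "psnr": psnr(h, r, sspec),
                "ssim": ssim(h, r, sspec),
            })
    return MetricsReport(rows=pd.DataFrame.from_records(records))
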