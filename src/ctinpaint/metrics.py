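"""Image-quality metrics with region restriction.

MSE, RMSE = sqrt(MSE), PSNR = 10 log10(s^2 / MSE) with s = 255 for 8-bit
data, and SSIM

    SSIM(x, y) = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
                 / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)),

with C1 = (k1 L)^2, C2 = (k2 L)^2, k1 = 0.01, k2 = 0.03, L = 255.

Every metric can be evaluated over the whole image or restricted to an
arbitrary pixel region — in particular the missing-tissue generation region
of a truncation mask, the evaluation area of interest for completion
quality. SSIM has two modes: *global* (one set of moments over the region,
the formula applied once) and *windowed* (the field-standard 11x11 Gaussian
sliding window, sigma 1.5; the SSIM map is averaged over window centers
lying in the region). SSIM is not clamped: anti-correlated inputs can yield
negative values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import CTSlice
from .preprocess import TruncationMask

__all__ = ["SSIMConstants", "MetricsReport", "mse_rmse", "psnr", "ssim",
           "evaluate_pair"]


@dataclass
class SSIMConstants:
    k1: float = 0.01
    k2: float = 0.03
    L: float = 255.0  # dynamic range
    mode: str = "windowed"  # windowed | global
    window_size: int = 11
    sigma: float = 1.5  # Gaussian window width

    @property
    def C1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.k2 * self.L) ** 2

    def validate(self) -> None:
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("C1 and C2 must be positive")
        if self.mode not in ("windowed", "global"):
            raise ValueError("mode must be 'windowed' or 'global'")
        if self.window_size % 2 == 0:
            raise ValueError("window_size must be odd")


@dataclass
class MetricsReport:
    region: str  # whole | generation_only
    ssim: float
    rmse: float
    psnr: float
    n_pixels: int
    empty: bool = False

    @property
    def psnr_is_infinite(self) -> bool:
        return math.isinf(self.psnr)


def _region_mask(x: np.ndarray, region) -> np.ndarray:
    if region is None:
        return np.ones(x.shape, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if region.shape != x.shape:
        raise ValueError("region shape must match image shape")
    return region


def mse_rmse(x: np.ndarray, y: np.ndarray, region=None) -> tuple[float, float]:
    """Mean squared error and its square root over the region."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("image shapes must agree")
    r = _region_mask(x, region)
    if not r.any():
        raise ValueError("empty evaluation region")
    mse = float(np.mean((x[r] - y[r]) ** 2))
    return mse, math.sqrt(mse)


def psnr(x: np.ndarray, y: np.ndarray, region=None,
         consts: SSIMConstants = SSIMConstants()) -> float:
    """Peak signal-to-noise ratio in dB (s = consts.L); +inf when the
    images agree exactly on the region."""
    mse, _ = mse_rmse(x, y, region)
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(consts.L ** 2 / mse)


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    r = size // 2
    g = np.exp(-0.5 * ((np.arange(size) - r) / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def _ssim_global(x, y, r, consts) -> float:
    xr, yr = x[r], y[r]
    mx, my = xr.mean(), yr.mean()
    vx, vy = xr.var(), yr.var()
    cov = ((xr - mx) * (yr - my)).mean()
    c1, c2 = consts.C1, consts.C2
    return float(((2 * mx * my + c1) * (2 * cov + c2))
                 / ((mx * mx + my * my + c1) * (vx + vy + c2)))


def _ssim_windowed(x, y, r, consts) -> float:
    size = consts.window_size
    pad = size // 2
    if x.shape[0] < size or x.shape[1] < size:
        warnings.warn("region smaller than the SSIM window; falling back to "
                      "global mode", stacklevel=3)
        return _ssim_global(x, y, r, consts)
    k = _gaussian_kernel(size, consts.sigma)

    def f(img):
        return ndimage.correlate(img, k, mode="constant")

    mx, my = f(x), f(y)
    mxx, myy, mxy = f(x * x), f(y * y), f(x * y)
    vx = mxx - mx * mx
    vy = myy - my * my
    cov = mxy - mx * my
    c1, c2 = consts.C1, consts.C2
    smap = ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx * mx + my * my + c1) * (vx + vy + c2))
    valid = np.zeros(x.shape, dtype=bool)
    valid[pad:x.shape[0] - pad, pad:x.shape[1] - pad] = True
    sel = r & valid
    if not sel.any():
        warnings.warn("no window center inside the region; falling back to "
                      "global mode", stacklevel=3)
        return _ssim_global(x, y, r, consts)
    return float(smap[sel].mean())


def ssim(x: np.ndarray, y: np.ndarray, region=None,
         consts: SSIMConstants = SSIMConstants()) -> float:
    """Structural similarity over the region; 1.0 for identical inputs."""
    consts.validate()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("image shapes must agree")
    r = _region_mask(x, region)
    if not r.any():
        raise ValueError("empty evaluation region")
    if consts.mode == "global":
        return _ssim_global(x, y, r, consts)
    return _ssim_windowed(x, y, r, consts)


def evaluate_pair(truth: CTSlice, output: CTSlice, mask: TruncationMask,
                  consts: SSIMConstants = SSIMConstants()
                  ) -> tuple[MetricsReport, MetricsReport]:
    """Metric reports over the whole image and over the missing-tissue
    generation region only."""
    t = truth.to_gray8().pixels.astype(np.float64)
    o = output.to_gray8().pixels.astype(np.float64)
    if t.shape != o.shape or t.shape != mask.known.shape:
        raise ValueError("truth, output and mask shapes must agree")

    def report(region_name, region):
        n = int(np.count_nonzero(region)) if region is not None else t.size
        if n == 0:
            return MetricsReport(region=region_name, ssim=math.nan,
                                 rmse=math.nan, psnr=math.nan,
                                 n_pixels=0, empty=True)
        _, r = mse_rmse(t, o, region)
        return MetricsReport(
            region=region_name,
            ssim=ssim(t, o, region, consts),
            rmse=r,
            psnr=psnr(t, o, region, consts),
            n_pixels=n,
        )

    whole = report("whole", None)
    gen = report("generation_only", mask.missing)
    return whole, gen
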