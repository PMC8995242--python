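"""Pixel-wise T1rho fitting, dispersion analysis and evaluation metrics.

T1rho maps come from a per-pixel two-parameter mono-exponential fit
``S(t_SL) = S0 * exp(-t_SL / T1rho)`` to the magnitude image series,
initialized by log-linear regression and refined by damped Gauss-Newton
iterations (vectorized over pixels).  Dispersion maps are per-pixel
ordinary least squares of T1rho against the spin-lock amplitude in kHz,
so the slope is reported in ms/kHz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kwic import ImageSeries

__all__ = [
    "T1rhoMap",
    "DispersionMap",
    "RoiReport",
    "fit_t1rho",
    "fit_dispersion",
    "snr_metric",
    "delta_q",
    "circular_roi",
]


@dataclass(frozen=True)
class T1rhoMap:
    """Fitted relaxation map with per-pixel goodness of fit."""

    t1rho: np.ndarray  # ms, NaN outside mask
    s0: np.ndarray
    r2: np.ndarray  # coefficient of determination, <= 1
    mask: np.ndarray
    f_SL: float

    @property
    def matrix(self) -> int:
        return self.t1rho.shape[0]


@dataclass(frozen=True)
class DispersionMap:
    """Linear dispersion fit: offset T1rho0 (ms) and slope m1rho (ms/kHz)."""

    offset: np.ndarray
    slope: np.ndarray
    r2: np.ndarray
    mask: np.ndarray
    f_SL_list: tuple


@dataclass(frozen=True)
class RoiReport:
    """ROI statistics of a map, optionally relative to a reference."""

    label: str
    mean: float
    std: float
    n_pixels: int
    delta_q_mean: float | None = None
    delta_q_std: float | None = None


def fit_t1rho(
    series: ImageSeries,
    mask_threshold: float = 0.05,
    max_iter: int = 50,
) -> T1rhoMap:
    """Pixel-wise mono-exponential T1rho fit of a weighted image series.

    Pixels whose shortest-t_SL intensity falls below ``mask_threshold``
    times the image maximum are masked out, as are pixels with
    non-finite or non-positive samples.  R^2 = 1 - SS_res / SS_tot per
    pixel; for noiseless model data the fit is exact.
    """
    if series.n_weightings < 2:
        raise ValueError("at least two weightings are required for fitting")
    t = np.asarray(series.t_SL_list, dtype=float)
    imgs = np.asarray(series.images, dtype=float)
    W, N, _ = imgs.shape
    y = imgs.reshape(W, -1)  # (W, P)

    first = imgs[0]
    mask = (first > mask_threshold * first.max()).ravel()
    mask &= np.isfinite(y).all(axis=0) & (y > 0).all(axis=0)

    ym = y[:, mask]
    # log-linear initialization
    logy = np.log(ym)
    t_c = t - t.mean()
    slope = (t_c[:, None] * (logy - logy.mean(axis=0))).sum(axis=0) / (t_c**2).sum()
    rate = np.clip(-slope, 1e-6, None)  # 1/T1rho, keep positive
    s0 = np.exp(logy.mean(axis=0) + rate * t.mean())

    # damped Gauss-Newton on (s0, rate), vectorized over pixels
    lam = np.full(rate.shape, 1e-3)
    resid = ym - s0 * np.exp(-np.outer(t, rate))
    cost = (resid**2).sum(axis=0)
    for _ in range(max_iter):
        e = np.exp(-np.outer(t, rate))  # (W, P)
        j0 = e
        j1 = -s0 * t[:, None] * e
        r = ym - s0 * e
        g0 = (j0 * r).sum(axis=0)
        g1 = (j1 * r).sum(axis=0)
        a00 = (j0 * j0).sum(axis=0) * (1 + lam)
        a01 = (j0 * j1).sum(axis=0)
        a11 = (j1 * j1).sum(axis=0) * (1 + lam)
        det = a00 * a11 - a01**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        ds0 = (a11 * g0 - a01 * g1) / det
        dr = (a00 * g1 - a01 * g0) / det
        s0_new = s0 + ds0
        rate_new = np.clip(rate + dr, 1e-9, None)
        resid_new = ym - s0_new * np.exp(-np.outer(t, rate_new))
        cost_new = (resid_new**2).sum(axis=0)
        improved = cost_new <= cost
        s0 = np.where(improved, s0_new, s0)
        rate = np.where(improved, rate_new, rate)
        lam = np.where(improved, lam * 0.3, lam * 10.0)
        cost = np.where(improved, cost_new, cost)
        if np.max(cost) == 0 or np.all(lam > 1e8):
            break

    resid = ym - s0 * np.exp(-np.outer(t, rate))
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((ym - ym.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)

    # constant pixels (no decay information) are flagged out, never negative
    valid = np.isfinite(r2) & (rate > 1e-8)
    out_mask = np.zeros(N * N, dtype=bool)
    out_mask[np.where(mask)[0][valid]] = True

    full = lambda v: _scatter(v[valid], out_mask, (N, N))
    return T1rhoMap(
        t1rho=full(1.0 / rate),
        s0=full(s0),
        r2=full(r2),
        mask=out_mask.reshape(N, N),
        f_SL=series.f_SL,
    )


def _scatter(values: np.ndarray, mask_flat: np.ndarray, shape) -> np.ndarray:
    out = np.full(int(np.prod(shape)), np.nan)
    out[mask_flat] = values
    return out.reshape(shape)


def fit_dispersion(maps: list) -> DispersionMap:
    """Per-pixel linear dispersion fit across T1rho maps at several amplitudes.

    Ordinary least squares of T1rho(f_SL) = T1rho0 + m1rho * f_SL with
    f_SL in kHz.  Pixels are fitted only where every input map is valid.
    """
    if len(maps) < 2:
        raise ValueError("at least two maps with distinct f_SL are required")
    f = np.asarray([m.f_SL for m in maps], dtype=float) / 1000.0  # kHz
    if len(np.unique(f)) < 2:
        raise ValueError("spin-lock amplitudes must be distinct")
    shape = maps[0].t1rho.shape
    if any(m.t1rho.shape != shape for m in maps):
        raise ValueError("maps must share one grid")

    mask = np.logical_and.reduce([m.mask for m in maps])
    y = np.stack([m.t1rho for m in maps]).reshape(len(maps), -1)[:, mask.ravel()]

    f_c = f - f.mean()
    denom = (f_c**2).sum()
    slope = (f_c[:, None] * (y - y.mean(axis=0))).sum(axis=0) / denom
    offset = y.mean(axis=0) - slope * f.mean()
    resid = y - (offset + np.outer(f, slope))
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)

    mflat = mask.ravel()
    valid = np.ones(slope.shape, dtype=bool)
    return DispersionMap(
        offset=_scatter(offset[valid], mflat, shape),
        slope=_scatter(slope[valid], mflat, shape),
        r2=_scatter(r2[valid], mflat, shape),
        mask=mask,
        f_SL_list=tuple(float(m.f_SL) for m in maps),
    )


def snr_metric(image: np.ndarray, signal_masks: list, noise_mask: np.ndarray) -> float:
    """Signal-to-noise ratio on a magnitude image.

    Mean over the pooled signal-mask pixels divided by the standard
    deviation over the noise-mask pixels.
    """
    signal_masks = [np.asarray(m, dtype=bool) for m in signal_masks]
    noise_mask = np.asarray(noise_mask, dtype=bool)
    pooled = np.logical_or.reduce(signal_masks)
    if not pooled.any() or not noise_mask.any():
        raise ValueError("signal and noise masks must be non-empty")
    if (pooled & noise_mask).any():
        raise ValueError("signal and noise masks must be disjoint")
    noise_std = float(np.std(image[noise_mask]))
    if noise_std == 0:
        raise ValueError("noise region has zero standard deviation")
    return float(np.mean(image[pooled]) / noise_std)


def delta_q(map_test: np.ndarray, map_ref: np.ndarray, roi: np.ndarray, label: str = "") -> RoiReport:
    """Pixel-wise relative quantification error, percent, over an ROI.

    delta_Q = 100 * (test - ref) / ref per pixel; the report carries the
    ROI mean and standard deviation of both the test map and delta_Q.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.sum() < 1:
        raise ValueError("ROI is empty")
    test = np.asarray(map_test, dtype=float)[roi]
    ref = np.asarray(map_ref, dtype=float)[roi]
    if np.any(ref == 0) or np.any(~np.isfinite(ref)):
        raise ValueError("reference contains zeros or non-finite values in ROI")
    dq = 100.0 * (test - ref) / ref
    return RoiReport(
        label=label,
        mean=float(np.nanmean(test)),
        std=float(np.nanstd(test)),
        n_pixels=int(roi.sum()),
        delta_q_mean=float(np.nanmean(dq)),
        delta_q_std=float(np.nanstd(dq)),
    )


def circular_roi(matrix: int, fov: float, center_mm: tuple, radius_mm: float) -> np.ndarray:
    """Boolean circular ROI on the centred reconstruction grid."""
    px = fov / matrix
    coords = (np.arange(matrix) - matrix // 2 + 0.5) * px
    X, Y = np.meshgrid(coords, coords, indexing="xy")
    return np.hypot(X - center_mm[0], Y - center_mm[1]) <= radius_mm
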