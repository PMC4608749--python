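"""Pixel-wise relaxation-time mapping.

Two signal models cover all five magnetization preparations:

* inversion recovery (T1):  ``S(TI) = A * (1 - 2*exp(-TI/T1))``
* mono-exponential decay (T2, T1rho, adiabatic T1rho, T_RAFF):
  ``S(t) = A * exp(-t/T)``

Acquisitions are magnitude-valued, so the inversion-recovery fit defaults to
the magnitude model ``|A*(1 - 2*exp(-TI/T1))|``; an optional
polarity-restoration mode re-signs the samples before the signal null and
fits the signed model instead.

Fitting is per pixel (independent nonlinear least squares via
:func:`scipy.optimize.least_squares`) and deterministic: the result does not
depend on pixel visit order.  Pixels whose fit fails to converge, lands on a
parameter bound, or lacks usable samples are marked invalid rather than
raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .protocols import AcquisitionProtocol, build_time_axis

__all__ = [
    "ImageSeries",
    "FitOptions",
    "ParameterMap",
    "fit_ir_t1",
    "fit_monoexp",
    "fit_series",
    "two_point_exact",
    "make_mask",
]


class SeriesError(ValueError):
    """Raised for an image series inconsistent with its protocol."""


@dataclass
class ImageSeries:
    """Ordered stack of co-registered magnitude frames.

    ``frames`` has shape (n_times, height, width) with non-negative finite
    intensities in arbitrary units; ``times_ms`` is the fitting abscissa (one
    entry per frame).  ``pixel_size_um`` is carried as metadata.
    """

    frames: np.ndarray
    times_ms: np.ndarray
    pixel_size_um: float | None = None
    protocol: AcquisitionProtocol | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.frames.ndim != 3:
            raise SeriesError("frames must be a rank-3 array (n_times, h, w)")
        if self.frames.shape[0] != self.times_ms.size:
            raise SeriesError(
                f"{self.frames.shape[0]} frames but {self.times_ms.size} time points"
            )
        if not np.all(np.isfinite(self.frames)):
            raise SeriesError("frames contain non-finite intensities")
        if np.any(self.frames < 0):
            raise SeriesError("magnitude frames must be non-negative")
        if self.protocol is not None:
            expected = build_time_axis(self.protocol)
            if not np.allclose(expected, self.times_ms, atol=1e-9):
                raise SeriesError("series times do not match the protocol time axis")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class FitOptions:
    """Options controlling the per-pixel fits.

    ``t_lower_ms``/``t_upper_factor`` bound the relaxation time: by default
    T is constrained to [min(0.1, 1e-3 * t_max), 50 * t_max] where t_max is
    the largest preparation time, and the amplitude to (0, 10 * max
    intensity].  Estimates landing on a bound are marked invalid.
    """

    restore_polarity: bool = False
    t_lower_ms: float | None = None  # None -> min(0.1, 1e-3 * max(times))
    t_upper_factor: float = 50.0
    amp_upper_factor: float = 10.0
    xtol: float = 1e-8
    max_iter: int = 200


@dataclass
class ParameterMap:
    """Per-pixel fit result: relaxation time, amplitude, R^2, validity.

    ``tmap`` is in the unit of the series' time axis (milliseconds for the
    study protocols) and NaN wherever ``valid`` is False; likewise for
    ``amplitude`` and ``r2_fit``.
    """

    tmap: np.ndarray
    amplitude: np.ndarray
    r2_fit: np.ndarray
    valid: np.ndarray
    parameter: str | None = None

    def masked(self, labels: np.ndarray, label: int) -> np.ndarray:
        """Valid relaxation times within one ROI label."""
        sel = (labels == label) & self.valid
        return self.tmap[sel]

    def roi_summary(self, labels: np.ndarray, label: int) -> tuple[float, float, int]:
        """(mean, SD, n) of valid relaxation times in an ROI (SD with ddof=1)."""
        vals = self.masked(labels, label)
        if vals.size == 0:
            raise ValueError(f"ROI label {label} contains no valid pixels")
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        return float(np.mean(vals)), sd, int(vals.size)


def two_point_exact(s1: float, s2: float, t1: float, t2: float) -> float:
    """Exact mono-exponential decay time through two points.

    ``T = (t2 - t1) / ln(s1 / s2)`` for s1 > s2 > 0 and t2 > t1.
    """
    if not (s1 > s2 > 0):
        raise ValueError("requires s1 > s2 > 0 (decaying positive signal)")
    if not t2 > t1:
        raise ValueError("requires t2 > t1")
    return (t2 - t1) / np.log(s1 / s2)


def make_mask(series: ImageSeries, rel_threshold: float = 0.1) -> np.ndarray:
    """Foreground mask from the first frame.

    A pixel is included iff its frame-0 intensity exceeds ``rel_threshold``
    times the 99th percentile of frame-0.  A constant (degenerate) frame
    yields an empty mask with a warning.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must be in (0, 1)")
    frame0 = series.frames[0]
    p99 = np.percentile(frame0, 99)
    if frame0.max() == frame0.min():
        warnings.warn("constant first frame: returning empty mask", stacklevel=2)
        return np.zeros(frame0.shape, dtype=bool)
    return frame0 > rel_threshold * p99


def _t_bounds(times: np.ndarray, opts: FitOptions) -> tuple[float, float]:
    t_max = float(times.max())
    lo = opts.t_lower_ms if opts.t_lower_ms is not None else min(0.1, 1e-3 * t_max)
    return lo, opts.t_upper_factor * t_max


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return np.nan
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


_BOUND_TOL = 1e-9


def _finalize_pixel(res, lo, hi, a_hi, y, model):
    """Common convergence / bound / R^2 bookkeeping; returns (A, T, r2, ok)."""
    a, t = res.x
    ok = bool(res.success) and np.isfinite(a) and np.isfinite(t)
    if ok:
        at_bound = (
            t - lo <= _BOUND_TOL * max(1.0, lo)
            or hi - t <= _BOUND_TOL * hi
            or a_hi - a <= _BOUND_TOL * a_hi
            or a <= _BOUND_TOL * a_hi
        )
        ok = not at_bound
    r2 = _r_squared(y, model(a, t)) if ok else np.nan
    if ok and not np.isfinite(r2):
        ok = False
    return a, t, r2, ok


def fit_monoexp(
    series: ImageSeries,
    opts: FitOptions | None = None,
    mask: np.ndarray | None = None,
) -> ParameterMap:
    """Fit ``S(t) = A * exp(-t/T)`` per masked pixel.

    Initialization is an ordinary least-squares line through (t, ln S) over
    the strictly positive samples; pixels with fewer than two positive
    samples (or all-zero signal) are marked invalid.
    """
    opts = opts or FitOptions()
    if series.protocol is not None and series.protocol.model != "MONOEXP":
        raise SeriesError(f"{series.protocol.name} is not a mono-exponential preparation")
    times = series.times_ms
    if times.size < 3:
        raise SeriesError("mono-exponential fitting needs at least 3 time points "
                          "(use two_point_exact for the 2-point case)")
    return _fit_pixels(series, opts, mask, ir=False)


def fit_ir_t1(
    series: ImageSeries,
    opts: FitOptions | None = None,
    mask: np.ndarray | None = None,
) -> ParameterMap:
    """Fit the inversion-recovery model per masked pixel.

    Default mode fits ``|A*(1 - 2*exp(-TI/T1))|`` to the magnitude signal.
    With ``opts.restore_polarity`` the samples before the fitted null point
    are sign-flipped and the signed model is fitted; both modes agree on
    noiseless data.  T1 is initialized from the null condition
    ``TI_null = T1 * ln 2`` using the minimum-|S| frame.
    """
    opts = opts or FitOptions()
    if series.protocol is not None and series.protocol.model != "INVERSION_RECOVERY":
        raise SeriesError(f"{series.protocol.name} is not an inversion-recovery preparation")
    if series.times_ms.size < 3:
        raise SeriesError("inversion-recovery fitting needs at least 3 TI points")
    return _fit_pixels(series, opts, mask, ir=True)


def fit_series(
    series: ImageSeries,
    opts: FitOptions | None = None,
    mask: np.ndarray | None = None,
) -> ParameterMap:
    """Dispatch to the model the series' protocol prescribes."""
    if series.protocol is None:
        raise SeriesError("fit_series needs a series with an attached protocol")
    if series.protocol.model == "INVERSION_RECOVERY":
        pm = fit_ir_t1(series, opts, mask)
    else:
        pm = fit_monoexp(series, opts, mask)
    pm.parameter = series.protocol.name
    return pm


def _fit_pixels(series, opts, mask, ir):
    t = series.times_ms
    h, w = series.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (h, w):
        raise SeriesError("mask shape does not match the image")

    tmap = np.full((h, w), np.nan)
    amp = np.full((h, w), np.nan)
    r2 = np.full((h, w), np.nan)
    valid = np.zeros((h, w), dtype=bool)

    lo, hi = _t_bounds(t, opts)
    max_intensity = float(series.frames.max())
    if max_intensity <= 0:
        return ParameterMap(tmap, amp, r2, valid)
    a_hi = opts.amp_upper_factor * max_intensity

    ys = series.frames[:, mask].T  # (n_pix, n_t)
    idx = np.flatnonzero(mask.ravel())
    out = np.empty((idx.size, 4))
    fit_one = _fit_ir_pixel if ir else _fit_monoexp_pixel
    for k in range(idx.size):
        out[k] = fit_one(t, ys[k], lo, hi, a_hi, opts)
    flat_t, flat_a, flat_r2, flat_ok = out.T
    ok = flat_ok > 0.5
    rr, cc = np.unravel_index(idx, (h, w))
    tmap[rr[ok], cc[ok]] = flat_t[ok]
    amp[rr[ok], cc[ok]] = flat_a[ok]
    r2[rr[ok], cc[ok]] = flat_r2[ok]
    valid[rr[ok], cc[ok]] = True
    return ParameterMap(tmap, amp, r2, valid)


def _fit_monoexp_pixel(t, y, lo, hi, a_hi, opts):
    pos = y > 0
    if pos.sum() < 2 or np.unique(t[pos]).size < 2:
        return np.nan, np.nan, np.nan, 0.0
    # log-linear init on strictly positive samples
    tp, lp = t[pos], np.log(y[pos])
    slope, intercept = np.polyfit(tp, lp, 1)
    t0 = -1.0 / slope if slope < 0 else 0.5 * hi
    t0 = float(np.clip(t0, lo * (1 + 1e-6), hi * (1 - 1e-6)))
    a0 = float(np.clip(np.exp(intercept), a_hi * 1e-12, a_hi * (1 - 1e-6)))

    def resid(p):
        return p[0] * np.exp(-t / p[1]) - y

    def jac(p):
        e = np.exp(-t / p[1])
        return np.column_stack([e, p[0] * t / p[1] ** 2 * e])

    res = least_squares(
        resid, [a0, t0], jac=jac, bounds=([0.0, lo], [a_hi, hi]),
        xtol=opts.xtol, ftol=None, gtol=None, max_nfev=opts.max_iter,
    )
    a, tt, r2, ok = _finalize_pixel(
        res, lo, hi, a_hi, y, lambda a_, t_: a_ * np.exp(-t / t_)
    )
    return tt, a, r2, 1.0 if ok else 0.0


def _ir_signed(a, t1, ti):
    return a * (1.0 - 2.0 * np.exp(-ti / t1))


def _fit_ir_pixel(t, y, lo, hi, a_hi, opts):
    if np.all(y <= 0):
        return np.nan, np.nan, np.nan, 0.0
    i_null = int(np.argmin(np.abs(y)))
    t1_0 = t[i_null] / np.log(2.0) if t[i_null] > 0 else t[1] / np.log(2.0)
    t1_0 = float(np.clip(t1_0, lo * (1 + 1e-6), hi * (1 - 1e-6)))
    denom = 1.0 - 2.0 * np.exp(-t[-1] / t1_0)
    a0 = y[-1] / denom if denom > 0.1 else float(np.max(y))
    a0 = float(np.clip(a0, a_hi * 1e-12, a_hi * (1 - 1e-6)))

    if opts.restore_polarity:
        # try the null sample on either side of the zero crossing
        best = None
        for split in (i_null, i_null + 1):
            signs = np.where(np.arange(t.size) < split, -1.0, 1.0)
            ys = signs * y

            def resid(p, ys=ys):
                return _ir_signed(p[0], p[1], t) - ys

            res = least_squares(
                resid, [a0, t1_0], bounds=([0.0, lo], [a_hi, hi]),
                xtol=opts.xtol, ftol=None, gtol=None, max_nfev=opts.max_iter,
            )
            if best is None or res.cost < best[0].cost:
                best = (res, ys)
        res, y_fit = best
        a, t1, r2, ok = _finalize_pixel(
            res, lo, hi, a_hi, y_fit, lambda a_, t_: _ir_signed(a_, t_, t)
        )
        return t1, a, r2, 1.0 if ok else 0.0

    def resid(p):
        return np.abs(_ir_signed(p[0], p[1], t)) - y

    res = least_squares(
        resid, [a0, t1_0], bounds=([0.0, lo], [a_hi, hi]),
        xtol=opts.xtol, ftol=None, gtol=None, max_nfev=opts.max_iter,
    )
    a, t1, r2, ok = _finalize_pixel(
        res, lo, hi, a_hi, y, lambda a_, t_: np.abs(_ir_signed(a_, t_, t))
    )
    return t1, a, r2, 1.0 if ok else 0.0
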