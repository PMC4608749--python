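"""Optical-density quantification of stained-section transmission images.

Safranin-O binds stoichiometrically to cartilage proteoglycans, so the
absorbance of a stained section at the dye's 530 nm absorption peak measures
local proteoglycan content.  The pipeline mirrors standard transmission
densitometry: detector counts of the sample and of a sample-free reference
area are background-subtracted and normalized to counts per second (which
cancels differing exposure times), their ratio gives transmittance, and
``OD = -log10(transmittance)`` gives optical density (absorbance, a.u.).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransmissionImage",
    "ODImage",
    "normalize_counts",
    "compute_transmittance",
    "compute_od",
    "summarize_od",
    "od_from_pair",
]

#: Transmittance below this is treated as opaque/invalid division.
_EPS_RATE = 1e-12


@dataclass
class TransmissionImage:
    """Raw transmission-microscopy detector counts with exposure metadata.

    ``background`` is the dark-count level, a scalar or a full dark frame of
    the same shape.  ``saturation_level`` (detector full scale) lets
    saturated pixels be flagged before normalization instead of averaged in.
    ``wavelength_nm`` is metadata only.
    """

    counts: np.ndarray
    exposure_s: float
    background: float | np.ndarray = 0.0
    saturation_level: float | None = None
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a rank-2 image")
        if np.any(self.counts < 0):
            raise ValueError("detector counts must be non-negative")
        if not self.exposure_s > 0:
            raise ValueError("exposure must be positive")
        bg = np.asarray(self.background, dtype=float)
        if bg.ndim not in (0, 2) or (bg.ndim == 2 and bg.shape != self.counts.shape):
            raise ValueError("background must be a scalar or match the image shape")

    def saturated(self) -> np.ndarray:
        if self.saturation_level is None:
            return np.zeros(self.counts.shape, dtype=bool)
        return self.counts >= self.saturation_level


@dataclass
class ODImage:
    """Per-pixel optical density (dimensionless absorbance) with validity."""

    od: np.ndarray
    valid: np.ndarray
    log_base: float = 10.0


def normalize_counts(img: TransmissionImage) -> np.ndarray:
    """Background-subtracted count rate, ``(counts - background) / exposure``.

    Negative differences clip to zero; saturated pixels become NaN so they
    propagate to invalid downstream.  An everywhere-zero result (background
    at or above the counts) triggers a warning.
    """
    rate = (img.counts - np.asarray(img.background, dtype=float)) / img.exposure_s
    rate = np.clip(rate, 0.0, None)
    sat = img.saturated()
    if sat.any():
        rate = rate.copy()
        rate[sat] = np.nan
    if np.nanmax(rate, initial=0.0) == 0.0:
        warnings.warn("background exceeds counts everywhere: all-zero rate image",
                      stacklevel=2)
    return rate


def compute_transmittance(sample_rate: np.ndarray, reference_rate: np.ndarray) -> np.ndarray:
    """Elementwise ``sample / reference`` count-rate ratio.

    Pixels where the reference rate is ~0 or either rate is NaN come back
    NaN (invalid); the OD step turns NaN into invalid pixels.
    """
    sample_rate = np.asarray(sample_rate, dtype=float)
    reference_rate = np.asarray(reference_rate, dtype=float)
    if sample_rate.shape != reference_rate.shape:
        raise ValueError("sample and reference shapes differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(reference_rate > _EPS_RATE, sample_rate / reference_rate, np.nan)
    return t


def compute_od(transmittance: np.ndarray, log_base: float = 10.0) -> ODImage:
    """Optical density ``-log(transmittance)`` (base 10 by default).

    Transmittance <= 0 or NaN marks the pixel invalid; transmittance
    slightly above 1 (noise on an unstained region) clamps to OD 0 and
    stays valid.
    """
    t = np.asarray(transmittance, dtype=float)
    valid = np.isfinite(t) & (t > 0)
    od = np.full(t.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        od[valid] = -np.log(t[valid]) / np.log(log_base)
    od[valid & (t > 1.0)] = 0.0
    return ODImage(od=od, valid=valid, log_base=log_base)


def od_from_pair(
    sample: TransmissionImage,
    reference: TransmissionImage,
    log_base: float = 10.0,
) -> ODImage:
    """Full pipeline: normalize both images, divide, take the negative log."""
    return compute_od(
        compute_transmittance(normalize_counts(sample), normalize_counts(reference)),
        log_base=log_base,
    )


def summarize_od(od: ODImage, roi: np.ndarray, label: int) -> tuple[float, float, int]:
    """(mean, SD, n) of valid OD pixels carrying an ROI label (SD with ddof=1)."""
    roi = np.asarray(roi)
    if roi.shape != od.od.shape:
        raise ValueError("ROI label image shape does not match the OD map")
    sel = (roi == label) & od.valid
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"ROI label {label} is empty (or has no valid pixels)")
    vals = od.od[sel]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return float(np.mean(vals)), sd, n
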