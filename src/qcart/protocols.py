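"""Magnetization-preparation protocols and their fitting time axes.

An :class:`AcquisitionProtocol` describes one magnetization preparation of a
relaxometry experiment: which signal model applies (inversion recovery for T1,
mono-exponential decay for T2 / spin-lock / pulse-train preparations) and the
preparation times at which frames were acquired.  For pulse-train
preparations (adiabatic T1rho, T_RAFF) the time axis is not stored explicitly
but derived as pulse count x per-pulse duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

VALID_NAMES = ("T1", "T2", "T1RHO", "AD_T1RHO", "RAFF")
VALID_MODELS = ("INVERSION_RECOVERY", "MONOEXP")

#: Preparations whose abscissa is pulse_count x pulse_duration.
PULSE_TRAIN_NAMES = ("AD_T1RHO", "RAFF")


class ProtocolError(ValueError):
    """Raised for an ill-formed acquisition protocol."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One magnetization preparation with its time-axis rule.

    Parameters
    ----------
    name:
        Which relaxation parameter the preparation encodes
        (``T1 | T2 | T1RHO | AD_T1RHO | RAFF``).
    model:
        Signal model: ``INVERSION_RECOVERY`` (T1) or ``MONOEXP`` (the rest).
    times_ms:
        Explicit preparation times in milliseconds (TI for inversion
        recovery, TE for spin echo, spin-lock duration for T1rho).
    pulse_counts, pulse_duration_ms:
        For pulse-train preparations: number of pulses per frame and the
        per-pulse duration; the fitting abscissa is their product.
    metadata:
        Free-form acquisition metadata (pulse power gamma*B1max, pulse
        family, readout settings ...).  Never used in computation.
    """

    name: str
    model: str
    times_ms: Sequence[float] | None = None
    pulse_counts: Sequence[int] | None = None
    pulse_duration_ms: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in VALID_NAMES:
            raise ProtocolError(f"unknown preparation {self.name!r}")
        if self.model not in VALID_MODELS:
            raise ProtocolError(f"unknown signal model {self.model!r}")
        if self.name == "T1" and self.model != "INVERSION_RECOVERY":
            raise ProtocolError("T1 preparation requires the inversion-recovery model")
        if self.name != "T1" and self.model == "INVERSION_RECOVERY":
            raise ProtocolError(f"{self.name} is not an inversion-recovery preparation")
        if self.times_ms is None and self.pulse_counts is None:
            raise ProtocolError("protocol needs either explicit times or a pulse train")
        if self.times_ms is not None and self.pulse_counts is not None:
            if self.pulse_duration_ms is None:
                raise ProtocolError("pulse train given without a per-pulse duration")
            train = np.asarray(self.pulse_counts, dtype=float) * float(self.pulse_duration_ms)
            if not np.allclose(np.asarray(self.times_ms, dtype=float), train, atol=1e-9):
                raise ProtocolError("explicit times inconsistent with pulse train")
        build_time_axis(self)  # validates monotonicity etc.

    @property
    def n_times(self) -> int:
        return len(build_time_axis(self))


def build_time_axis(protocol: AcquisitionProtocol) -> np.ndarray:
    """Return the fitting abscissa of a protocol in milliseconds.

    Explicit times pass through unchanged; pulse-train protocols return
    pulse count x per-pulse duration per frame.

    Raises
    ------
    ProtocolError
        If a pulse-train protocol lacks a pulse duration, or the resulting
        axis is not strictly increasing and non-negative, or has fewer than
        two points.
    """
    if protocol.times_ms is not None:
        times = np.asarray(protocol.times_ms, dtype=float)
    else:
        if protocol.pulse_duration_ms is None:
            raise ProtocolError(
                f"{protocol.name}: pulse-train protocol without a per-pulse duration"
            )
        counts = np.asarray(protocol.pulse_counts, dtype=float)
        times = counts * float(protocol.pulse_duration_ms)
    if times.ndim != 1 or times.size < 2:
        raise ProtocolError("protocol needs at least two time points")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise ProtocolError("time points must be finite and non-negative")
    if np.any(np.diff(times) <= 0):
        raise ProtocolError("time points must be strictly increasing")
    return times
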