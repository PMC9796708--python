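"""Differentiation of marker trajectories into acceleration and jerk.

Acceleration is the second and jerk the third time-derivative of position.
Derivatives are taken by repeated central finite differences, which are
second-order accurate and exact on polynomials up to the derivative order;
each application trims one frame from both ends.  An optional zero-phase
low-pass filter (4th-order Butterworth equivalent, applied forward and
backward) can be applied to positions first: measured optical data needs it
before a third derivative, noise-free synthetic data does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .io import AXES, MarkerTrial

__all__ = ["AxisSeriesMatrix", "differentiate", "lowpass_filter", "axis_series"]

QUANTITIES = ("acceleration", "jerk")
_DERIV_ORDER = {"acceleration": 2, "jerk": 3}


@dataclass
class AxisSeriesMatrix:
    """Per-marker derivative series along one axis.

    ``values`` is (frames - 2*order) x markers, in m/s^2 (acceleration) or
    m/s^3 (jerk).
    """

    quantity: str
    axis: str
    values: np.ndarray
    sampling_rate: float
    labels: tuple[str, ...]
    subject_id: str = ""
    session: str = ""


def differentiate(series: np.ndarray, order: int, dt: float) -> np.ndarray:
    """Apply the central first difference ``order`` times.

    ``series`` is frames x k (a 1-D array is treated as a single column).
    The result has ``frames - 2*order`` rows.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if order < 1:
        raise ValueError("order must be a positive integer")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if x.shape[0] <= 2 * order:
        raise ValueError(
            f"need more than {2 * order} frames for an order-{order} "
            f"derivative, got {x.shape[0]}"
        )
    for _ in range(order):
        x = (x[2:] - x[:-2]) / (2.0 * dt)
    return x[:, 0] if squeeze else x


def lowpass_filter(
    series: np.ndarray, cutoff_hz: float, sampling_rate: float
) -> np.ndarray:
    """Zero-phase low-pass filter (Butterworth, effective 4th order)."""
    x = np.asarray(series, dtype=float)
    nyquist = sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff_hz}"
        )
    # order-2 design; filtfilt's forward-backward pass doubles the rolloff
    b, a = butter(2, cutoff_hz / nyquist)
    return filtfilt(b, a, x, axis=0)


def axis_series(
    trial: MarkerTrial,
    quantity: str,
    axis: str,
    filter_cutoff_hz: float | None = None,
) -> AxisSeriesMatrix:
    """Derivative time series of every marker along one axis.

    ``filter_cutoff_hz`` low-pass filters the positions before
    differentiation when given (use ~10 Hz for measured optical data).
    """
    if quantity not in QUANTITIES:
        raise ValueError(f"quantity must be one of {QUANTITIES}")
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    positions = trial.axis_positions(axis)
    if filter_cutoff_hz is not None:
        positions = lowpass_filter(
            positions, filter_cutoff_hz, trial.sampling_rate
        )
    values = differentiate(positions, _DERIV_ORDER[quantity], trial.dt)
    return AxisSeriesMatrix(
        quantity=quantity,
        axis=axis,
        values=values,
        sampling_rate=trial.sampling_rate,
        labels=trial.marker_set.labels,
        subject_id=trial.subject_id,
        session=trial.session,
    )
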