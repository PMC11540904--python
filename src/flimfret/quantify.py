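"""Synaptic-potentiation and sensor-kinetics quantification.

EPSP/EPSC sweep series are normalized to a pre-induction baseline window
(0-5 min by default); the magnitude of potentiation is the percent change of
the normalized amplitude in a late window (25-30 min).  Sensor response
kinetics are summarized by a single-exponential fit y = A exp(-t/tau) + B to
the decay segment after the last stimulus, and peak responses by the trace
maximum over a stimulus-indexed or absolute-time window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .decay_model import DomainError
from .imaging import ROITrace

__all__ = [
    "SweepSeries",
    "KineticsFit",
    "normalize_sweeps",
    "potentiation_magnitude",
    "exp_decay_fit",
    "peak_response",
]


@dataclass(frozen=True)
class SweepSeries:
    """EPSP/EPSC amplitude series (mV or pA) over a recording."""

    times_min: np.ndarray
    amplitudes: np.ndarray
    condition: str = "stimulated"
    induction_time_min: float = 5.0
    normalized: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise DomainError("times_min and amplitudes must be 1-D and equal length")
        if np.any(np.diff(t) < 0):
            raise DomainError("times_min must be non-decreasing")
        if not np.all(np.isfinite(a)):
            raise DomainError("amplitudes must be finite")
        if not (t[0] <= self.induction_time_min <= t[-1]):
            raise DomainError("induction_time_min must lie within the recorded span")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "amplitudes", a)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_min": self.times_min,
                "amplitude": self.amplitudes,
                "condition": self.condition,
                "induction_time_min": self.induction_time_min,
            }
        ).to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "SweepSeries":
        df = pd.read_csv(path)
        return SweepSeries(
            times_min=df["time_min"].to_numpy(),
            amplitudes=df["amplitude"].to_numpy(),
            condition=str(df["condition"].iloc[0]),
            induction_time_min=float(df["induction_time_min"].iloc[0]),
        )


@dataclass(frozen=True)
class KineticsFit:
    """Single-exponential decay fit y = A exp(-t/tau) + B."""

    amplitude: float
    tau_s: float
    offset: float
    rss: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and not self.tau_s > 0:
            raise DomainError("converged fit must have tau_s > 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "A": self.amplitude,
                "tau_s": self.tau_s,
                "B": self.offset,
                "rss": self.rss,
                "converged": self.converged,
                "message": self.message,
            },
            indent=2,
        )


def normalize_sweeps(series: SweepSeries, baseline_window_min: tuple = (0.0, 5.0)) -> SweepSeries:
    """Divide amplitudes by the baseline-window mean (output baseline = 1).

    Idempotent: normalizing an already-normalized series changes nothing
    beyond floating-point round-off.
    """
    lo, hi = baseline_window_min
    sel = (series.times_min >= lo) & (series.times_min <= hi)
    if sel.sum() < 3:
        raise DomainError(f"baseline window {baseline_window_min!r} holds fewer than 3 sweeps")
    base = float(np.mean(series.amplitudes[sel]))
    if base == 0:
        raise DomainError("zero baseline amplitude")
    return replace(series, amplitudes=series.amplitudes / base, normalized=True)


def potentiation_magnitude(normalized: SweepSeries, window_min: tuple = (25.0, 30.0)) -> float:
    """Percent change of normalized amplitude in a late window:
    100 x (window mean - 1)."""
    lo, hi = window_min
    sel = (normalized.times_min >= lo) & (normalized.times_min <= hi)
    if sel.sum() < 3:
        raise DomainError(f"window {window_min!r} holds fewer than 3 sweeps")
    return float(100.0 * (np.mean(normalized.amplitudes[sel]) - 1.0))


def exp_decay_fit(times_s, values) -> KineticsFit:
    """Unweighted least-squares fit of A exp(-t/tau) + B to a decay segment.

    The time origin should be the last stimulus.  Non-convergence returns
    ``converged=False`` with diagnostics rather than raising.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 5:
        raise DomainError("decay segment needs at least 5 samples")

    def model(tt, a, tau, b):
        return a * np.exp(-tt / tau) + b

    span = max(t[-1] - t[0], 1e-9)
    b0 = float(y[-1])
    a0 = float(y[0] - b0) or 1e-3
    tau0 = span / 3.0
    try:
        popt, _ = curve_fit(
            model, t, y, p0=[a0, tau0, b0],
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        resid = y - model(t, *popt)
        return KineticsFit(
            amplitude=float(popt[0]), tau_s=float(popt[1]), offset=float(popt[2]),
            rss=float(np.sum(resid**2)), converged=True,
        )
    except RuntimeError as exc:  # optimizer failure, never silent
        return KineticsFit(
            amplitude=float("nan"), tau_s=float("nan"), offset=float("nan"),
            rss=float("nan"), converged=False, message=str(exc),
        )


def peak_response(
    trace: ROITrace,
    time_window_s: tuple | None = None,
    stim_times_s=None,
    stim_index_range: tuple | None = None,
) -> float:
    """Maximum of a (processed) trace within a response window.

    The window is either an absolute ``time_window_s`` interval or a
    1-based stimulus-index range ``stim_index_range`` mapped through the
    ``stim_times_s`` table (e.g. pulses 6-11 of an uncaging train).
    """
    if time_window_s is None:
        if stim_times_s is None or stim_index_range is None:
            raise DomainError("give either time_window_s or stim_times_s + stim_index_range")
        stim_times_s = np.asarray(stim_times_s, dtype=float)
        lo_i, hi_i = stim_index_range
        if not (1 <= lo_i <= hi_i <= stim_times_s.size):
            raise DomainError(f"stimulus index range {stim_index_range!r} outside the table")
        time_window_s = (float(stim_times_s[lo_i - 1]), float(stim_times_s[hi_i - 1]))
    lo, hi = time_window_s
    t = trace.times_s
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise DomainError(f"window {time_window_s!r} outside trace span")
    sel = (t >= lo) & (t <= hi)
    if not sel.any():
        raise DomainError("window selects no samples")
    return float(np.nanmax(trace.value[sel]))
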