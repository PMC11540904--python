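"""Lifetime images and ROI time courses from FLIM frame stacks.

A FLIM acquisition is stored as two per-frame, per-pixel arrays: the photon
count and the sum of photon arrival times.  These are sufficient statistics
for the mean-arrival-time lifetime estimator used throughout:
<tau> = (sum of arrival times)/(photon count) - t0, with t0 the session-level
offset from a whole-image fit.  Traces are processed with the standard chain:
moving-average smoothing (30 frames for time courses, 60 data points before
event calling) and normalization to the first 100 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decay_model import DomainError, binding_fraction_from_lifetime

__all__ = [
    "FLIMStack",
    "LifetimeImage",
    "ROITrace",
    "lifetime_image",
    "roi_trace",
    "smooth_trace",
    "normalize_trace",
    "ca_ratio",
]

DEFAULT_SMOOTH_FRAMES = 30
DEFAULT_BASELINE_FRAMES = 100
DEFAULT_MIN_PHOTONS = 10


@dataclass(frozen=True)
class FLIMStack:
    """Raw FLIM imaging data: per-frame, per-pixel photon statistics.

    Arrays are shaped ``(n_frames, ny, nx)``; pixel indices are 0-based with
    (x, y) = (column, row); times are seconds from recording start.
    """

    photon_count: np.ndarray
    arrival_sum_ns: np.ndarray
    frame_interval_s: float
    window_ns: float = 12.5

    def __post_init__(self) -> None:
        pc = np.asarray(self.photon_count)
        asum = np.asarray(self.arrival_sum_ns, dtype=float)
        if pc.shape != asum.shape or pc.ndim != 3:
            raise DomainError("photon_count and arrival_sum_ns must share a (frames, ny, nx) shape")
        if np.any(pc < 0):
            raise DomainError("photon_count must be non-negative")
        if np.any(asum[pc == 0] != 0):
            raise DomainError("arrival_sum_ns must be 0 wherever photon_count is 0")
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_t = np.where(pc > 0, asum / np.maximum(pc, 1), 0.0)
        if np.any(mean_t < 0) or np.any(mean_t > self.window_ns):
            raise DomainError("mean arrival times fall outside [0, window_ns]")
        object.__setattr__(self, "photon_count", pc.astype(np.int64))
        object.__setattr__(self, "arrival_sum_ns", asum)

    @property
    def n_frames(self) -> int:
        return int(self.photon_count.shape[0])

    @property
    def dims(self) -> tuple:
        f, ny, nx = self.photon_count.shape
        return (nx, ny, f)

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass(frozen=True)
class LifetimeImage:
    """Per-pixel mean lifetime with a validity mask (low-photon pixels masked)."""

    mean_lifetime_ns: np.ndarray
    valid_mask: np.ndarray
    t0_used: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.mean_lifetime_ns, dtype=float)
        mask = np.asarray(self.valid_mask, dtype=bool)
        if vals.shape != mask.shape:
            raise DomainError("image and mask shapes differ")
        if np.any(~np.isfinite(vals[mask])):
            raise DomainError("unmasked lifetime values must be finite")
        object.__setattr__(self, "mean_lifetime_ns", vals)
        object.__setattr__(self, "valid_mask", mask)


@dataclass(frozen=True)
class ROITrace:
    """Time series of lifetime (ns), lifetime change (ns) or normalized
    intensity for one ROI, with processing provenance.

    ``value`` may contain NaN at frames flagged missing (e.g. zero ROI
    photons); raw traces are never silently overwritten — every operation
    returns a new trace with an appended provenance entry.
    """

    times_s: np.ndarray
    value: np.ndarray
    intensity: np.ndarray | None = None
    roi_id: str = "roi"
    compartment: str = "dendrite"
    units: str = "ns"
    processing: tuple = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise DomainError("times_s and value must be 1-D arrays of equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise DomainError("times_s must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "value", v)
        if self.intensity is not None:
            inten = np.asarray(self.intensity, dtype=float)
            if inten.shape != t.shape:
                raise DomainError("intensity length must match times_s")
            object.__setattr__(self, "intensity", inten)

    @property
    def frame_interval_s(self) -> float:
        if self.times_s.size < 2:
            raise DomainError("trace too short to define a frame interval")
        return float(np.median(np.diff(self.times_s)))

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.value)

    def with_value(self, value, step: str, units: str | None = None) -> "ROITrace":
        return replace(
            self,
            value=np.asarray(value, dtype=float),
            units=self.units if units is None else units,
            processing=self.processing + (step,),
        )


def roi_mask_to_csv(mask: np.ndarray, path) -> None:
    """Write an ROI mask as a CSV pixel list (columns x, y; 0-based)."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    pd.DataFrame({"x": xs, "y": ys}).to_csv(path, index=False)


def roi_mask_from_csv(path, shape: tuple) -> np.ndarray:
    """Read a CSV pixel list back into a boolean mask of ``shape`` (ny, nx)."""
    df = pd.read_csv(path)
    mask = np.zeros(shape, dtype=bool)
    xs = df["x"].to_numpy(int)
    ys = df["y"].to_numpy(int)
    if xs.size and (xs.min() < 0 or ys.min() < 0 or xs.max() >= shape[1] or ys.max() >= shape[0]):
        raise DomainError("pixel list exceeds the requested mask shape")
    mask[ys, xs] = True
    return mask


def lifetime_image(
    stack: FLIMStack,
    t0: float,
    min_photons: int = DEFAULT_MIN_PHOTONS,
    frame_range: tuple | None = None,
) -> LifetimeImage:
    """Pool frames and map each pixel to <tau> = pooled mean arrival - t0.

    Pixels whose pooled photon count falls below ``min_photons`` are masked.
    """
    if t0 < 0:
        raise DomainError("t0 must be >= 0")
    lo, hi = (0, stack.n_frames) if frame_range is None else frame_range
    if not (0 <= lo < hi <= stack.n_frames):
        raise DomainError(f"empty or out-of-range frame_range {frame_range!r}")
    counts = stack.photon_count[lo:hi].sum(axis=0)
    sums = stack.arrival_sum_ns[lo:hi].sum(axis=0)
    valid = counts >= max(min_photons, 1)
    img = np.full(counts.shape, np.nan)
    img[valid] = sums[valid] / counts[valid] - t0
    return LifetimeImage(mean_lifetime_ns=img, valid_mask=valid, t0_used=t0)


def roi_trace(
    stack: FLIMStack,
    roi_mask: np.ndarray,
    t0: float,
    roi_id: str = "roi",
    compartment: str = "dendrite",
    estimator: str = "mean_arrival",
    tau_d: float | None = None,
    tau_ad: float | None = None,
) -> ROITrace:
    """Per-frame ROI lifetime by photon pooling.

    The default estimator is the pooled mean arrival time minus ``t0`` (ns).
    ``estimator="binding_fraction"`` instead returns the bound fraction
    obtained by inverting the two-state lifetime formula with the session
    lifetimes held fixed — the fixed-lifetime ROI readout.  Frames with zero
    ROI photons are flagged missing (NaN) and the trace continues.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != stack.photon_count.shape[1:]:
        raise DomainError("roi_mask shape must match the stack image shape")
    if not roi_mask.any():
        raise DomainError("roi_mask selects no pixels")
    counts = stack.photon_count[:, roi_mask].sum(axis=1)
    sums = stack.arrival_sum_ns[:, roi_mask].sum(axis=1)
    value = np.full(counts.shape, np.nan)
    nonzero = counts > 0
    value[nonzero] = sums[nonzero] / counts[nonzero] - t0
    units = "ns"
    step = f"roi_trace(t0={t0:g}, estimator={estimator})"
    if estimator == "binding_fraction":
        if tau_d is None or tau_ad is None:
            raise DomainError("binding_fraction estimator needs fixed tau_d and tau_ad")
        bf = np.full_like(value, np.nan)
        bf[nonzero] = [
            binding_fraction_from_lifetime(v, tau_d, tau_ad) for v in value[nonzero]
        ]
        value = bf
        units = "fraction"
    elif estimator != "mean_arrival":
        raise DomainError(f"unknown estimator {estimator!r}")
    return ROITrace(
        times_s=stack.times_s(),
        value=value,
        intensity=counts.astype(float),
        roi_id=roi_id,
        compartment=compartment,
        units=units,
        processing=(step,),
    )


def _moving_average(values: np.ndarray, window: int, mode: str) -> np.ndarray:
    kernel = np.ones(window)
    if mode == "centered":
        num = np.convolve(values, kernel, mode="same")
        den = np.convolve(np.ones_like(values), kernel, mode="same")
        return num / den
    if mode == "trailing":
        padded = np.concatenate([np.zeros(window - 1), values])
        ones = np.concatenate([np.zeros(window - 1), np.ones_like(values)])
        c = np.cumsum(padded)
        n = np.cumsum(ones)
        num = c[window - 1 :] - np.concatenate([[0.0], c[: len(values) - 1]])
        den = n[window - 1 :] - np.concatenate([[0.0], n[: len(values) - 1]])
        return num / den
    raise DomainError(f"unknown smoothing mode {mode!r}")


def smooth_trace(
    trace: ROITrace, window_frames: int = DEFAULT_SMOOTH_FRAMES, mode: str = "centered"
) -> ROITrace:
    """Moving-average smoothing (centered by default, shrinking edge windows).

    Missing values are linearly interpolated for the filter only; the missing
    flags survive in the output.  ``mode="trailing"`` gives the causal variant
    for sensitivity checks.
    """
    if window_frames < 1:
        raise DomainError("window_frames must be >= 1")
    n = trace.value.size
    if window_frames > n:
        raise DomainError(f"window ({window_frames}) exceeds trace length ({n})")
    filled = trace.value.copy()
    missing = trace.missing
    if missing.any():
        if missing.all():
            raise DomainError("trace has no valid samples to smooth")
        idx = np.arange(n)
        filled[missing] = np.interp(idx[missing], idx[~missing], filled[~missing])
    smoothed = _moving_average(filled, window_frames, mode)
    out = trace.with_value(smoothed, f"smooth(window={window_frames}, mode={mode})")
    return out


def normalize_trace(trace: ROITrace, baseline_frames: int = DEFAULT_BASELINE_FRAMES) -> ROITrace:
    """Subtract the mean of the first ``baseline_frames`` samples, giving a
    lifetime-change trace (baseline mean of the output is 0)."""
    if trace.value.size <= baseline_frames:
        raise DomainError(
            f"trace has {trace.value.size} frames; needs more than {baseline_frames}"
        )
    base = trace.value[:baseline_frames]
    if not np.isfinite(base).any():
        raise DomainError("baseline window contains no valid samples")
    baseline = float(np.nanmean(base))
    return trace.with_value(
        trace.value - baseline, f"normalize(baseline_frames={baseline_frames})"
    )


def ca_ratio(
    ca_channel: np.ndarray,
    structural_channel: np.ndarray,
    baseline_frames: int = DEFAULT_BASELINE_FRAMES,
    times_s: np.ndarray | None = None,
    zero_baseline: bool = True,
) -> ROITrace:
    """Ratio-normalized Ca2+ trace.

    The Ca-dye intensity is divided by the structural-dye intensity (common
    multiplicative bleaching cancels), then by the mean of the first
    ``baseline_frames`` ratios.  With ``zero_baseline`` (default) 1 is
    subtracted so the result is a dF/F-style trace around 0.
    """
    ca = np.asarray(ca_channel, dtype=float)
    st = np.asarray(structural_channel, dtype=float)
    if ca.shape != st.shape or ca.ndim != 1:
        raise DomainError("channels must be 1-D arrays of equal length")
    if ca.size <= baseline_frames:
        raise DomainError(f"need more than {baseline_frames} frames")
    if np.any(st <= 0):
        raise DomainError("structural channel must be strictly positive")
    ratio = ca / st
    base = float(np.mean(ratio[:baseline_frames]))
    if base <= 0:
        raise DomainError("non-positive baseline ratio")
    value = ratio / base - (1.0 if zero_baseline else 0.0)
    t = np.arange(ca.size, dtype=float) if times_s is None else np.asarray(times_s, float)
    return ROITrace(
        times_s=t,
        value=value,
        intensity=ca,
        roi_id="ca",
        compartment="dendrite",
        units="dF/F",
        processing=(f"ca_ratio(baseline_frames={baseline_frames}, zero_baseline={zero_baseline})",),
    )
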