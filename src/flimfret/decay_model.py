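"""Fluorescence-decay model for TCSPC / 2pFLIM-FRET data.

The donor fluorophore of a FRET sensor decays with lifetime ``tau_d`` when
free and ``tau_ad`` when bound to (quenched by) the acceptor.  After
convolution with a Gaussian instrument pulse response of width ``tau_g`` the
photon-arrival histogram follows

    F(t) = F0 * [P_D * H(t, t0, tau_d, tau_g) + P_AD * H(t, t0, tau_ad, tau_g)]

with H the exponentially modified Gaussian kernel

    H(t, t0, tau, tau_g) = 1/2 * exp(tau_g^2/(2 tau^2) - (t - t0)/tau)
                             * erfc((tau_g^2 - tau (t - t0)) / (sqrt(2) tau tau_g))

P_D and P_AD are *amplitude* fractions (P_D + P_AD = 1 for a two-state
sensor); the binding fraction P_AD/(P_D+P_AD) is the sensor's activity
readout.  This module provides the model, moment-based lifetime estimators
(mean photon arrival time <t>, mean lifetime <tau> = <t> - t0) and a
Poisson maximum-likelihood curve fit.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import erfc, erfcx
from scipy.stats import exponnorm

__all__ = [
    "DecayParams",
    "TCSPCHistogram",
    "FitResult",
    "irf_exp_density",
    "decay_curve",
    "channel_expected_counts",
    "mean_arrival_time",
    "mean_lifetime",
    "fit_decay",
    "estimate_t0_global",
    "binding_fraction",
    "DEFAULT_WINDOW_NS",
    "DEFAULT_N_CHANNELS",
    "DEFAULT_SEED",
]

#: Measurement window: one 80 MHz laser period (conventional; configurable).
DEFAULT_WINDOW_NS = 12.5
#: TCSPC channels per window (conventional; configurable).
DEFAULT_N_CHANNELS = 256
#: Default seed for every stochastic routine in the package.
DEFAULT_SEED = 20241009

#: Parameters that fit_decay can optimize (p_d is tied to 1 - p_ad).
FITTABLE = ("f0", "p_ad", "tau_d", "tau_ad", "tau_g", "t0")


class DomainError(ValueError):
    """Raised when a model parameter violates its physical domain."""


@dataclass(frozen=True)
class DecayParams:
    """Parameter set of the two-state convolved-exponential decay model.

    Attributes
    ----------
    tau_d : float
        Lifetime of the free donor, ns.
    tau_ad : float
        Lifetime of the acceptor-bound (FRET-quenched) donor, ns.
    tau_g : float
        Width of the Gaussian pulse response, ns.
    t0 : float
        Arrival-time offset, ns.
    f0 : float
        Peak amplitude before convolution, photons/channel.
    p_d, p_ad : float
        Amplitude fractions of free and bound donor; must sum to 1.
    """

    tau_d: float = 2.6
    tau_ad: float = 1.1
    tau_g: float = 0.2
    t0: float = 2.0
    f0: float = 1.0
    p_d: float = 1.0
    p_ad: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_d", "tau_ad", "tau_g"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("p_d", "p_ad"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must lie in [0, 1], got {v!r}")
        if abs(self.p_d + self.p_ad - 1.0) > 1e-9:
            raise DomainError(
                f"p_d + p_ad must equal 1 (two-state model); got {self.p_d + self.p_ad!r}"
            )
        if self.f0 < 0:
            raise DomainError(f"f0 must be >= 0, got {self.f0!r}")
        if self.tau_ad >= self.tau_d:
            warnings.warn(
                "tau_ad >= tau_d: not a FRET-quencher configuration",
                stacklevel=2,
            )

    @staticmethod
    def two_state(p_ad: float, **kwargs) -> "DecayParams":
        """Build params from the bound fraction alone (p_d = 1 - p_ad)."""
        return DecayParams(p_ad=p_ad, p_d=1.0 - p_ad, **kwargs)

    @property
    def mean_lifetime_ns(self) -> float:
        """Closed-form amplitude-weighted mean lifetime of the model,
        <tau> = (P_D tau_d^2 + P_AD tau_ad^2) / (P_D tau_d + P_AD tau_ad)."""
        num = self.p_d * self.tau_d**2 + self.p_ad * self.tau_ad**2
        den = self.p_d * self.tau_d + self.p_ad * self.tau_ad
        return num / den

    @property
    def photon_fraction_ad(self) -> float:
        """Fraction of *photons* emitted by the bound state (P_AD weighted by
        its time integral tau_ad)."""
        den = self.p_d * self.tau_d + self.p_ad * self.tau_ad
        return self.p_ad * self.tau_ad / den

    def replace(self, **kwargs) -> "DecayParams":
        if "p_ad" in kwargs and "p_d" not in kwargs:
            kwargs["p_d"] = 1.0 - kwargs["p_ad"]
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TCSPCHistogram:
    """Binned photon-arrival counts for one pixel, ROI or session."""

    channel_width_ns: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise DomainError("counts must be a non-empty 1-D array")
        if np.any(counts < 0):
            raise DomainError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise DomainError("counts must be integral-valued")
        if not self.channel_width_ns > 0:
            raise DomainError("channel_width_ns must be > 0")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_channels(self) -> int:
        return int(self.counts.size)

    @property
    def window_ns(self) -> float:
        return self.n_channels * self.channel_width_ns

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())

    def channel_centers(self) -> np.ndarray:
        return (np.arange(self.n_channels) + 0.5) * self.channel_width_ns

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "channel_index": np.arange(self.n_channels),
                "time_ns": self.channel_centers(),
                "counts": self.counts,
            }
        ).to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "TCSPCHistogram":
        df = pd.read_csv(path)
        t = df["time_ns"].to_numpy()
        width = float(t[1] - t[0]) if len(t) > 1 else float(2 * t[0])
        return TCSPCHistogram(channel_width_ns=width, counts=df["counts"].to_numpy())


@dataclass(frozen=True)
class FitResult:
    """Outcome of a decay-curve fit."""

    params: DecayParams
    fixed_mask: tuple
    objective: float
    converged: bool
    stderr: dict = field(default_factory=dict)
    n_photons: int = 0
    message: str = ""

    def to_json(self) -> str:
        d = {
            "params": {k: getattr(self.params, k) for k in FITTABLE + ("p_d",)},
            "fixed": list(self.fixed_mask),
            "objective": self.objective,
            "converged": self.converged,
            "stderr": self.stderr,
            "n_photons": self.n_photons,
            "message": self.message,
        }
        return json.dumps(d, indent=2)


def irf_exp_density(t, t0: float, tau: float, tau_g: float):
    """Single-exponential decay convolved with a Gaussian pulse response.

    Evaluates H(t, t0, tau, tau_g); vectorized over ``t``.  Uses the scaled
    complementary error function on the overflow-prone branch so the value is
    finite and accurate for (t - t0)/tau well beyond 50.  Note that H is an
    *amplitude* kernel: its time integral equals tau, not 1.
    """
    if not tau > 0:
        raise DomainError(f"tau must be > 0, got {tau!r}")
    if not tau_g > 0:
        raise DomainError(f"tau_g must be > 0, got {tau_g!r}")
    x = np.asarray(t, dtype=float) - t0
    b = (tau_g**2 - tau * x) / (math.sqrt(2.0) * tau * tau_g)
    out = np.empty_like(x)
    pos = b > 0
    # b > 0 (early times): erfc(b) underflows against the exploding exponential;
    # rewrite with erfcx using  a - b^2 = -x^2 / (2 tau_g^2).
    xp = x[pos]
    out[pos] = 0.5 * np.exp(-(xp**2) / (2.0 * tau_g**2)) * erfcx(b[pos])
    neg = ~pos
    a = tau_g**2 / (2.0 * tau**2) - x[neg] / tau
    out[neg] = 0.5 * np.exp(a) * erfc(b[neg])
    if out.ndim == 0:
        return float(out)
    return out


def decay_curve(params: DecayParams, t_grid):
    """Model photon counts F(t) on ``t_grid`` for a two-state sensor."""
    h_d = irf_exp_density(t_grid, params.t0, params.tau_d, params.tau_g)
    h_ad = irf_exp_density(t_grid, params.t0, params.tau_ad, params.tau_g)
    return params.f0 * (params.p_d * h_d + params.p_ad * h_ad)


def channel_expected_counts(params: DecayParams, edges_ns: np.ndarray, model: str = "integral"):
    """Expected model counts per TCSPC channel.

    ``model="integral"`` (default) integrates F(t) exactly over each channel
    using the closed-form CDF of the exponentially modified Gaussian and
    reports the channel-mean of F (so f0 keeps the same scale as
    ``decay_curve``).  ``model="center"`` evaluates F at channel centers —
    cheaper, but biased where the curve rises steeply compared with the
    channel width.
    """
    edges = np.asarray(edges_ns, dtype=float)
    width = np.diff(edges)
    if model == "center":
        return decay_curve(params, (edges[:-1] + edges[1:]) / 2.0)
    if model != "integral":
        raise DomainError(f"unknown channel model {model!r}")
    out = np.zeros(edges.size - 1)
    for tau, p in ((params.tau_d, params.p_d), (params.tau_ad, params.p_ad)):
        if p == 0:
            continue
        k = tau / params.tau_g
        cdf = exponnorm.cdf(edges, k, loc=params.t0, scale=params.tau_g)
        out += params.f0 * p * tau * np.diff(cdf)
    return out / width


def model_cdf(params: DecayParams, window_ns: float, n_grid: int = 20001):
    """Arrival-time CDF of the model truncated to [0, window_ns].

    Returns ``(grid, cdf)``; used to validate photon samplers against the
    analytic model.
    """
    grid = np.linspace(0.0, window_ns, n_grid)
    dens = decay_curve(params, grid)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(grid))])
    cdf /= cdf[-1]
    return grid, cdf


def mean_arrival_time(hist: TCSPCHistogram) -> float:
    """Count-weighted mean of channel-center times, <t>."""
    if hist.total_photons <= 0:
        raise DomainError("histogram contains no photons; mean arrival time undefined")
    centers = hist.channel_centers()
    return float(np.sum(centers * hist.counts) / hist.total_photons)


def mean_lifetime(mean_t: float, t0: float) -> float:
    """Mean lifetime <tau> = <t> - t0 (may be negative; caller decides masking)."""
    return mean_t - t0


def _pack(params: DecayParams) -> dict:
    return {k: getattr(params, k) for k in FITTABLE}


def _unpack(values: dict) -> DecayParams:
    p_ad = min(max(values["p_ad"], 0.0), 1.0)
    return DecayParams(
        tau_d=values["tau_d"],
        tau_ad=values["tau_ad"],
        tau_g=values["tau_g"],
        t0=values["t0"],
        f0=values["f0"],
        p_d=1.0 - p_ad,
        p_ad=p_ad,
    )


def _poisson_nll(counts, mu) -> float:
    mu = np.clip(mu, 1e-300, None)
    return float(np.sum(mu - counts * np.log(mu)))


def _wls_objective(counts, mu) -> float:
    w = 1.0 / np.clip(counts, 1.0, None)
    return float(np.sum(w * (counts - mu) ** 2))


def initial_guess(hist: TCSPCHistogram, init: DecayParams | None = None) -> DecayParams:
    """Heuristic starting point: t0 near the histogram rise, f0 from the total
    photon budget, lifetimes from the supplied template (or class defaults)."""
    base = init if init is not None else DecayParams.two_state(0.3)
    centers = hist.channel_centers()
    peak_idx = int(np.argmax(hist.counts))
    t0 = max(centers[peak_idx] - 2.0 * base.tau_g, 0.0)
    mean_tau = base.p_d * base.tau_d + base.p_ad * base.tau_ad
    f0 = hist.total_photons * hist.channel_width_ns / max(mean_tau, 1e-6)
    return base.replace(t0=t0, f0=f0)


def fit_decay(
    hist: TCSPCHistogram,
    init: DecayParams,
    fixed_mask=(),
    min_photons: int = 100,
    objective: str = "poisson",
    channel_model: str = "integral",
    n_starts: int = 3,
    seed: int = DEFAULT_SEED,
) -> FitResult:
    """Maximum-likelihood fit of the two-state decay model to a histogram.

    Free parameters are optimized (L-BFGS-B, bounded); parameters named in
    ``fixed_mask`` are held at their ``init`` values exactly.  ``p_d`` is tied
    to ``1 - p_ad`` throughout (two-state constraint).  The default objective
    is the Poisson negative log-likelihood of the channel counts against the
    channel-integrated model (``channel_model="center"`` evaluates at channel
    centers instead); ``objective="wls"`` gives weighted least squares for
    cross-checks.  On non-convergence up to ``n_starts``
    perturbed restarts are tried; the result is returned with
    ``converged=False`` if all fail.
    """
    if hist.total_photons < min_photons:
        raise DomainError(
            f"insufficient photons: {hist.total_photons} < required minimum {min_photons}"
        )
    fixed_mask = tuple(fixed_mask)
    unknown = set(fixed_mask) - set(FITTABLE) - {"p_d"}
    if unknown:
        raise DomainError(f"unknown parameters in fixed_mask: {sorted(unknown)}")
    free = [k for k in FITTABLE if k not in fixed_mask and not (k == "p_ad" and "p_d" in fixed_mask)]
    if not free:
        raise DomainError("no free parameters to fit")

    edges = np.arange(hist.n_channels + 1) * hist.channel_width_ns
    counts = hist.counts.astype(float)
    obj_fun = _poisson_nll if objective == "poisson" else _wls_objective
    bounds_map = {
        "f0": (1e-12, None),
        "p_ad": (0.0, 1.0),
        "tau_d": (0.1, 10.0),
        "tau_ad": (0.1, 10.0),
        "tau_g": (1e-3, 5.0),
        "t0": (0.0, hist.window_ns),
    }
    fixed_values = _pack(init)

    def objective_vec(theta) -> float:
        vals = dict(fixed_values)
        vals.update(zip(free, theta))
        try:
            params = _unpack(vals)
        except DomainError:
            return 1e300
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mu = channel_expected_counts(params, edges, model=channel_model)
        return obj_fun(counts, mu)

    rng = np.random.default_rng(seed)
    theta0 = np.array([fixed_values[k] for k in free], dtype=float)
    # Optimize in unit-scaled coordinates with a per-photon objective so the
    # finite-difference gradient steps of L-BFGS-B resolve the likelihood for
    # any f0 magnitude or photon budget.
    par_scale = np.where(np.abs(theta0) > 1e-12, np.abs(theta0), 1.0)
    obj_scale = float(max(hist.total_photons, 1))

    def objective_scaled(u) -> float:
        return objective_vec(u * par_scale) / obj_scale

    def scale_bounds(bounds):
        return [
            (lo / s if lo is not None else None, hi / s if hi is not None else None)
            for (lo, hi), s in zip(bounds, par_scale)
        ]

    bounds = [bounds_map[k] for k in free]
    sbounds = scale_bounds(bounds)
    best = None
    for start in range(max(1, n_starts)):
        u0 = theta0 / par_scale
        if start > 0:
            u0 = u0 * (1.0 + rng.normal(0.0, 0.1, size=u0.size))
            u0 = np.array(
                [min(max(v, lo if lo is not None else v), hi if hi is not None else v)
                 for v, (lo, hi) in zip(u0, sbounds)]
            )
        res = minimize(
            objective_scaled, u0, method="L-BFGS-B", bounds=sbounds,
            options={"ftol": 1e-13, "gtol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            best = res if res.fun <= best.fun else best
            break

    vals = dict(fixed_values)
    vals.update(zip(free, best.x * par_scale))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = _unpack(vals)
    stderr = _stderr_from_hessian(objective_vec, best.x * par_scale, free)
    return FitResult(
        params=params,
        fixed_mask=fixed_mask,
        objective=float(best.fun * obj_scale),
        converged=bool(best.success),
        stderr=stderr,
        n_photons=hist.total_photons,
        message=str(best.message),
    )


def _stderr_from_hessian(fun, x, names, rel_step: float = 1e-4) -> dict:
    """Parameter uncertainties from a central-difference Hessian of the NLL."""
    n = x.size
    h = np.where(x != 0, np.abs(x), 1.0) * rel_step
    hess = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.any(diag < 0) or not np.all(np.isfinite(diag)):
            return {}
        return {k: float(math.sqrt(v)) for k, v in zip(names, diag)}
    except np.linalg.LinAlgError:
        return {}
    finally:
        del f0


def estimate_t0_global(image_summed_hist: TCSPCHistogram, init: DecayParams, **kwargs) -> float:
    """Session-level arrival-time offset from a whole-image (all pixels summed)
    fit with every parameter free; reuse for lifetime images and ROI traces."""
    fit = fit_decay(image_summed_hist, init, fixed_mask=(), **kwargs)
    return fit.params.t0


def binding_fraction(fit: FitResult) -> float:
    """Binding fraction P_AD / (P_D + P_AD) of a converged fit."""
    den = fit.params.p_d + fit.params.p_ad
    if den == 0:
        raise DomainError("p_d + p_ad is zero; binding fraction undefined")
    return fit.params.p_ad / den


def binding_fraction_from_lifetime(
    mean_tau: float, tau_d: float, tau_ad: float
) -> float:
    """Invert the two-state closed form <tau>(p_ad) for the bound fraction.

    With lifetimes fixed, the amplitude-weighted mean lifetime identifies
    p_ad exactly; the result is clipped to [0, 1].
    """
    if tau_d == tau_ad:
        raise DomainError("tau_d == tau_ad: binding fraction unidentifiable")
    num = tau_d * (tau_d - mean_tau)
    den = (tau_d - tau_ad) * (tau_d + tau_ad - mean_tau)
    if den == 0:
        raise DomainError("degenerate lifetime combination")
    return float(np.clip(num / den, 0.0, 1.0))
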