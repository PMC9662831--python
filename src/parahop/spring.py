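"""Over-damped-spring (Ornstein–Uhlenbeck) trajectory analysis.

A Brownian particle of diffusion coefficient D in a harmonic potential of
stiffness k/kBT relaxes with timescale τ = 1/(D·k/kBT).  Its transition
density over a lag δt is Gaussian with mean x0·e^(−δt/τ) (about the
equilibrium point) and variance D·τ·(1 − e^(−2δt/τ)).  Two observable
signatures identify this motion in sampled tracks:

* the stepwise velocity v = (x(t+δt) − x(t))/δt has conditional mean
  E[v|x0] = x0·(e^(−δt/τ) − 1)/δt — a linear velocity-vs-position profile of
  slope m — and position-independent variance
  Var[v] = D·τ/δt²·(1 − e^(−2δt/τ));
* the velocity autocorrelation is negative at a lag equal to the sampling
  time.

Inverting the two moments gives the estimators implemented here:
τ = −δt/ln(δt·m + 1) and D = Var[v]·ln(δt·m + 1)/(δt·m² + 2m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .simulate import Trajectory

__all__ = [
    "VelocityProfile",
    "OUEstimates",
    "stepwise_velocities",
    "pooled_velocity_pairs",
    "fit_velocity_profile",
    "ou_estimates",
    "ou_transition_density",
    "autocorr_models",
    "empirical_autocorr",
    "msd",
    "characteristic_force",
]

#: Boltzmann constant in pN·μm/K (1.380649e−23 J/K = 1.380649e−5 pN·μm/K).
KB_PN_UM = 1.380649e-5

#: Fraction of (position, velocity) points the fit region must contain,
#: the ±1σ mass of a Gaussian.
FIT_REGION_MASS = 0.6827


@dataclass
class VelocityProfile:
    """Binned velocity-vs-position profile with its central linear fit.

    Positions are relative to the trajectory mean (μm); velocities in μm/min.
    ``slope`` is the fitted m (1/min) over ``fit_region`` (lo, hi), the
    smallest symmetric interval holding at least 68.27% of the points.
    ``var_v`` is the residual velocity variance about the fit line inside the
    region.
    """

    bin_centers: np.ndarray
    mean_v: np.ndarray
    sd_v: np.ndarray
    se_v: np.ndarray
    counts: np.ndarray
    slope: float
    intercept: float
    var_v: float
    fit_region: tuple[float, float]
    n_points: int


@dataclass
class OUEstimates:
    """Fitted over-damped-spring parameters.

    ``tau`` in min, ``D`` in μm²/s, ``k_over_kBT = 1/(D·τ)`` in μm⁻² (with τ
    converted to s), ``slope`` (m) in 1/min, ``var_v`` in (μm/min)².
    """

    tau: float
    D: float
    k_over_kBT: float
    slope: float
    var_v: float
    dt_sample: float


def _series_and_dt_min(traj: Trajectory | np.ndarray, plasmid: int):
    if isinstance(traj, Trajectory):
        x = traj.series(plasmid)
        dt_min = traj.sampling_interval / 60.0
    else:
        x = np.asarray(traj, dtype=float)
        dt_min = 1.0
    x = x[~np.isnan(x)]
    return x, dt_min


def stepwise_velocities(
    traj: Trajectory | np.ndarray, plasmid: int = 0
) -> np.ndarray:
    """Pairs (x_rel, v): position relative to the trajectory mean (μm) and
    the velocity to the next frame (μm/min).

    Returns an array of shape (n−1, 2).  For a bare array input the sampling
    interval is taken as 1 min.
    """
    x, dt_min = _series_and_dt_min(traj, plasmid)
    if x.size < 2:
        raise ValueError("need at least 2 samples to form velocities")
    x_rel = x - x.mean()
    v = np.diff(x) / dt_min
    return np.column_stack([x_rel[:-1], v])


def pooled_velocity_pairs(
    trajs: Iterable[Trajectory], plasmid: int | None = None
) -> np.ndarray:
    """Pool (x_rel, v) pairs over an ensemble of trajectories.

    Each track is centred on its own mean, as in per-trajectory analysis of
    tracking data.  ``plasmid=None`` pools all plasmids of each trajectory.
    """
    chunks = []
    for t in trajs:
        ids = range(t.n_plasmids) if plasmid is None else [plasmid]
        for i in ids:
            chunks.append(stepwise_velocities(t, i))
    if not chunks:
        raise ValueError("no trajectories given")
    return np.vstack(chunks)


def _central_fit_region(x_rel: np.ndarray) -> tuple[float, float]:
    """Smallest symmetric interval about 0 holding >= 68.27% of the points."""
    r = np.sort(np.abs(x_rel))
    n = r.size
    k = int(math.ceil(FIT_REGION_MASS * n))
    k = min(max(k, 1), n)
    half = r[k - 1]
    return (-half, half)


def fit_velocity_profile(
    pairs: np.ndarray, bin_width: float = 0.05
) -> VelocityProfile:
    """Bin the velocity-vs-position pairs and fit the central linear profile.

    The fit is ordinary least squares on the raw pairs inside the smallest
    symmetric region about zero containing at least 68.27% of points; binned
    mean/sd/se are display statistics computed over all occupied bins.
    """
    pairs = np.asarray(pairs, dtype=float)
    x, v = pairs[:, 0], pairs[:, 1]
    lo, hi = _central_fit_region(x)
    in_region = (x >= lo) & (x <= hi)
    if np.unique(x[in_region]).size < 2:
        raise ValueError("all points in a single bin; cannot fit a slope")
    slope, intercept = np.polyfit(x[in_region], v[in_region], 1)
    resid = v[in_region] - (slope * x[in_region] + intercept)
    var_v = float(np.var(resid))

    edges = np.arange(
        math.floor(x.min() / bin_width) * bin_width,
        math.ceil(x.max() / bin_width) * bin_width + bin_width / 2,
        bin_width,
    )
    if edges.size < 3:
        edges = np.array([x.min(), (x.min() + x.max()) / 2, x.max()])
    idx = np.clip(np.digitize(x, edges) - 1, 0, edges.size - 2)
    centers, mean_v, sd_v, se_v, counts = [], [], [], [], []
    for b in range(edges.size - 1):
        sel = idx == b
        c = int(sel.sum())
        if c == 0:
            continue
        centers.append((edges[b] + edges[b + 1]) / 2)
        mean_v.append(v[sel].mean())
        sd = float(np.std(v[sel]))
        sd_v.append(sd)
        se_v.append(sd / math.sqrt(c))
        counts.append(c)
    if len(centers) < 2:
        raise ValueError("fewer than 2 occupied bins")
    return VelocityProfile(
        bin_centers=np.array(centers),
        mean_v=np.array(mean_v),
        sd_v=np.array(sd_v),
        se_v=np.array(se_v),
        counts=np.array(counts),
        slope=float(slope),
        intercept=float(intercept),
        var_v=var_v,
        fit_region=(lo, hi),
        n_points=int(in_region.sum()),
    )


def ou_estimates(m: float, var_v: float, dt_sample: float = 1.0) -> OUEstimates:
    """Invert the velocity-profile moments into (τ, D, k/kBT).

    ``m`` in 1/min, ``var_v`` in (μm/min)², ``dt_sample`` in min.  Requires
    −1/δt < m < 0 (a restoring slope); τ = −δt/ln(δt·m+1) is returned in min
    and D = var_v·ln(δt·m+1)/(δt·m²+2m) in μm²/s.
    """
    if var_v <= 0:
        raise ValueError("var_v must be positive")
    if not (-1.0 / dt_sample < m < 0.0):
        raise ValueError(
            f"slope m = {m} must lie in (-1/dt_sample, 0) for a finite "
            "positive relaxation time"
        )
    log_term = math.log(dt_sample * m + 1.0)
    tau_min = -dt_sample / log_term
    d_um2_per_min = var_v * log_term / (dt_sample * m * m + 2.0 * m)
    d_um2_per_s = d_um2_per_min / 60.0
    k = 1.0 / (d_um2_per_s * tau_min * 60.0)
    return OUEstimates(
        tau=tau_min,
        D=d_um2_per_s,
        k_over_kBT=k,
        slope=m,
        var_v=var_v,
        dt_sample=dt_sample,
    )


def ou_transition_density(
    x: np.ndarray | float, dt_sample: float, x0: float, D: float, tau: float
) -> np.ndarray | float:
    """Exact OU transition density p(x, δt | x0) about equilibrium 0.

    Gaussian with mean x0·e^(−δt/τ) and variance D·τ·(1 − e^(−2δt/τ)); any
    consistent time units for ``dt_sample`` and ``tau``.
    """
    if D <= 0 or tau <= 0:
        raise ValueError("D and tau must be positive")
    a = math.exp(-dt_sample / tau)
    var = D * tau * (1.0 - a * a)
    x = np.asarray(x, dtype=float)
    dens = np.exp(-((x - x0 * a) ** 2) / (2.0 * var)) / math.sqrt(
        2.0 * math.pi * var
    )
    return dens if dens.shape else float(dens)


def autocorr_models(
    t: np.ndarray | float, dt_sample: float, tau: float
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Model position and velocity autocorrelations of a stationary OU track.

    position: e^(−t/τ); velocity (sampled at δt):
    (2e^(−t/τ) − e^(−|t−δt|/τ) − e^(−(t+δt)/τ)) / (2 − 2e^(−δt/τ)).
    The velocity curve is negative at t = δt — the signature of elastic
    (spring-like) motion.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    pos = np.exp(-t / tau)
    vel = (
        2.0 * np.exp(-t / tau)
        - np.exp(-np.abs(t - dt_sample) / tau)
        - np.exp(-(t + dt_sample) / tau)
    ) / (2.0 - 2.0 * math.exp(-dt_sample / tau))
    if pos.shape == ():
        return float(pos), float(vel)
    return pos, vel


def empirical_autocorr(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Mean-subtracted, lag-0-normalised autocorrelation for lags 0..max_lag."""
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n <= max_lag or max_lag < 1:
        raise ValueError("series length must exceed max_lag >= 1")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("constant series has no autocorrelation")
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        out[k] = np.dot(x[: n - k], x[k:]) / denom
    return out


def msd(
    traj: Trajectory | np.ndarray,
    lags: Sequence[float] | None = None,
    plasmid: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged 1D mean squared displacement, long axis.

    ``lags`` in seconds (multiples of the sampling interval); defaults to all
    lags up to a quarter of the track.  Returns (lags_s, msd_um2).
    """
    if isinstance(traj, Trajectory):
        x = traj.series(plasmid)
        dt_s = traj.sampling_interval
    else:
        x = np.asarray(traj, dtype=float)
        dt_s = 1.0
    x = x[~np.isnan(x)]
    n = x.size
    if lags is None:
        ks = np.arange(1, max(2, n // 4))
    else:
        ks = []
        for lag in lags:
            k = lag / dt_s
            if abs(k - round(k)) > 1e-6:
                raise ValueError(f"lag {lag} is not a multiple of the sampling interval")
            k = int(round(k))
            if not (1 <= k < n):
                raise ValueError(f"lag {lag} outside the trajectory span")
            ks.append(k)
        ks = np.asarray(ks)
    out = np.array([np.mean((x[k:] - x[:-k]) ** 2) for k in ks])
    return ks * dt_s, out


def characteristic_force(k_over_kBT: float, T: float = 303.15) -> float:
    """Force (pN) on the particle at one standard deviation of the
    equilibrium distribution: F = kBT·sqrt(k/kBT), with k/kBT in μm⁻²."""
    if k_over_kBT < 0:
        raise ValueError("k_over_kBT must be >= 0")
    return KB_PN_UM * T * math.sqrt(k_over_kBT)
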