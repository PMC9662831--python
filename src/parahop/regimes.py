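"""Phase-space regime descriptors φ, ψ, χ and grid scanning.

Three per-trajectory quantities summarise where a parameter point sits in
the (λ, ε) phase diagram:

* φ — goodness of regular positioning: the trajectory mean position fed
  through a triangle wave that peaks (φ=1) at the n-plasmid home positions
  (2i−1)·L/(2n) and vanishes at the poles and midway between home positions;
* ψ — mobility: the position standard deviation divided by L/(n·√12), the
  standard deviation of a uniform distribution of width L/n (≈1 for a
  trajectory that sweeps its whole territory);
* χ — oscillation strength: the highest positive local maximum after the
  first negative local minimum of the position autocorrelation (0 if either
  is absent).

Scores: regular = (1−ψ)·φ, static = (1−ψ)·(1−φ), oscillation = χ, with ψ
clamped to 1.  A diffusive trajectory scores ≈0 on all three (rendered
black); each regime has a reference colour and the display colour is the
score-weighted blend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import ModelParams, dh_for_lambda
from .simulate import Trajectory, run
from .spring import empirical_autocorr

__all__ = [
    "RegimeDescriptor",
    "phi_regular",
    "psi_mobility",
    "chi_oscillation",
    "regime_descriptors",
    "classify_trajectories",
    "phase_grid",
    "smooth_score_grid",
    "REGIME_COLOURS",
]

REGIME_COLOURS = {
    "regular": np.array([255, 193, 7], dtype=float),   # light brown
    "static": np.array([30, 136, 229], dtype=float),   # blue
    "oscillation": np.array([216, 27, 96], dtype=float),  # pink
}

#: Decision thresholds for the categorical regime call: a trajectory is
#: confined when ψ is below CONFINED_PSI_MAX; a confined trajectory is at a
#: home position when φ is at least PHI_REGULAR_MIN; an unconfined one is
#: oscillatory when χ reaches OSC_CHI_MIN.
CONFINED_PSI_MAX = 0.6
PHI_REGULAR_MIN = 0.5
OSC_CHI_MIN = 0.15


@dataclass
class RegimeDescriptor:
    """φ/ψ/χ values, regime scores and display colour for one trajectory."""

    phi: float
    psi: float
    chi: float
    score_regular: float
    score_static: float
    score_osc: float
    colour: np.ndarray

    @property
    def dominant(self) -> str:
        """Categorical regime call, mirroring the phase-diagram legend:
        confined with mean at a home position → regular; confined elsewhere
        → static; unconfined with an autocorrelation oscillation peak →
        oscillation; otherwise diffusive."""
        if self.psi <= CONFINED_PSI_MAX:
            return "regular" if self.phi >= PHI_REGULAR_MIN else "static"
        if self.chi >= OSC_CHI_MIN:
            return "oscillation"
        return "diffusive"


def phi_regular(mean_x: float, L: float, n: int = 1) -> float:
    """Triangle-wave goodness of regular positioning.

    ``mean_x`` is the trajectory mean in absolute nucleoid coordinates
    [0, L].  φ = 1 − 2·|frac(n·x/L) − 0.5|: 1 at the home positions
    (2i−1)·L/(2n), 0 at the poles and midway between home positions.
    """
    if not (0.0 <= mean_x <= L):
        raise ValueError(f"mean position {mean_x} outside [0, {L}]")
    if n < 1:
        raise ValueError("n must be >= 1")
    u = n * mean_x / L
    return 1.0 - 2.0 * abs(u - math.floor(u) - 0.5)


def psi_mobility(std_x: float, L: float, n: int = 1) -> float:
    """Mobility: position sd over the sd of a uniform distribution of width
    L/n.  Unclamped (can exceed 1); scoring clamps at 1."""
    if std_x < 0:
        raise ValueError("std_x must be >= 0")
    return std_x * n * math.sqrt(12.0) / L


def chi_oscillation(positions: np.ndarray) -> float:
    """Oscillation strength from the position autocorrelation.

    Scans lags 1..len//2 of the normalised autocorrelation for the first
    local minimum with a negative value, then returns the largest positive
    local-maximum value at any later lag; 0 if either feature is absent.
    Invariant under shift and positive scaling of the series.
    """
    x = np.asarray(positions, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    max_lag = x.size // 2
    ac = empirical_autocorr(x, max_lag)
    d = np.diff(ac)
    # local extrema strictly inside 1..max_lag-1 by sign change of first diff
    first_min = None
    for k in range(1, max_lag):
        if d[k - 1] < 0.0 <= d[k] and ac[k] < 0.0:
            first_min = k
            break
    if first_min is None:
        return 0.0
    best = 0.0
    for k in range(first_min + 1, max_lag):
        if d[k - 1] > 0.0 >= d[k] and ac[k] > best:
            best = ac[k]
    return float(best)


def _descriptor_from_values(phi: float, psi: float, chi: float) -> RegimeDescriptor:
    psi_c = min(psi, 1.0)
    s_reg = (1.0 - psi_c) * phi
    s_sta = (1.0 - psi_c) * (1.0 - phi)
    s_osc = chi
    colour = (
        s_reg * REGIME_COLOURS["regular"]
        + s_sta * REGIME_COLOURS["static"]
        + s_osc * REGIME_COLOURS["oscillation"]
    )
    return RegimeDescriptor(
        phi=phi,
        psi=psi,
        chi=chi,
        score_regular=s_reg,
        score_static=s_sta,
        score_osc=s_osc,
        colour=np.clip(colour, 0, 255),
    )


def regime_descriptors(
    traj: Trajectory, n: int | None = None, plasmid: int = 0
) -> RegimeDescriptor:
    """Compute φ/ψ/χ and regime scores for one plasmid track.

    Positions are converted from mid-relative to absolute nucleoid
    coordinates for φ.  ``n`` defaults to the trajectory's plasmid count.
    """
    if n is None:
        n = traj.n_plasmids
    x = traj.series(plasmid)
    x = x[~np.isnan(x)]
    x_abs = np.clip(x + traj.L / 2.0, 0.0, traj.L)
    phi = phi_regular(float(x_abs.mean()), traj.L, n)
    psi = psi_mobility(float(x_abs.std()), traj.L, n)
    chi = chi_oscillation(x)
    return _descriptor_from_values(phi, psi, chi)


def classify_trajectories(
    trajs: Sequence[Trajectory], n: int | None = None
) -> RegimeDescriptor:
    """Ensemble descriptor: mean φ/ψ/χ over all plasmid tracks."""
    phis, psis, chis = [], [], []
    for t in trajs:
        nn = t.n_plasmids if n is None else n
        for i in range(t.n_plasmids):
            d = regime_descriptors(t, nn, plasmid=i)
            phis.append(d.phi)
            psis.append(d.psi)
            chis.append(d.chi)
    return _descriptor_from_values(
        float(np.mean(phis)), float(np.mean(psis)), float(np.mean(chis))
    )


def phase_grid(
    lam_values: Sequence[float],
    eps_values: Sequence[float],
    base_params: ModelParams,
    duration: float = 2100.0,
    burn_in: float = 600.0,
    sampling_interval: float = 60.0,
    seeds: Sequence[int] = (0,),
    smooth: bool = False,
) -> list[list[RegimeDescriptor | None]]:
    """Scan the (λ, ε) plane: λ realised by varying Dh, ε by varying kh.

    Returns a grid ``out[i][j]`` of ensemble descriptors for
    (lam_values[i], eps_values[j]); a cell whose realised parameters are
    invalid is left as None and the scan continues.  ``smooth=True`` applies
    morphological opening + Gaussian smoothing to each score channel
    (display only; never applied before numeric checks).
    """
    out: list[list[RegimeDescriptor | None]] = []
    for lam in lam_values:
        row: list[RegimeDescriptor | None] = []
        for eps in eps_values:
            try:
                p = base_params.replace(
                    Dh=dh_for_lambda(lam, base_params.L, base_params.kd),
                    kh=eps * base_params.kd,
                )
            except ValueError:
                row.append(None)  # cell unrealisable; scan continues
                continue
            trajs = [
                run(p, duration, burn_in, sampling_interval, seed=s)
                for s in seeds
            ]
            row.append(classify_trajectories(trajs))
        out.append(row)
    if smooth:
        out = _smooth_grid(out)
    return out


def smooth_score_grid(scores: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Morphological opening (3×3 square) then Gaussian filter on one score
    channel, as used to smoothen rendered phase diagrams."""
    from skimage.morphology import opening, footprint_rectangle
    from scipy.ndimage import gaussian_filter

    opened = opening(scores, footprint_rectangle((3, 3)))
    return gaussian_filter(opened, sigma=sigma)


def _smooth_grid(grid):
    shape = (len(grid), len(grid[0]))
    channels = {}
    for name in ("score_regular", "score_static", "score_osc"):
        arr = np.zeros(shape)
        for i, row in enumerate(grid):
            for j, d in enumerate(row):
                arr[i, j] = getattr(d, name) if d is not None else 0.0
        channels[name] = smooth_score_grid(arr)
    out = []
    for i, row in enumerate(grid):
        new_row = []
        for j, d in enumerate(row):
            if d is None:
                new_row.append(None)
                continue
            s_reg = channels["score_regular"][i, j]
            s_sta = channels["score_static"][i, j]
            s_osc = channels["score_osc"][i, j]
            colour = np.clip(
                s_reg * REGIME_COLOURS["regular"]
                + s_sta * REGIME_COLOURS["static"]
                + s_osc * REGIME_COLOURS["oscillation"],
                0,
                255,
            )
            new_row.append(
                RegimeDescriptor(
                    phi=d.phi,
                    psi=d.psi,
                    chi=d.chi,
                    score_regular=float(s_reg),
                    score_static=float(s_sta),
                    score_osc=float(s_osc),
                    colour=colour,
                )
            )
        out.append(new_row)
    return out
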