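"""Synthetic trajectories with known ground truth.

Three generators cover the statistical structures the analysis toolkit must
distinguish: an exact-discretisation Ornstein–Uhlenbeck track (spring-like
regular positioning), a pure-diffusion random walk with reflecting walls,
and a noisy triangle wave (the back-and-forth motion of the oscillatory
regime).  Defaults mirror experimental tracking scales: 60 s sampling and
D, τ at the magnitudes fitted for F plasmid (D ≈ 2.27×10⁻⁴ μm²/s,
τ ≈ 2 min).

OU generation uses the exact discrete transition density, so analysis tests
carry no time-discretisation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import Trajectory

__all__ = ["SyntheticSpec", "gen_ou", "gen_diffusion", "gen_triangle"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of a synthetic track.

    ``kind`` ∈ {"ou", "diffusion", "triangle"}.  ``D`` (μm²/s) and ``tau``
    (s) apply to ou/diffusion; ``amplitude`` (μm), ``period`` (s) and
    ``noise_sd`` (μm) to triangle.  ``dt_sample`` in s; positions are
    mid-relative within a cell of length ``cell_length`` (μm).
    """

    kind: str
    dt_sample: float = 60.0
    n_steps: int = 100
    seed: int = 0
    cell_length: float = 2.53
    mean_x: float = 0.0
    D: float = 2.27e-4
    tau: float = 120.0
    amplitude: float = 0.8
    period: float = 600.0
    noise_sd: float = 0.05

    def validate(self) -> "SyntheticSpec":
        if self.kind not in ("ou", "diffusion", "triangle"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.dt_sample <= 0 or self.n_steps < 2 or self.cell_length <= 0:
            raise ValueError("dt_sample > 0, n_steps >= 2, cell_length > 0 required")
        if self.kind in ("ou", "diffusion") and self.D <= 0:
            raise ValueError("D must be positive")
        if self.kind == "ou" and self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.kind == "triangle":
            if self.amplitude <= 0 or self.period <= 0 or self.noise_sd < 0:
                raise ValueError("amplitude, period > 0 and noise_sd >= 0 required")
            if abs(self.mean_x) + self.amplitude > self.cell_length / 2.0:
                raise ValueError("triangle wave exceeds the cell half-length")
        return self


def _wrap(spec: SyntheticSpec, x: np.ndarray) -> Trajectory:
    n = x.size
    return Trajectory(
        times=np.arange(n) * spec.dt_sample,
        positions=x[:, None],
        tether_counts=np.zeros((n, 1), dtype=np.int64),
        sampling_interval=spec.dt_sample,
        L=spec.cell_length,
        seed=spec.seed,
        duration=(n - 1) * spec.dt_sample,
        cell_id=f"synth-{spec.kind}",
        plasmid_ids=["0"],
    )


def gen_ou(spec: SyntheticSpec) -> Trajectory:
    """Stationary OU track by the exact discrete transition.

    x₀ ~ N(mean_x, D·τ); then x_{k+1} = mean_x + (x_k − mean_x)·a + ξ with
    a = e^(−δt/τ) and ξ ~ N(0, D·τ·(1−a²)).
    """
    spec = spec.validate()
    if spec.kind != "ou":
        raise ValueError("spec.kind must be 'ou'")
    rng = np.random.default_rng(spec.seed)
    a = math.exp(-spec.dt_sample / spec.tau)
    stat_sd = math.sqrt(spec.D * spec.tau)
    step_sd = stat_sd * math.sqrt(1.0 - a * a)
    x = np.empty(spec.n_steps)
    x[0] = spec.mean_x + rng.normal() * stat_sd
    noise = rng.normal(size=spec.n_steps - 1) * step_sd
    for k in range(1, spec.n_steps):
        x[k] = spec.mean_x + (x[k - 1] - spec.mean_x) * a + noise[k - 1]
    return _wrap(spec, x)


def gen_diffusion(spec: SyntheticSpec) -> Trajectory:
    """Pure-diffusion track: Gaussian steps of sd sqrt(2·D·δt), reflected at
    ±cell_length/2."""
    spec = spec.validate()
    if spec.kind != "diffusion":
        raise ValueError("spec.kind must be 'diffusion'")
    rng = np.random.default_rng(spec.seed)
    half = spec.cell_length / 2.0
    steps = rng.normal(size=spec.n_steps - 1) * math.sqrt(2.0 * spec.D * spec.dt_sample)
    x = np.empty(spec.n_steps)
    x[0] = min(max(spec.mean_x, -half), half)
    for k in range(1, spec.n_steps):
        y = x[k - 1] + steps[k - 1]
        # specular reflection into [-half, half]
        period = 2.0 * spec.cell_length
        y = (y + half) % period
        if y > spec.cell_length:
            y = period - y
        x[k] = y - half
    return _wrap(spec, x)


def gen_triangle(spec: SyntheticSpec) -> Trajectory:
    """Deterministic triangle wave about ``mean_x`` plus Gaussian noise."""
    spec = spec.validate()
    if spec.kind != "triangle":
        raise ValueError("spec.kind must be 'triangle'")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_steps) * spec.dt_sample
    phase = (t / spec.period) % 1.0
    wave = spec.amplitude * (4.0 * np.abs(phase - 0.5) - 1.0)
    x = spec.mean_x + wave
    if spec.noise_sd > 0:
        x = x + rng.normal(size=spec.n_steps) * spec.noise_sd
    return _wrap(spec, x)
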