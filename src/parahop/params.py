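"""Model parameters and the dimensionless quantities that organise the phase space.

The hopping-and-relay model of ParABS plasmid positioning is controlled by a
small set of physical parameters: binding/hydrolysis rates of ParA-ATP dimers
(``ka``, ``kd``, ``kh``), diffusion coefficients (``Dp``, ``Dh``, ``DA``),
the geometry of the nucleoid rectangle (``L``, ``W``) and the elastic
fluctuation widths of the chromosome (``sigma_x``, ``sigma_y``).  All lengths
are in μm and all times in s, package-wide.

Three dimensionless combinations organise the dynamics:

* ``λ = sqrt(2·Dh/kd) / (L/2)`` — the distance a bound dimer diffuses (hops)
  on the nucleoid before basal hydrolysis releases it, relative to half the
  nucleoid length.  Regular positioning requires λ ≳ 1.
* ``ε = kh/kd`` — ParB-stimulated versus basal hydrolysis.  Large ε depletes
  ParA at the plasmid and gates the oscillatory instability (onset near
  ε ≈ 10).
* ``θ = nA·ka/(ka+kd)`` — the steady-state number of nucleoid-bound dimers in
  the absence of a plasmid.

For n plasmids the relevant scale is ``λn = n·λ``: each plasmid only needs to
"sense" a 1/n fraction of the nucleoid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

__all__ = [
    "ModelParams",
    "DimensionlessParams",
    "dimensionless_params",
    "validate_params",
    "make_params",
    "PRESETS",
    "preset",
]

#: Default parameter values (SI-μm units).  ``kh`` and ``Dh`` are swept
#: quantities with no single default and must always be supplied.
_DEFAULTS = dict(
    ka=0.19,        # 1/s, association rate to the nucleoid of cytosolic ParA
    kd=0.01,        # 1/s, dissociation due to basal hydrolysis
    Dp=3.0e-3,      # μm²/s, intrinsic plasmid diffusion
    DA=0.01,        # μm²/s, bound-ParA diffusion due to chromosome fluctuations
    sigma_x=0.1,    # μm, elastic fluctuation width, long axis
    sigma_y=0.05,   # μm, elastic fluctuation width, short axis
    Rp=0.05,        # μm, plasmid disk radius
    RA=0.002,       # μm, ParA radius
    nA=500,         # ParA dimer count
    np=1,           # plasmid count
    L=2.53,         # μm, nucleoid length
    W=0.95,         # μm, nucleoid width
    dt=0.001,       # s, simulation time step
)


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the hopping-and-relay model.

    Rates in 1/s, diffusion coefficients in μm²/s, lengths in μm, ``dt`` in s.
    ``kh`` (ParB-stimulated hydrolysis) and ``Dh`` (hopping diffusion) have no
    default: they are the quantities swept to move through the phase diagram.
    """

    kh: float
    Dh: float
    ka: float = _DEFAULTS["ka"]
    kd: float = _DEFAULTS["kd"]
    Dp: float = _DEFAULTS["Dp"]
    DA: float = _DEFAULTS["DA"]
    sigma_x: float = _DEFAULTS["sigma_x"]
    sigma_y: float = _DEFAULTS["sigma_y"]
    Rp: float = _DEFAULTS["Rp"]
    RA: float = _DEFAULTS["RA"]
    nA: int = _DEFAULTS["nA"]
    np: int = _DEFAULTS["np"]
    L: float = _DEFAULTS["L"]
    W: float = _DEFAULTS["W"]
    dt: float = _DEFAULTS["dt"]

    def replace(self, **overrides) -> "ModelParams":
        return validate_params(replace(self, **overrides))


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless characterisation of a parameter point.

    ``s`` is the diffusive length scale sqrt(2·Dh/kd) in μm; ``lam``, ``eps``,
    ``theta`` and ``lam_n`` are λ, ε, θ and λn = np·λ.
    """

    s: float
    lam: float
    eps: float
    theta: float
    lam_n: float


class ParameterError(ValueError):
    """A model parameter violates one of its invariants."""


def validate_params(params: ModelParams | Mapping[str, float]) -> ModelParams:
    """Check all parameter invariants, filling missing fields from defaults.

    Accepts a :class:`ModelParams` or a plain mapping of field names.  Raises
    :class:`ParameterError` naming the offending field and bound.
    """
    if isinstance(params, Mapping):
        unknown = set(params) - {f.name for f in fields(ModelParams)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        params = ModelParams(**params)

    p = params
    for name in ("ka", "kd", "kh"):
        if getattr(p, name) < 0:
            raise ParameterError(f"{name} must be >= 0, got {getattr(p, name)}")
    for name in ("Dp", "Dh", "DA"):
        if getattr(p, name) < 0:
            raise ParameterError(f"{name} must be >= 0, got {getattr(p, name)}")
    for name in ("sigma_x", "sigma_y", "Rp", "RA", "L", "W", "dt"):
        if getattr(p, name) <= 0:
            raise ParameterError(f"{name} must be > 0, got {getattr(p, name)}")
    max_rate = max(p.ka, p.kd, p.kh)
    if p.dt * max_rate >= 0.1:
        raise ParameterError(
            f"dt*max(ka,kd,kh) = {p.dt * max_rate:.3g} must be < 0.1 so that "
            "per-step event probabilities stay small"
        )
    if 2.0 * (p.Rp + p.RA) >= p.W:
        raise ParameterError(
            f"plasmid contact diameter 2*(Rp+RA) = {2 * (p.Rp + p.RA):.3g} μm "
            f"must be < nucleoid width W = {p.W:.3g} μm"
        )
    for name in ("nA", "np"):
        v = getattr(p, name)
        if v < 0 or v != int(v):
            raise ParameterError(f"{name} must be a non-negative integer, got {v}")
    return p


def make_params(**overrides) -> ModelParams:
    """Build a validated :class:`ModelParams` from keyword overrides."""
    return validate_params(overrides)


def dimensionless_params(params: ModelParams) -> DimensionlessParams:
    """Compute (s, λ, ε, θ, λn) for a parameter point.

    ``kd = 0`` is the no-basal-hydrolysis limit of earlier models in which a
    dimer diffuses unboundedly before release; λ is then reported as ``inf``
    with a warning rather than raising.
    """
    p = params
    if p.kd > 0:
        s = math.sqrt(2.0 * p.Dh / p.kd)
        eps = p.kh / p.kd
    else:
        warnings.warn(
            "kd = 0: the diffusive length scale is infinite (the λ=∞ limit); "
            "λ and ε reported as inf",
            stacklevel=2,
        )
        s = math.inf if p.Dh > 0 else 0.0
        eps = math.inf if p.kh > 0 else 0.0
    lam = s / (p.L / 2.0)
    denom = p.ka + p.kd
    theta = p.nA * p.ka / denom if denom > 0 else 0.0
    return DimensionlessParams(s=s, lam=lam, eps=eps, theta=theta, lam_n=p.np * lam)


def dh_for_lambda(lam: float, L: float, kd: float) -> float:
    """Invert λ(Dh): the hopping coefficient realising a target λ."""
    s = lam * L / 2.0
    return s * s * kd / 2.0


def kh_for_epsilon(eps: float, kd: float) -> float:
    """Invert ε(kh)."""
    return eps * kd


#: Named parameter sets for the published per-figure parameter
#: combinations: (kh, Dh, L, np) overrides on the defaults above.
PRESETS: dict[str, dict] = {
    # phase-diagram example panels, single plasmid on a 2.53 μm nucleoid
    "fig3C": dict(kh=0.0133, Dh=0.000440, L=2.53, np=1),   # static
    "fig3D": dict(kh=0.0769, Dh=0.000440, L=2.53, np=1),   # diffusive
    "fig3E": dict(kh=0.1785, Dh=0.000623, L=2.53, np=1),   # oscillatory
    "fig3F": dict(kh=0.0752, Dh=0.002497, L=2.53, np=1),
    "fig3G": dict(kh=0.5642, Dh=0.014162, L=2.53, np=1),
    "fig3H": dict(kh=0.5642, Dh=0.056760, L=2.53, np=1),   # regular positioning
    # fitted single-plasmid point, (λ,ε) = (2.66, 56.42)
    "fig4": dict(kh=0.5642, Dh=0.056760, L=2.53, np=1),
    # two plasmids on the longer nucleoid matched to two-focus cells
    "fig5": dict(kh=0.5642, Dh=0.056760, L=2.91, np=2),
    # replication run: starts with one plasmid, duplicated mid-run
    "fig5rep": dict(kh=0.5642, Dh=0.007179, L=2.91, np=1),
    # length sweep end-points at the fitted rates
    "fig6short": dict(kh=0.5642, Dh=0.056760, L=1.82, np=1),
    "fig6long": dict(kh=0.5642, Dh=0.056760, L=4.93, np=1),
}


def preset(name: str, **overrides) -> ModelParams:
    """Return the validated parameter set for a named figure preset."""
    try:
        base = dict(PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    base.update(overrides)
    return make_params(**base)
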