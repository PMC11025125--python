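"""Osmotic-ensemble thermodynamics: chemical-potential/pressure
conversion and the direct/indirect pressure decomposition.

In the osmotic-stress setup the water between the surfaces exchanges
with a reservoir at chemical potential ``mu_osm`` and hydrostatic
pressure ``Pi_osm``.  To first order in the pressure difference the
Gibbs-Duhem relation converts a measured chemical potential into the
equivalent hydrostatic pressure acting between the surfaces,

    Pi = Pi_osm + (mu - mu_osm) / v_w,

with ``v_w = 0.0304 nm^3`` the bulk molecular volume of water.  The
total hydration pressure splits into a direct surface-surface part and
the water-mediated remainder, ``Pi = Pi_dir + Pi_ind``; in the systems
modelled here the direct part is strongly attractive while the indirect
part is repulsive and overcompensates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ExtrapolationError, ValidationError
from .units import WATER_MOLECULAR_VOLUME

Contribution = Literal["total", "direct", "indirect"]
Ensemble = Literal["osmotic", "fixed_volume"]


@dataclass(frozen=True)
class PressureDistanceCurve:
    """(d, Pi) samples for one pressure contribution."""

    d: np.ndarray  # nm, strictly increasing
    pressure: np.ndarray  # kT/nm^3 unless units says otherwise
    contribution: Contribution = "total"
    ensemble: Ensemble = "osmotic"
    units: str = "kT/nm^3"

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "pressure", p)
        if d.ndim != 1 or p.shape != d.shape:
            raise ValidationError("d and pressure must be matching 1-D arrays")
        if np.any(np.diff(d) <= 0):
            raise ValidationError("separations must be strictly increasing")
        if self.contribution not in ("total", "direct", "indirect"):
            raise ValidationError(f"unknown contribution {self.contribution!r}")


@dataclass(frozen=True)
class ChemicalPotentialCurve:
    """Chemical potential versus water number at fixed volume or pressure."""

    n_water: np.ndarray
    mu: np.ndarray  # kT per molecule
    fixed: Literal["pressure", "volume"] = "volume"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = np.asarray(self.n_water, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "n_water", n)
        object.__setattr__(self, "mu", mu)
        if n.ndim != 1 or mu.shape != n.shape:
            raise ValidationError("n_water and mu must be matching 1-D arrays")
        if np.any(np.diff(n) <= 0):
            raise ValidationError("n_water must be strictly increasing")
        if not np.all(np.isfinite(mu)):
            raise ValidationError("mu must be finite")


def equivalent_pressure(mu, mu_osm: float, pi_osm: float,
                        v_w: float = WATER_MOLECULAR_VOLUME):
    """Equivalent hydrostatic pressure from a chemical potential (kT/nm^3).

    Linear Gibbs-Duhem form ``Pi = Pi_osm + (mu - mu_osm)/v_w``; exact
    to first order in Pi - Pi_osm for incompressible water.  Accepts
    scalars or arrays in ``mu``.
    """
    if v_w <= 0:
        raise ValidationError(f"v_w must be positive, got {v_w}")
    mu = np.asarray(mu, dtype=float)
    out = pi_osm + (mu - mu_osm) / v_w
    return float(out) if out.ndim == 0 else out


def decompose_pressure(
    total: PressureDistanceCurve, direct: PressureDistanceCurve
) -> PressureDistanceCurve:
    """Indirect water-mediated pressure ``Pi_ind = Pi - Pi_dir``.

    The direct curve is interpolated onto the total curve's separations
    where the grids differ; separations of the total curve outside the
    direct curve's range are refused.
    """
    if total.d[0] < direct.d[0] - 1e-12 or total.d[-1] > direct.d[-1] + 1e-12:
        raise ValidationError(
            "total-curve separations extend beyond the direct curve; "
            "cannot decompose without extrapolation"
        )
    if total.d.shape == direct.d.shape and np.allclose(total.d, direct.d):
        direct_p = direct.pressure
    else:
        direct_p = PchipInterpolator(direct.d, direct.pressure)(total.d)
    return PressureDistanceCurve(
        d=total.d,
        pressure=total.pressure - direct_p,
        contribution="indirect",
        ensemble=total.ensemble,
        units=total.units,
    )


def recompose_pressure(
    direct: PressureDistanceCurve, indirect: PressureDistanceCurve
) -> PressureDistanceCurve:
    """Total pressure ``Pi = Pi_dir + Pi_ind`` on the common grid."""
    if direct.d.shape != indirect.d.shape or not np.allclose(direct.d, indirect.d):
        raise ValidationError("recompose requires matching separation grids")
    return PressureDistanceCurve(
        d=direct.d,
        pressure=direct.pressure + indirect.pressure,
        contribution="total",
        ensemble=direct.ensemble,
        units=direct.units,
    )


def interpolate_to_bulk_mu(
    curve: ChemicalPotentialCurve, pressures, mu_bulk: float
) -> tuple[float, float]:
    """Water number and pressure at the bulk chemical potential.

    Monotone piecewise-cubic (PCHIP) interpolation of ``N_w(mu)`` and
    ``Pi(mu)``; this mirrors the constant-volume protocol in which the
    water number is adjusted until the confined water is in equilibrium
    with bulk.  ``mu_bulk`` outside the sampled range is refused rather
    than extrapolated.
    """
    mu = curve.mu
    sign = 1.0
    if np.all(np.diff(mu) < 0):
        sign = -1.0  # repulsive branch: mu decreases toward bulk as water is added
    elif np.any(np.diff(mu) <= 0):
        raise ValidationError("mu must be strictly monotone in n_water")
    mu = sign * mu
    mu_bulk = sign * mu_bulk
    if not (mu[0] <= mu_bulk <= mu[-1]):
        raise ExtrapolationError(
            f"mu_bulk = {sign * mu_bulk} outside sampled range "
            f"[{sign * mu[0]}, {sign * mu[-1]}]"
        )
    pressures = np.asarray(pressures, dtype=float)
    if pressures.shape != mu.shape:
        raise ValidationError("pressures must match the curve's sampling")
    exact = np.nonzero(mu == mu_bulk)[0]
    if exact.size:
        i = int(exact[0])
        return float(curve.n_water[i]), float(pressures[i])
    n_star = float(PchipInterpolator(mu, curve.n_water)(mu_bulk))
    p_star = float(PchipInterpolator(mu, pressures)(mu_bulk))
    return n_star, p_star
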