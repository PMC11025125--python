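"""Surface-separation definitions for hydrated planar surfaces.

Three separations are in use for stacked bilayers: the periodic repeat
distance ``d_rep``, the water-slab thickness ``d_w = N_w v_w / A``
(equivalently the distance between the two Gibbs dividing surfaces of
the water density profile), and the structural headgroup-headgroup
distance ``d_s`` (oxygen atoms for alcohol surfaces, phosphorus for
phosphatidylcholine).  The separation entering the Landau-Ginzburg
analysis is ``d = d_s - d_s0`` with the zero-hydration offset ``d_s0``
(0.27 nm for grafted-decanol surfaces, 0.46 nm for DPPC), chosen so
that d vanishes in the absence of hydration water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ValidationError
from .units import WATER_MOLECULAR_VOLUME

#: zero-hydration structural offsets, nm
D_S0_DECANOL = 0.27
D_S0_DPPC = 0.46


@dataclass(frozen=True)
class SeparationRecord:
    """The separation bookkeeping for one state point (all nm)."""

    d_s: float  # structural headgroup-headgroup distance
    d: float  # d_s - d_s0
    d_s0: float  # zero-hydration offset
    d_w: float | None = None  # water-slab thickness
    d_rep: float | None = None  # periodic repeat distance

    def __post_init__(self) -> None:
        if abs(self.d - (self.d_s - self.d_s0)) > 1e-12:
            raise ValidationError("d must equal d_s - d_s0")
        if self.d_w is not None and self.d_w < 0:
            raise ValidationError("d_w must be nonnegative")
        if self.d_rep is not None and self.d_w is not None and self.d_rep < self.d_w:
            raise ValidationError("d_rep must be >= d_w")


def water_slab_thickness(
    n_water: int, area: float, v_w: float = WATER_MOLECULAR_VOLUME
) -> float:
    """Thermodynamic water-slab thickness ``d_w = N_w v_w / A`` (nm)."""
    if area <= 0:
        raise ValidationError(f"area must be positive, got {area}")
    if n_water < 0 or v_w <= 0:
        raise ValidationError("n_water must be >= 0 and v_w > 0")
    return n_water * v_w / area


def structural_separation(
    upper_positions, lower_positions, d_s0: float
) -> tuple[float, float]:
    """Structural separation from opposing headgroup z positions.

    Returns ``(d_s, d)`` with ``d_s`` the difference of the mean
    headgroup z positions and ``d = d_s - d_s0``.
    """
    upper = np.asarray(upper_positions, dtype=float)
    lower = np.asarray(lower_positions, dtype=float)
    if upper.size == 0 or lower.size == 0:
        raise ValidationError("headgroup selections must be nonempty")
    d_s = float(np.mean(upper) - np.mean(lower))
    return d_s, d_s - d_s0


class GibbsSurfaces(NamedTuple):
    z_lower: float
    z_upper: float
    bulk_density: float
    flagged: bool


def gibbs_dividing_surfaces(
    z: np.ndarray,
    density: np.ndarray,
    bulk_density: float | None = None,
    plateau_fraction: float = 0.2,
    plateau_rtol: float = 0.05,
) -> GibbsSurfaces:
    """Gibbs dividing surfaces of a water slab density profile.

    Equal-area construction per interface: each dividing surface is
    placed so that a step profile at ``bulk_density`` conserves the
    integrated water mass on its side of the slab center.  If
    ``bulk_density`` is not given it is taken as the mean over the
    central ``plateau_fraction`` of the slab; a missing interior plateau
    (relative variation above ``plateau_rtol``) triggers a warning and
    the best-effort result is flagged.

    ``z_upper - z_lower`` equals ``N_w v_w / A`` for consistent inputs
    up to discretization error.
    """
    z = np.asarray(z, dtype=float)
    rho = np.asarray(density, dtype=float)
    if z.ndim != 1 or rho.shape != z.shape or z.size < 5:
        raise ValidationError("need matching 1-D profiles with >= 5 points")
    if np.any(np.diff(z) <= 0):
        raise ValidationError("z grid must be strictly increasing")
    mass = np.trapezoid(rho, z)
    if mass <= 0:
        raise ValidationError("density profile carries no mass")

    z_c = float(np.trapezoid(rho * z, z) / mass)

    flagged = False
    # interior plateau: central fraction of the mass-weighted support
    half_width = plateau_fraction * (z[-1] - z[0]) / 2.0
    sel = np.abs(z - z_c) <= half_width
    plateau = rho[sel]
    if plateau.size < 3 or np.mean(plateau) <= 0:
        flagged = True
        plateau = rho[rho > 0.5 * np.max(rho)]
    est_bulk = float(np.mean(plateau))
    if np.std(plateau) > plateau_rtol * est_bulk:
        flagged = True
    if bulk_density is None:
        bulk_density = est_bulk
    if flagged:
        warnings.warn(
            "no clear interior density plateau; Gibbs surfaces are best-effort",
            RuntimeWarning,
            stacklevel=2,
        )

    below = z <= z_c
    mass_low = np.trapezoid(np.where(below, rho, 0.0), z)
    mass_high = mass - mass_low
    z_lower = z_c - mass_low / bulk_density
    z_upper = z_c + mass_high / bulk_density
    return GibbsSurfaces(float(z_lower), float(z_upper), float(bulk_density), flagged)
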