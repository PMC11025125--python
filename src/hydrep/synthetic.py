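"""Synthetic water-slab and pressure-curve generation.

The generator emulates the statistical structure of the molecular
ensembles the analysis consumes, without molecular dynamics: rigid
3-site waters are placed uniformly between two implicit planar walls,
and each molecule's dipole orientation is drawn from an exponentially
tilted axial distribution ``p(u_z) ~ exp(alpha(z) u_z)`` whose tilt is
chosen, by inverting the Langevin function ``L(alpha) = coth(alpha) -
1/alpha``, so that the ensemble-mean dipolar density follows the
sinh-shaped Landau-Ginzburg target profile.  Pressure-distance and
chemical-potential curves are built from the same closed forms the
analysis fits, plus seeded noise, so that every planted parameter can
be recovered end to end.

Intermolecular interactions are deliberately absent: the analysis only
consumes laterally averaged profiles and curves, not liquid structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .errors import ValidationError
from .lg_model import LGParameters, indirect_pressure, surface_value
from .multipole import MolecularConfiguration
from .thermo import ChemicalPotentialCurve, PressureDistanceCurve, equivalent_pressure
from .units import (
    SPCE_HOH_ANGLE_DEG,
    SPCE_OH_BOND,
    SPCE_Q_H,
    SPCE_Q_O,
    WATER_MOLECULAR_VOLUME,
    kT_per_nm3_to_bar,
)

#: bulk water chemical potential scale used by the mu-curve emulator, kT
MU_BULK_KT = -11.9


@dataclass(frozen=True)
class WaterTemplate:
    """Rigid 3-site water geometry and charges (default: SPC/E)."""

    oh_bond: float = SPCE_OH_BOND  # nm
    hoh_angle_deg: float = SPCE_HOH_ANGLE_DEG
    q_O: float = SPCE_Q_O  # e
    q_H: float = SPCE_Q_H  # e

    @property
    def dipole_moment(self) -> float:
        """|p| of the rigid geometry, e*nm."""
        return 2.0 * self.q_H * self.oh_bond * math.cos(
            math.radians(self.hoh_angle_deg / 2.0)
        )

    @property
    def charges(self) -> np.ndarray:
        return np.array([self.q_O, self.q_H, self.q_H])


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic system.

    Defaults are the liquid-phase DPPC conditions: correlation length
    0.22 nm, rescaled surface field -0.273 e/nm, stiffness 492 nm/e^2,
    5x10^4 waters in a d = 2 nm slab at bulk density, 5% multiplicative
    noise on pressure curves.  The direct pressure is an attractive
    exponential whose magnitude stays below the indirect repulsion so
    the total remains repulsive.
    """

    n_water: int = 50_000
    d: float = 2.0  # nm
    area: float | None = None  # nm^2; default fills the slab at bulk density
    lam: float = 0.22  # nm
    h_over_a: float = -0.273  # e/nm
    a: float = 492.0  # nm/e^2
    noise_level: float = 0.05
    seed: int = 0
    direct_amplitude: float = 200.0  # kT/nm^3 (attractive prefactor)
    direct_decay: float | None = None  # nm; default = lam
    v_w: float = WATER_MOLECULAR_VOLUME
    temperature_K: float = 300.0
    margin: float = 0.2  # nm of empty box beyond each wall, keeps molecules whole
    taper: float = 0.2  # nm over which the density decays to zero at each wall
    water_geometry: WaterTemplate = field(default_factory=WaterTemplate)

    def __post_init__(self) -> None:
        if self.n_water <= 0 or self.d <= 0 or self.lam <= 0 or self.a <= 0:
            raise ValidationError("n_water, d, lam and a must be positive")
        if self.noise_level < 0:
            raise ValidationError("noise_level must be >= 0")

    @property
    def resolved_area(self) -> float:
        return self.area if self.area is not None else self.n_water * self.v_w / self.d

    @property
    def lg_params(self) -> LGParameters:
        return LGParameters.from_correlation_length(
            a=self.a, lam=self.lam, h_over_a=self.h_over_a,
            temperature_K=self.temperature_K,
        )

    def with_(self, **kwargs) -> "GeneratorSpec":
        return replace(self, **kwargs)


def _langevin(alpha: np.ndarray) -> np.ndarray:
    out = np.empty_like(alpha)
    small = np.abs(alpha) < 1e-4
    a = alpha[~small]
    out[~small] = 1.0 / np.tanh(a) - 1.0 / a
    out[small] = alpha[small] / 3.0 - alpha[small] ** 3 / 45.0
    return out


def invert_langevin(target: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Tilt parameters alpha with ``L(alpha) = target``, elementwise.

    Bracketed root finding per unique tolerance-grid node, then strictly
    monotone interpolation; |target| must be < 1.
    """
    t = np.asarray(target, dtype=float)
    if np.any(np.abs(t) >= 1.0):
        raise ValidationError("Langevin inversion requires |target| < 1")
    tmax = float(np.max(np.abs(t)))
    if tmax == 0.0:
        return np.zeros_like(t)
    grid = np.linspace(0.0, tmax, 256)
    alphas = np.zeros_like(grid)
    for i, g in enumerate(grid[1:], start=1):
        hi = 3.0 * g / (1.0 - g) + 1.0
        alphas[i] = brentq(lambda x: (1.0 / math.tanh(x) - 1.0 / x) - g,
                           1e-12, hi, xtol=tol)
    interp = PchipInterpolator(grid, alphas)
    return np.sign(t) * interp(np.abs(t))


def _sample_tilted_uz(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-transform samples of p(u) ~ exp(alpha*u) on [-1, 1]."""
    u01 = rng.random(alpha.size)
    out = 2.0 * u01 - 1.0
    big = np.abs(alpha) > 1e-8
    a = alpha[big]
    w = u01[big]
    # u = 1 + log(w (1 - e^{-2a}) + e^{-2a}) / a, stable for either sign of a
    e = np.exp(-2.0 * a)
    out[big] = 1.0 + np.log(w * (1.0 - e) + e) / a
    return np.clip(out, -1.0, 1.0)


def generate_ordered_slab(
    spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> MolecularConfiguration:
    """Water slab whose mean dipolar density follows the sinh target.

    Oxygens are placed with a flat interior number density that decays
    smoothly (cosine ramp of width ``taper``) to zero at the walls
    ``z = +-d/2``, emulating the soft water/surface interface of the
    molecular systems; a hard density edge would defeat the multipole
    expansion at the boundary.  The dipole axis of each rigid water is
    tilted so that the mean orientation follows the antisymmetric
    Landau-Ginzburg profile built from ``(lam, h_over_a)`` at separation
    ``d`` — the dipolar density is then the sinh profile modulated by
    the density taper, and purely sinh-shaped in the interior.  Azimuth
    and spin about the dipole axis are uniform.  Raises if the requested
    ordering would require |<u_z>| >= 1 anywhere.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    tpl = spec.water_geometry
    area = spec.resolved_area
    lx = math.sqrt(area)
    lz = spec.d + 2.0 * spec.margin
    box = np.array([lx, lx, lz])
    n = spec.n_water
    w = min(spec.taper, 0.45 * spec.d)

    # rejection-sample z against the tapered density shape s(z)
    z1 = spec.d / 2.0 - w
    def shape(zz: np.ndarray) -> np.ndarray:
        s = np.ones_like(zz)
        ramp = np.abs(zz) > z1
        s[ramp] = 0.5 * (1.0 + np.cos(math.pi * (np.abs(zz[ramp]) - z1) / w))
        return s

    z = np.empty(0)
    while z.size < n:
        cand = (rng.random(2 * n) - 0.5) * spec.d
        cand = cand[rng.random(cand.size) < shape(cand)]
        z = np.concatenate([z, cand])
    z = z[:n]
    pos_o = np.column_stack([rng.random(n) * lx, rng.random(n) * lx, z + lz / 2.0])

    params = spec.lg_params
    m_s = surface_value(spec.d, params)
    target_m = m_s * np.sinh(z / spec.lam) / math.sinh(0.5 * spec.d / spec.lam)
    rho_plateau = n / (area * (spec.d - w))  # int s(z) dz = d - taper
    target_uz = target_m / (rho_plateau * tpl.dipole_moment)
    bad = np.abs(target_uz) >= 1.0
    if np.any(bad):
        worst = z[np.argmax(np.abs(target_uz))]
        raise ValidationError(
            f"target orientation unattainable (|<u_z>| >= 1) near z = {worst:+.3f} nm; "
            "reduce |h_over_a| or increase the density"
        )

    alpha = invert_langevin(target_uz)
    uz = _sample_tilted_uz(alpha, rng)
    phi = rng.random(n) * 2.0 * math.pi
    psi = rng.random(n) * 2.0 * math.pi

    st = np.sqrt(1.0 - uz**2)
    axis = np.column_stack([st * np.cos(phi), st * np.sin(phi), uz])
    # orthonormal frame about the dipole axis
    e1 = np.column_stack([uz * np.cos(phi), uz * np.sin(phi), -st])
    e2 = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros(n)])

    half = math.radians(tpl.hoh_angle_deg / 2.0)
    c = tpl.oh_bond * math.cos(half)
    s = tpl.oh_bond * math.sin(half)
    perp = (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2) * s
    h1 = pos_o + c * axis + perp
    h2 = pos_o + c * axis - perp

    sites = np.stack([pos_o, h1, h2], axis=1)  # (n, 3, 3)
    return MolecularConfiguration.from_site_array(
        box=box,
        site_positions=sites,
        site_charges=tpl.charges,
        reference_index=0,
        resname="SOL",
        atom_names=("OW", "HW1", "HW2"),
    )


def generate_pressure_curves(
    spec: GeneratorSpec, d_grid, rng: np.random.Generator | None = None
) -> tuple[PressureDistanceCurve, PressureDistanceCurve, PressureDistanceCurve]:
    """(total, direct, indirect) pressure curves on the given separations.

    The indirect part is the closed-form Landau-Ginzburg pressure of the
    spec's parameters; the direct part is the attractive exponential
    ``-A_dir exp(-d/lam_dir)``; the total is their sum.  Multiplicative
    Gaussian noise of relative size ``noise_level`` is applied to the
    direct and indirect parts independently (the total stays their exact
    sum, mirroring how a decomposition is measured).
    """
    d = np.asarray(d_grid, dtype=float)
    if d.ndim != 1 or d.size == 0 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ValidationError("d_grid must be positive and strictly increasing")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    params = spec.lg_params
    ind = np.array([indirect_pressure(x, params) for x in d])
    lam_dir = spec.direct_decay if spec.direct_decay is not None else spec.lam
    dire = -spec.direct_amplitude * np.exp(-d / lam_dir)
    if spec.noise_level > 0:
        ind = ind * (1.0 + spec.noise_level * rng.standard_normal(d.size))
        dire = dire * (1.0 + spec.noise_level * rng.standard_normal(d.size))
    tot = ind + dire
    mk = lambda p, tag: PressureDistanceCurve(d=d, pressure=p, contribution=tag)
    return mk(tot, "total"), mk(dire, "direct"), mk(ind, "indirect")


def _total_pressure(spec: GeneratorSpec, d: float) -> float:
    lam_dir = spec.direct_decay if spec.direct_decay is not None else spec.lam
    return indirect_pressure(d, spec.lg_params) - spec.direct_amplitude * math.exp(
        -d / lam_dir
    )


def generate_mu_curve(
    spec: GeneratorSpec, n_grid, mu_bulk: float = MU_BULK_KT
) -> ChemicalPotentialCurve:
    """Chemical-potential curve mu(N_w) at fixed volume.

    Emulates the constant-volume protocol: the water number maps to a
    separation ``d = N_w v_w / A``, the noiseless total pressure of the
    spec's parameters gives ``Pi(N_w)``, and the linear Gibbs-Duhem
    relation is inverted for ``mu(N_w) = mu_bulk + v_w (Pi - Pi_osm)``.
    The curve is smooth, strictly monotone (decreasing toward bulk for a
    net-repulsive system) and crosses ``mu_bulk`` exactly where
    ``Pi = Pi_osm``; the paired pressures and, when bracketed, the
    planted crossing ``n_star`` are stored in the metadata.
    """
    n = np.asarray(n_grid, dtype=float)
    if n.ndim != 1 or n.size < 3 or np.any(np.diff(n) <= 0):
        raise ValidationError("n_grid must be increasing with >= 3 entries")
    area = spec.resolved_area
    d = n * spec.v_w / area
    pressures = np.array([_total_pressure(spec, x) for x in d])
    pi_osm = 1.0 / kT_per_nm3_to_bar(spec.temperature_K)  # 1 bar in kT/nm^3
    mu = mu_bulk + spec.v_w * (pressures - pi_osm)
    meta = {
        "mu_bulk": mu_bulk,
        "pi_osm": pi_osm,
        "v_w": spec.v_w,
        "area": area,
        "pressures": pressures,
    }
    lo, hi = float(d[0]), float(d[-1])
    f = lambda x: _total_pressure(spec, x) - pi_osm
    if f(lo) * f(hi) < 0:
        d_star = brentq(f, lo, hi, xtol=1e-12)
        meta["n_star"] = d_star * area / spec.v_w
        meta["pressure_at_n_star"] = pi_osm
    curve = ChemicalPotentialCurve(n_water=n, mu=mu, fixed="volume", metadata=meta)
    # consistency by construction with the Gibbs-Duhem conversion
    assert np.allclose(
        equivalent_pressure(mu, mu_bulk, pi_osm, spec.v_w), pressures
    )
    return curve
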