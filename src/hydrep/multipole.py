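"""Multipole decomposition of molecular charge distributions into the
laterally averaged normal polarization.

Expanding the partial-charge distribution of each (neutral) molecule
about a reference site up to the third moment gives per-molecule
z-moments

    p_z = sum_j q_j dz_j        (dipole, e*nm)
    q_zz = sum_j q_j dz_j^2     (quadrupole, e*nm^2)
    o_zzz = sum_j q_j dz_j^3    (octupole, e*nm^3)

with ``dz_j`` the site offset from the reference along the surface
normal.  Binning these moments at the reference-site position and
dividing by the bin volume yields the laterally averaged densities
``p_bar(z)``, ``q_bar(z)``, ``o_bar(z)``; the polarization then
decomposes as

    m(z) = p_bar(z) - (1/2) d/dz q_bar(z) + (1/6) d^2/dz^2 o_bar(z) + ...

The prefactors and signs follow from the exact bound-charge identity
``m(z) = -integral of the laterally averaged charge density up to z``,
which :func:`bound_charge_polarization` computes directly from all
partial charges and which serves as the truncation-free oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import ValidationError

NEUTRALITY_TOL = 1e-12  # e, per molecule


@dataclass(frozen=True)
class Molecule:
    """Sites of one molecule: positions (nm), partial charges (e)."""

    positions: np.ndarray  # (n_sites, 3)
    charges: np.ndarray  # (n_sites,)
    reference_index: int = 0
    resname: str = "SOL"
    atom_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        q = np.atleast_1d(np.asarray(self.charges, dtype=float))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", q)
        if pos.shape != (q.size, 3):
            raise ValidationError("positions must be (n_sites, 3) matching charges")
        if not 0 <= self.reference_index < q.size:
            raise ValidationError(f"reference_index {self.reference_index} out of range")


@dataclass(frozen=True)
class MultipoleMoments:
    """z-moments of one molecule about its reference site."""

    p_z: float  # e*nm
    q_zz: float  # e*nm^2
    o_zzz: float  # e*nm^3


@dataclass
class MolecularConfiguration:
    """Box plus molecules, stored as flat site arrays for vector math.

    ``positions`` are wrapped into the box on demand; every molecule
    must be net-neutral.  ``mol_id`` maps each site to its molecule and
    ``ref_sites`` holds the flat index of each molecule's reference
    site (the water oxygen for SPC/E-like waters).
    """

    box: np.ndarray  # (Lx, Ly, Lz), nm
    positions: np.ndarray  # (n_total_sites, 3), nm
    charges: np.ndarray  # (n_total_sites,), e
    mol_id: np.ndarray  # (n_total_sites,), int
    ref_sites: np.ndarray  # (n_molecules,), int
    resnames: list[str] = field(default_factory=list)  # per molecule
    atom_names: list[str] = field(default_factory=list)  # per site

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.mol_id = np.asarray(self.mol_id, dtype=np.intp)
        self.ref_sites = np.asarray(self.ref_sites, dtype=np.intp)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValidationError("box must be three positive lengths (nm)")
        net = np.abs(np.bincount(self.mol_id, weights=self.charges,
                                 minlength=self.n_molecules))
        bad = np.nonzero(net > NEUTRALITY_TOL)[0]
        if bad.size:
            raise ValidationError(
                f"molecule {bad[0]} carries net charge {net[bad[0]]:+.3e} e "
                f"({bad.size} non-neutral molecules in total)"
            )

    # -- construction -------------------------------------------------------
    @classmethod
    def from_molecules(cls, box, molecules: list[Molecule]) -> "MolecularConfiguration":
        if not molecules:
            raise ValidationError("configuration must contain at least one molecule")
        pos, q, mid, refs, resnames, at_names = [], [], [], [], [], []
        offset = 0
        for i, mol in enumerate(molecules):
            n = mol.charges.size
            pos.append(mol.positions)
            q.append(mol.charges)
            mid.append(np.full(n, i))
            refs.append(offset + mol.reference_index)
            resnames.append(mol.resname)
            at_names.extend(
                mol.atom_names
                if mol.atom_names is not None
                else [f"X{j+1}" for j in range(n)]
            )
            offset += n
        return cls(
            box=np.asarray(box, dtype=float),
            positions=np.concatenate(pos),
            charges=np.concatenate(q),
            mol_id=np.concatenate(mid),
            ref_sites=np.asarray(refs),
            resnames=resnames,
            atom_names=at_names,
        )

    @classmethod
    def from_site_array(
        cls, box, site_positions: np.ndarray, site_charges: np.ndarray,
        reference_index: int = 0, resname: str = "SOL",
        atom_names: tuple[str, ...] | None = None,
    ) -> "MolecularConfiguration":
        """Homogeneous configuration from an (n_mol, n_sites, 3) array."""
        site_positions = np.asarray(site_positions, dtype=float)
        n_mol, n_sites, _ = site_positions.shape
        charges = np.tile(np.asarray(site_charges, dtype=float), n_mol)
        mol_id = np.repeat(np.arange(n_mol), n_sites)
        refs = np.arange(n_mol) * n_sites + reference_index
        names = list(atom_names) * n_mol if atom_names else \
            [f"X{j+1}" for _ in range(n_mol) for j in range(n_sites)]
        return cls(
            box=np.asarray(box, dtype=float),
            positions=site_positions.reshape(-1, 3),
            charges=charges,
            mol_id=mol_id,
            ref_sites=refs,
            resnames=[resname] * n_mol,
            atom_names=names,
        )

    # -- views --------------------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return self.ref_sites.size

    @property
    def n_sites(self) -> int:
        return self.charges.size

    @property
    def area(self) -> float:
        return float(self.box[0] * self.box[1])

    def molecules(self) -> list[Molecule]:
        out = []
        bounds = np.searchsorted(self.mol_id, np.arange(self.n_molecules + 1))
        for i in range(self.n_molecules):
            lo, hi = bounds[i], bounds[i + 1]
            out.append(
                Molecule(
                    positions=self.positions[lo:hi],
                    charges=self.charges[lo:hi],
                    reference_index=int(self.ref_sites[i] - lo),
                    resname=self.resnames[i] if self.resnames else "SOL",
                    atom_names=tuple(self.atom_names[lo:hi]) if self.atom_names else None,
                )
            )
        return out


@dataclass(frozen=True)
class ProfileSet:
    """Binned multipole-density profiles on one common z grid.

    z is measured from the slab midplane; bins are half-open
    ``[z, z + dz)``.  ``m_sum`` is the truncated multipole composition,
    ``m_bound`` the exact bound-charge polarization on the same grid.
    """

    z: np.ndarray  # bin centers, nm (midplane origin)
    p_bar: np.ndarray  # e/nm^2
    dq_bar: np.ndarray  # d/dz of quadrupole density, e/nm^2
    d2o_bar: np.ndarray  # d^2/dz^2 of octupole density, e/nm^2
    m_sum: np.ndarray  # e/nm^2
    m_bound: np.ndarray  # e/nm^2
    q_bar: np.ndarray  # e/nm (raw quadrupole density)
    o_bar: np.ndarray  # e (raw octupole density)
    bin_width: float

    def composition(self, order: int = 3) -> np.ndarray:
        """Multipole sum truncated at dipole (1), +quadrupole (2), +octupole (3)."""
        m = self.p_bar.copy()
        if order >= 2:
            m -= 0.5 * self.dq_bar
        if order >= 3:
            m += self.d2o_bar / 6.0
        return m

    def order_parameter(
        self, kind: str, d: float | None = None, edge_exclusion: float = 0.0
    ):
        """One order-parameter profile, optionally cropped to the slab.

        ``polarization`` is the full multipole sum, ``dipolar`` the
        dipole-density contribution, ``quadrupolar_gradient`` the
        ``-1/2 d/dz q_bar`` contribution and ``octupolar_curvature`` the
        ``+1/6 d^2/dz^2 o_bar`` contribution.  With ``d`` given, bins
        outside ``[-d/2, d/2]`` (vacuum margins) are dropped;
        ``edge_exclusion`` additionally drops the interfacial band where
        the density decays and the bulk profile shapes do not apply.
        """
        from .lg_model import OrderParameterProfile

        fields = {
            "polarization": self.m_sum,
            "dipolar": self.p_bar,
            "quadrupolar_gradient": -0.5 * self.dq_bar,
            "octupolar_curvature": self.d2o_bar / 6.0,
        }
        if kind not in fields:
            raise ValidationError(f"unknown order-parameter kind {kind!r}")
        values = fields[kind]
        z = self.z
        if d is not None:
            sel = np.abs(z) <= d / 2.0 - edge_exclusion
            z, values = z[sel], values[sel]
        return OrderParameterProfile(
            z=z, values=values, d=float(d if d is not None else z[-1] - z[0]),
            kind=kind,
        )

    def oracle_residual(self) -> float:
        """RMS deviation of the multipole sum from the bound-charge
        oracle, relative to the oracle's maximum magnitude."""
        return float(
            np.sqrt(np.mean((self.m_sum - self.m_bound) ** 2))
            / np.max(np.abs(self.m_bound))
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_nm": self.z,
                "p_bar_e_nm2": self.p_bar,
                "dq_bar_e_nm2": self.dq_bar,
                "d2o_bar_e_nm2": self.d2o_bar,
                "m_sum_e_nm2": self.m_sum,
                "m_bound_e_nm2": self.m_bound,
            }
        )


def molecular_moments(molecule: Molecule) -> MultipoleMoments:
    """z-multipole moments of one neutral molecule about its reference site.

    The dipole ``p_z`` is reference-independent for neutral molecules;
    ``q_zz`` and ``o_zzz`` depend on the reference choice (documented
    package convention: raw, non-traceless moments about the reference).
    """
    if abs(float(np.sum(molecule.charges))) > NEUTRALITY_TOL:
        raise ValidationError(
            f"molecule carries net charge {np.sum(molecule.charges):+.3e} e"
        )
    dz = molecule.positions[:, 2] - molecule.positions[molecule.reference_index, 2]
    q = molecule.charges
    return MultipoleMoments(
        p_z=float(np.sum(q * dz)),
        q_zz=float(np.sum(q * dz * dz)),
        o_zzz=float(np.sum(q * dz**3)),
    )


def _bin_grid(config: MolecularConfiguration, bin_width: float) -> tuple[int, float]:
    lz = float(config.box[2])
    if not bin_width > 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    if bin_width > lz / 10.0:
        raise ValidationError(
            f"bin_width {bin_width} exceeds Lz/10 = {lz / 10.0:.4g} nm"
        )
    n_bins = int(round(lz / bin_width))
    return n_bins, lz / n_bins


def bin_profiles(
    config: MolecularConfiguration,
    bin_width: float,
    smoothing_sigma_bins: float = 0.0,
) -> ProfileSet:
    """Laterally averaged multipole-density profiles of a configuration.

    Each molecule's moments are deposited in the bin of its (wrapped)
    reference site and divided by the bin volume ``A * dz``.  Central
    differences give the gradient of the quadrupole density and the
    curvature of the octupole density; an optional Gaussian smoothing
    (sigma in bins) may be applied to the binned densities before
    differentiating, and is off by default so that comparisons against
    the bound-charge oracle are unbiased.
    """
    if config.n_molecules == 0:
        raise ValidationError("empty configuration")
    n_bins, dz = _bin_grid(config, bin_width)
    lz = float(config.box[2])
    area = config.area

    zref = np.mod(config.positions[config.ref_sites, 2], lz)
    # per-molecule moments, vectorized over the flat site arrays
    dzs = config.positions[:, 2] - config.positions[config.ref_sites, 2][config.mol_id]
    dzs -= lz * np.round(dzs / lz)  # re-join molecules split by wrapping
    q = config.charges
    n_mol = config.n_molecules
    p = np.bincount(config.mol_id, weights=q * dzs, minlength=n_mol)
    qq = np.bincount(config.mol_id, weights=q * dzs * dzs, minlength=n_mol)
    oo = np.bincount(config.mol_id, weights=q * dzs**3, minlength=n_mol)

    idx = np.minimum((zref / dz).astype(np.intp), n_bins - 1)
    vol = area * dz
    p_bar = np.bincount(idx, weights=p, minlength=n_bins) / vol
    q_bar = np.bincount(idx, weights=qq, minlength=n_bins) / vol
    o_bar = np.bincount(idx, weights=oo, minlength=n_bins) / vol

    if smoothing_sigma_bins > 0:
        p_bar = gaussian_filter1d(p_bar, smoothing_sigma_bins, mode="nearest")
        q_bar = gaussian_filter1d(q_bar, smoothing_sigma_bins, mode="nearest")
        o_bar = gaussian_filter1d(o_bar, smoothing_sigma_bins, mode="nearest")

    dq_bar = np.gradient(q_bar, dz)
    d2o_bar = np.gradient(np.gradient(o_bar, dz), dz)
    m_sum = p_bar - 0.5 * dq_bar + d2o_bar / 6.0
    m_bound = bound_charge_polarization(config, bin_width)

    z_centers = (np.arange(n_bins) + 0.5) * dz - lz / 2.0
    return ProfileSet(
        z=z_centers, p_bar=p_bar, dq_bar=dq_bar, d2o_bar=d2o_bar,
        m_sum=m_sum, m_bound=m_bound, q_bar=q_bar, o_bar=o_bar, bin_width=dz,
    )


def bound_charge_polarization(
    config: MolecularConfiguration, bin_width: float
) -> np.ndarray:
    """Exact normal polarization from the cumulative bound-charge density.

    Bins every partial charge into the laterally averaged charge density
    ``rho_bar(z)`` and returns ``m(z) = -int_0^z rho_bar dz'`` evaluated
    at bin centers.  For a net-neutral box the profile returns to zero
    on both sides of the slab; this is the quantity the multipole
    expansion approximates.
    """
    if config.n_molecules == 0:
        raise ValidationError("empty configuration")
    total = float(np.sum(config.charges))
    if abs(total) > 1e-9:
        raise ValidationError(f"box carries net charge {total:+.3e} e")
    n_bins, dz = _bin_grid(config, bin_width)
    lz = float(config.box[2])
    zs = np.mod(config.positions[:, 2], lz)
    idx = np.minimum((zs / dz).astype(np.intp), n_bins - 1)
    rho = np.bincount(idx, weights=config.charges, minlength=n_bins) / (config.area * dz)
    # -cumulative integral, evaluated mid-bin (exact for binned step density)
    cum = np.cumsum(rho) * dz
    return -(cum - 0.5 * rho * dz)
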