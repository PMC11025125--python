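"""Readers and writers: GRO coordinates + charge maps, profile and
curve tables, parameter configs.

Coordinates travel as GROMACS ``.gro`` files (fixed-column text, nm)
read and written through MDAnalysis; partial charges are attached from
a YAML charge map of the form::

    SOL:
      reference: OW
      charges: {OW: -0.8476, HW1: 0.4238, HW2: 0.4238}

All tables are tab-separated with ``#`` metadata lines carrying units,
bin conventions (half-open, z origin at the slab midplane) and
contribution tags, so every writer round-trips through its reader.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .lg_model import LGParameters, OrderParameterProfile
from .multipole import MolecularConfiguration, ProfileSet
from .thermo import PressureDistanceCurve


# ---------------------------------------------------------------------------
# charge maps and coordinates
# ---------------------------------------------------------------------------

def read_charge_map(path) -> dict:
    with open(path) as fh:
        cmap = yaml.safe_load(fh)
    if not isinstance(cmap, dict):
        raise ValidationError(f"charge map {path} must be a mapping")
    for res, entry in cmap.items():
        if "charges" not in entry:
            raise ValidationError(f"charge map entry {res!r} lacks 'charges'")
    return cmap


def write_charge_map(cmap: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cmap, fh, sort_keys=False)


SPCE_CHARGE_MAP = {
    "SOL": {
        "reference": "OW",
        "charges": {"OW": -0.8476, "HW1": 0.4238, "HW2": 0.4238},
    }
}


def write_configuration(config: MolecularConfiguration, path) -> None:
    """Write a configuration as a single-frame GRO file (nm)."""
    import MDAnalysis as mda

    n_mol = config.n_molecules
    u = mda.Universe.empty(
        n_atoms=config.n_sites,
        n_residues=n_mol,
        atom_resindex=config.mol_id,
        residue_segindex=np.zeros(n_mol, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", config.atom_names)
    u.add_TopologyAttr("resnames", config.resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_mol + 1))
    u.atoms.positions = config.positions * 10.0  # nm -> Angstrom
    u.dimensions = [*(config.box * 10.0), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_configuration_file(path, charge_map: dict | str) -> MolecularConfiguration:
    """Read a GRO file and attach charges from the charge map.

    Molecules are grouped by residue; each residue's type must appear
    in the charge map, each atom must have a charge entry, and every
    molecule must come out net-neutral.
    """
    import MDAnalysis as mda

    if not isinstance(charge_map, dict):
        charge_map = read_charge_map(charge_map)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except (ValueError, OSError, EOFError) as exc:
        raise ValidationError(f"{path}: malformed coordinate file: {exc}") from exc
    if u.dimensions is None:
        raise ValidationError(f"{path}: missing box dimensions")
    box = np.asarray(u.dimensions[:3], dtype=float) / 10.0
    positions = u.atoms.positions / 10.0
    charges = np.empty(len(u.atoms))
    mol_id = np.asarray(u.atoms.resindices, dtype=np.intp)
    ref_sites = np.full(len(u.residues), -1, dtype=np.intp)
    resnames, atom_names = [], []
    for res in u.residues:
        entry = charge_map.get(res.resname)
        if entry is None:
            raise ValidationError(
                f"{path}: no charge-map entry for molecule type {res.resname!r} "
                f"(residue index {res.resindex})"
            )
        qmap = entry["charges"]
        ref_name = entry.get("reference")
        resnames.append(res.resname)
        for atom in res.atoms:
            if atom.name not in qmap:
                raise ValidationError(
                    f"{path}: no charge for atom {atom.name!r} in molecule type "
                    f"{res.resname!r}"
                )
            charges[atom.ix] = qmap[atom.name]
            atom_names.append(atom.name)
            if ref_name is None or atom.name == ref_name:
                if ref_sites[res.resindex] < 0:
                    ref_sites[res.resindex] = atom.ix
        if ref_sites[res.resindex] < 0:
            raise ValidationError(
                f"{path}: reference atom {ref_name!r} absent from molecule type "
                f"{res.resname!r}"
            )
    return MolecularConfiguration(
        box=box,
        positions=positions,
        charges=charges,
        mol_id=mol_id,
        ref_sites=ref_sites,
        resnames=resnames,
        atom_names=atom_names,
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_table(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def write_profile(profile: OrderParameterProfile, path) -> None:
    """3-column table (z_nm, value, kind); z origin at the slab midplane."""
    df = pd.DataFrame(
        {"z_nm": profile.z, "value_e_nm2": profile.values,
         "kind": [profile.kind] * profile.z.size}
    )
    _write_table(df, path, {
        "separation_d_nm": profile.d,
        "convention": "z origin at slab midplane",
    })


def read_profile(path) -> OrderParameterProfile:
    df, meta = _read_table(path)
    return OrderParameterProfile(
        z=df["z_nm"].to_numpy(),
        values=df["value_e_nm2"].to_numpy(),
        d=float(meta["separation_d_nm"]),
        kind=str(df["kind"].iloc[0]),
    )


def write_profile_set(profiles: ProfileSet, path) -> None:
    _write_table(profiles.to_dataframe(), path, {
        "bin_width_nm": profiles.bin_width,
        "convention": "half-open bins [z, z+dz), z origin at slab midplane",
        "units": "densities e/nm^2",
    })


def write_pressure_curve(curve: PressureDistanceCurve, path) -> None:
    df = pd.DataFrame({"d_nm": curve.d, "pressure": curve.pressure})
    _write_table(df, path, {
        "contribution": curve.contribution,
        "ensemble": curve.ensemble,
        "units": curve.units,
    })


def read_pressure_curve(path) -> PressureDistanceCurve:
    df, meta = _read_table(path)
    return PressureDistanceCurve(
        d=df["d_nm"].to_numpy(),
        pressure=df["pressure"].to_numpy(),
        contribution=meta.get("contribution", "total"),
        ensemble=meta.get("ensemble", "osmotic"),
        units=meta.get("units", "kT/nm^3"),
    )


# ---------------------------------------------------------------------------
# model parameter configs
# ---------------------------------------------------------------------------

def write_lg_parameters(params: LGParameters, path) -> None:
    data = {
        "a": params.a,
        "lam": params.lam,
        "h_over_a": params.h_over_a,
        "bc_kind": params.bc_kind,
        "symmetry": params.symmetry,
        "temperature_K": params.temperature_K,
    }
    if params.m_surface is not None:
        data["m_surface"] = params.m_surface
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_lg_parameters(path) -> LGParameters:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return LGParameters.from_correlation_length(
            a=float(data["a"]),
            lam=float(data["lam"]),
            h_over_a=float(data.get("h_over_a", 0.0)),
            bc_kind=data.get("bc_kind", "fixed_field"),
            symmetry=data.get("symmetry", "antisymmetric"),
            m_surface=data.get("m_surface"),
            temperature_K=float(data.get("temperature_K", 300.0)),
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: missing parameter key {exc}") from exc


def write_parameter_table(df: pd.DataFrame, path) -> None:
    """Tab-separated Table-1-style summary (rows = parameters)."""
    with open(path, "w") as fh:
        for msg in df.attrs.get("messages", []):
            fh.write(f"# note: {msg}\n")
        df.to_csv(fh, sep="\t", index_label="parameter")
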