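"""End-to-end analysis pipeline: generate (or load) slabs, bin
profiles, run the fitting chain and assemble a parameter summary."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .errors import ValidationError
from .fitting import SystemDataset, extract_parameter_table
from .multipole import bin_profiles
from .synthetic import GeneratorSpec, generate_ordered_slab, generate_pressure_curves
from .thermo import decompose_pressure
from .units import WATER_MOLECULAR_VOLUME

logger = logging.getLogger("hydrep")


class PipelineStageError(RuntimeError):
    """Failure of a named pipeline stage; earlier outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    ``separations`` lists the slab separations (nm) at which ordered
    slabs are generated and profiled; the pressure analysis runs on
    ``pressure_d_grid``.
    """

    label: str = "dppc_liquid_like"
    temperature_K: float = 300.0
    d_s0: float = 0.46  # nm, zero-hydration offset (DPPC-like)
    v_w: float = WATER_MOLECULAR_VOLUME
    bin_width: float = 0.05  # nm
    headgroup_pattern: str = "P*"
    separations: tuple[float, ...] = (1.2, 1.6, 2.0, 2.4)
    pressure_d_grid: tuple[float, ...] = tuple(
        float(x) for x in np.round(np.arange(0.6, 2.41, 0.1), 3)
    )
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    profile_kinds: tuple[str, ...] = ("polarization", "dipolar")
    output_dir: str = "hydrep_out"

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("label must be nonempty")
        for name in ("temperature_K", "d_s0", "v_w", "bin_width"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")

    # -- (de)serialization --------------------------------------------------
    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        data = plain(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        required = {"label", "d_s0"}
        missing = required - data.keys()
        if missing:
            raise ValidationError(f"{path}: missing config keys {sorted(missing)}")
        gen = data.pop("generator", {})
        wg = gen.pop("water_geometry", None)
        from .synthetic import WaterTemplate

        spec = GeneratorSpec(
            **gen, **({"water_geometry": WaterTemplate(**wg)} if wg else {})
        )
        for key in ("separations", "pressure_d_grid", "profile_kinds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(generator=spec, **data)


def run_pipeline(config: PipelineConfig, seed: int | None = None) -> dict:
    """Run generate -> profiles -> fits -> parameter table -> report.

    Returns a report dict (also written to the output directory along
    with every intermediate table).  Any stage failure raises
    :class:`PipelineStageError` naming the stage; outputs of completed
    stages remain on disk.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.generator
    if seed is not None:
        spec = spec.with_(seed=seed)
    report: dict = {
        "label": config.label,
        "seed": spec.seed,
        "separations": list(config.separations),
        "stages": [],
    }

    dataset = SystemDataset(label=config.label)
    try:
        for d in config.separations:
            sp = spec.with_(d=d, n_water=max(
                int(round(spec.n_water * d / spec.d)), 1000))
            cfg = generate_ordered_slab(sp)
            profs = bin_profiles(cfg, config.bin_width)
            hio.write_profile_set(profs, outdir / f"profiles_d{d:.2f}.tsv")
            for kind in config.profile_kinds:
                prof = profs.order_parameter(kind, d=d, edge_exclusion=sp.taper)
                dataset.profiles.setdefault(kind, []).append(prof)
        report["stages"].append("profiles")
        logger.info("profiled %d separations", len(config.separations))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError("profiles", exc) from exc

    try:
        total, direct, indirect = generate_pressure_curves(
            spec, np.asarray(config.pressure_d_grid)
        )
        for name, curve in (("total", total), ("direct", direct),
                            ("indirect", indirect)):
            hio.write_pressure_curve(curve, outdir / f"pressure_{name}.tsv")
        recovered = decompose_pressure(total, direct)
        dataset.indirect_pressure = recovered
        report["stages"].append("pressures")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("pressures", exc) from exc

    try:
        table = extract_parameter_table([dataset])
        hio.write_parameter_table(table, outdir / "parameter_table.tsv")
        report["stages"].append("fits")
        report["parameter_table"] = {
            row: (None if np.isnan(val) else float(val))
            for row, val in table[config.label].items()
        }
        report["fit_messages"] = table.attrs.get("messages", [])
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("fits", exc) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("pipeline complete: %s", outdir / "report.json")
    return report
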