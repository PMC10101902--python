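"""File I/O and pipeline configuration.

One CSV dialect is used for every voltammogram: optional ``# key: value``
comment lines, then a header naming the two columns with their units
(``potential_mV,current_uA`` or ``potential_mV,current_nA``), then numeric
rows.  Potentials are stored in mV and currents in uA (macro cells) or nA
(micro cells) at the file boundary; in memory everything is volts/amperes.

Analysis configurations are YAML mappings validated into
:class:`AnalysisConfig`; :func:`run_pipeline` chains the library stages and
stamps every output with provenance (package version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _version
from .conditions import Conditions
from .electroanalysis import fit_calibration, standard_addition
from .errors import ConfigError, FormatError, InvalidInputError
from .partition import fit_partition_model, logp_from_potential
from .speciation import ProtolyticSystem, dominance_ranges, species_fractions
from .transport import CellGeometry, diffusion_from_scan_rate_series, saito_radius
from .units import (
    A_TO_NA,
    A_TO_UA,
    MV_TO_V,
    NA_TO_A,
    UA_TO_A,
    UM_TO_M,
    V_TO_MV,
)
from .voltprocess import Voltammogram, detect_analyte, extract_peaks
from .voltsim import SimConfig, TransferSpecies, simulate_macro_itv, simulate_micro_itv

logger = logging.getLogger("itieskit")

_CURRENT_UNITS = {"current_uA": UA_TO_A, "current_nA": NA_TO_A, "current_A": 1.0}
_POTENTIAL_UNITS = {"potential_mV": MV_TO_V, "potential_V": 1.0}

__all__ = [
    "read_voltammogram",
    "write_voltammogram",
    "AnalysisConfig",
    "load_config",
    "load_protolytic_system",
    "run_pipeline",
]


def write_voltammogram(v: Voltammogram, path, current_unit: str = "uA") -> None:
    """Write a voltammogram in the package CSV dialect.

    ``current_unit`` is ``"uA"`` or ``"nA"``; all metadata keys become
    ``# key: value`` comment lines so a trace is self-describing.
    """
    scale = {"uA": A_TO_UA, "nA": A_TO_NA, "A": 1.0}.get(current_unit)
    if scale is None:
        raise InvalidInputError(f"unsupported current unit {current_unit!r}")
    path = Path(path)
    lines = [f"# scan_rate_V_s: {v.scan_rate!r}"]
    for key, val in v.metadata.items():
        lines.append(f"# {key}: {json.dumps(val) if isinstance(val, (list, dict)) else val}")
    lines.append(f"potential_mV,current_{current_unit}")
    for p, c in zip(v.potential, v.current):
        lines.append(f"{p * V_TO_MV:.6f},{c * scale:.9g}")
    path.write_text("\n".join(lines) + "\n")


def read_voltammogram(path, scan_rate: float | None = None) -> Voltammogram:
    """Read a voltammogram CSV, validating units and every row.

    Units are declared by the header column names; malformed rows raise
    :class:`~itieskit.errors.FormatError` naming the offending line.  The
    scan rate comes from a ``# scan_rate_V_s:`` comment or the argument.
    """
    path = Path(path)
    metadata: dict = {}
    header = None
    potentials: list[float] = []
    currents: list[float] = []
    pot_scale = cur_scale = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    metadata[key.strip()] = val.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if len(header) != 2:
                    raise FormatError(
                        f"{path.name}:{lineno}: expected two columns, got {header}"
                    )
                pot_scale = _POTENTIAL_UNITS.get(header[0])
                cur_scale = _CURRENT_UNITS.get(header[1])
                if pot_scale is None or cur_scale is None:
                    raise FormatError(
                        f"{path.name}:{lineno}: header must declare units, e.g. "
                        f"'potential_mV,current_uA'; got {line!r}"
                    )
                continue
            cells = line.split(",")
            if len(cells) != 2:
                raise FormatError(f"{path.name}:{lineno}: expected two values, got {line!r}")
            try:
                p, c = float(cells[0]), float(cells[1])
            except ValueError:
                raise FormatError(
                    f"{path.name}:{lineno}: non-numeric row {line!r}"
                ) from None
            if not (math.isfinite(p) and math.isfinite(c)):
                raise FormatError(f"{path.name}:{lineno}: non-finite row {line!r}")
            potentials.append(p * pot_scale)
            currents.append(c * cur_scale)
    if header is None:
        raise FormatError(f"{path.name}: no header line found")
    if scan_rate is None:
        raw_rate = metadata.get("scan_rate_V_s")
        if raw_rate is None:
            raise FormatError(
                f"{path.name}: scan rate missing (no '# scan_rate_V_s:' comment "
                "and no argument)"
            )
        scan_rate = float(raw_rate)
    return Voltammogram(
        potential=np.asarray(potentials),
        current=np.asarray(currents),
        scan_rate=float(scan_rate),
        metadata=metadata,
    )


def _read_table(path, expected_cols: int = 2) -> np.ndarray:
    """Small numeric CSV (with optional header/comments) as an array."""
    rows = []
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split(",")
            if len(cells) != expected_cols:
                raise FormatError(
                    f"{path.name}:{lineno}: expected {expected_cols} columns, got {line!r}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                if lineno == 1 or not rows:
                    continue  # header line
                raise FormatError(f"{path.name}:{lineno}: non-numeric row {line!r}") from None
    if not rows:
        raise FormatError(f"{path.name}: no numeric rows")
    return np.asarray(rows)


def load_protolytic_system(name: str, spec: dict) -> ProtolyticSystem:
    """Build a :class:`ProtolyticSystem` from a config mapping."""
    missing = [k for k in ("pka", "charges", "labels") if k not in spec]
    if missing:
        raise ConfigError(f"drug {name!r}: missing fields {missing}")
    return ProtolyticSystem(
        name=name,
        pka_values=spec["pka"],
        species_charges=spec["charges"],
        species_labels=spec["labels"],
        molar_mass=spec.get("molar_mass"),
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated pipeline configuration."""

    drugs: dict
    conditions: Conditions
    geometry: CellGeometry
    stages: dict
    output_dir: Path
    seed: int = 0
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> AnalysisConfig:
    """Load and validate a YAML analysis configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or not raw:
        raise ConfigError(f"{path.name}: empty or non-mapping configuration")
    missing = [k for k in ("drugs", "geometry", "output_dir") if k not in raw]
    if missing:
        raise ConfigError(f"{path.name}: missing required fields {missing}")
    drugs = {
        name: load_protolytic_system(name, spec)
        for name, spec in (raw.get("drugs") or {}).items()
    }
    cond = Conditions(temperature=float(raw.get("temperature_K", 293.15)))
    geo_raw = raw["geometry"]
    for key in ("kind", "radius_cm"):
        if key not in geo_raw:
            raise ConfigError(f"{path.name}: geometry missing {key!r}")
    geometry = CellGeometry(kind=geo_raw["kind"], radius=float(geo_raw["radius_cm"]))
    return AnalysisConfig(
        drugs=drugs,
        conditions=cond,
        geometry=geometry,
        stages=raw.get("stages", {}),
        output_dir=Path(raw["output_dir"]),
        seed=int(raw.get("seed", 0)),
        raw=raw,
    )


def _write_result(config: AnalysisConfig, name: str, payload: dict) -> Path:
    config.output_dir.mkdir(parents=True, exist_ok=True)
    out = config.output_dir / f"{name}.txt"
    lines = [
        f"# itieskit {_version}",
        f"# config_hash: {config.config_hash}",
        f"# seed: {config.seed}",
        f"# temperature_K: {config.conditions.temperature}",
    ]
    lines += [f"{k}: {v}" for k, v in payload.items()]
    out.write_text("\n".join(lines) + "\n")
    logger.info("stage %s -> %s", name, out)
    return out


PIPELINE_STAGES = (
    "speciation",
    "partition-fit",
    "calibrate",
    "standard-addition",
    "transport",
    "peaks",
    "detect",
    "simulate",
)


def run_pipeline(config: AnalysisConfig, subcommand: str) -> Path:
    """Run one named pipeline stage; returns the result file path.

    Stage parameters come from ``config.stages[subcommand]``; every output
    carries the package version, config hash and seed, so a run is fully
    reproducible from its result file.
    """
    if subcommand not in PIPELINE_STAGES:
        raise ConfigError(
            f"unknown subcommand {subcommand!r}; expected one of {PIPELINE_STAGES}"
        )
    params = config.stages.get(subcommand, {})

    if subcommand == "speciation":
        payload: dict = {}
        grid = np.arange(
            float(params.get("ph_min", 0.0)), float(params.get("ph_max", 14.0)) + 1e-9,
            float(params.get("ph_step", 0.5)),
        )
        for name, system in config.drugs.items():
            ranges = dominance_ranges(system)
            payload[f"{name}_dominance"] = "; ".join(
                f"{lab}: {lo:.1f}..{hi:.1f}" for lab, lo, hi in ranges
            )
            for ph in grid:
                fr = species_fractions(system, float(ph))
                payload[f"{name}_fractions_pH_{ph:.2f}"] = ",".join(f"{x:.6f}" for x in fr)
        return _write_result(config, "speciation", payload)

    if subcommand == "partition-fit":
        table = _read_table(params["points_csv"])  # ph, potential_mV
        points = [(row[0], row[1] * MV_TO_V) for row in table]
        fit = fit_partition_model(
            points,
            pka=float(params["pka"]),
            charge=int(params.get("charge", 1)),
            conditions=config.conditions,
        )
        logp = logp_from_potential(
            fit.formal_potential, fit.model.charge, config.conditions
        )
        return _write_result(config, "partition_fit", {
            "kd": f"{fit.kd:.6g}",
            "kd_stderr": f"{fit.kd_stderr:.3g}",
            "formal_potential_mV": f"{fit.formal_potential * V_TO_MV:.3f}",
            "formal_potential_stderr_mV": f"{fit.formal_potential_stderr * V_TO_MV:.3f}",
            "logP": f"{logp:.3f}",
            "residual_norm_V": f"{fit.residual_norm:.3g}",
            "n_points": fit.n_points,
        })

    if subcommand == "calibrate":
        table = _read_table(params["points_csv"])  # concentration_uM, signal_uA|nA
        unit = params.get("signal_unit", "uA")
        scale = UA_TO_A if unit == "uA" else NA_TO_A
        pts = [(row[0] * UM_TO_M, row[1] * scale) for row in table]
        result = fit_calibration(pts, area=config.geometry.area)
        return _write_result(config, "calibration", {
            "sensitivity_A_per_M": f"{result.slope:.6g}",
            "normalized_sensitivity_A_per_M_cm2": f"{result.normalized_sensitivity:.6g}",
            "intercept_A": f"{result.intercept:.6g}",
            "sigma_intercept_A": f"{result.sigma_intercept:.6g}",
            "r_squared": f"{result.r_squared:.6f}",
            "lod_uM": f"{result.lod / UM_TO_M:.4g}",
            "loq_uM": f"{result.loq / UM_TO_M:.4g}",
        })

    if subcommand == "standard-addition":
        table = _read_table(params["points_csv"])  # added_uM, signal_nA
        unit = params.get("signal_unit", "nA")
        scale = NA_TO_A if unit == "nA" else UA_TO_A
        pts = [(row[0] * UM_TO_M, row[1] * scale) for row in table]
        result = standard_addition(
            pts,
            dilution_factor=float(params["dilution_factor"]),
            stock_volume=float(params["stock_volume_L"]),
            molar_mass=float(params["molar_mass"]),
            volume_correction=bool(params.get("volume_correction", False)),
        )
        return _write_result(config, "standard_addition", {
            "x_intercept_uM": f"{result.x_intercept_concentration / UM_TO_M:.4f}",
            "content_mass_mg": f"{result.content_mass * 1e3:.4f}",
            "slope_A_per_M": f"{result.slope:.6g}",
            "intercept_A": f"{result.intercept:.6g}",
            "r_squared": f"{result.r_squared:.6f}",
        })

    if subcommand == "transport":
        table = _read_table(params["points_csv"])  # scan_rate_mV_s, peak_current_uA
        pts = [(row[0] * MV_TO_V, row[1] * UA_TO_A) for row in table]
        fit = diffusion_from_scan_rate_series(
            pts,
            charge=int(params.get("charge", 1)),
            area=config.geometry.area,
            concentration=float(params["concentration_uM"]) * 1e-9,
            conditions=config.conditions,
        )
        payload = {
            "diffusion_cm2_s": f"{fit.diffusion:.4g}",
            "slope_A_sqrtVs": f"{fit.slope:.4g}",
            "intercept_A": f"{fit.intercept:.4g}",
            "r_squared": f"{fit.r_squared:.6f}",
        }
        if "steady_state_current_nA" in params:
            r = saito_radius(
                float(params["steady_state_current_nA"]) * NA_TO_A,
                charge=int(params.get("charge", 1)),
                diffusion=float(params["diffusion_cm2_s"]),
                concentration=float(params["concentration_uM"]) * 1e-9,
                conditions=config.conditions,
            )
            payload["saito_radius_um"] = f"{r * 1e4:.3f}"
        return _write_result(config, "transport", payload)

    if subcommand == "peaks":
        v = read_voltammogram(params["voltammogram_csv"])
        window = (float(params["window_low_mV"]) * MV_TO_V,
                  float(params["window_high_mV"]) * MV_TO_V)
        peaks = extract_peaks(v, window, baseline=params.get("baseline", "linear_pre_peak"))
        return _write_result(config, "peaks", {
            "forward_peak_potential_mV": f"{peaks.forward_peak_potential * V_TO_MV:.2f}",
            "forward_peak_current_A": f"{peaks.forward_peak_current:.6g}",
            "backward_peak_potential_mV": f"{peaks.backward_peak_potential * V_TO_MV:.2f}",
            "backward_peak_current_A": f"{peaks.backward_peak_current:.6g}",
            "midpoint_potential_mV": f"{peaks.midpoint_potential * V_TO_MV:.2f}",
            "baseline_method": peaks.baseline_method,
        })

    if subcommand == "detect":
        sample = read_voltammogram(params["sample_csv"])
        blank = read_voltammogram(params["blank_csv"])
        call = detect_analyte(
            sample,
            blank,
            expected_potential=float(params["expected_potential_mV"]) * MV_TO_V,
            tolerance=float(params.get("tolerance_mV", 50.0)) * MV_TO_V,
        )
        return _write_result(config, "detect", {"signal_present": call})

    # simulate
    species = [
        TransferSpecies(
            label=s["label"],
            charge=int(s.get("charge", 1)),
            formal_potential=float(s["formal_potential_mV"]) * MV_TO_V,
            diffusion_aq=float(s.get("diffusion_aq", 1.0e-5)),
            diffusion_org=float(s.get("diffusion_org", 1.0e-5)),
            concentration_aq=float(s["concentration_uM"]) * UM_TO_M,
        )
        for s in params.get("species", [])
    ]
    sim_kwargs = dict(params.get("sim", {}))
    sim_kwargs.setdefault("seed", config.seed)
    if config.geometry.kind == "micro":
        cfg = SimConfig.micro_defaults(radius_cm=config.geometry.radius, **sim_kwargs)
        v = simulate_micro_itv(species, cfg, config.conditions)
        unit = "nA"
    else:
        cfg = SimConfig(geometry=config.geometry, **sim_kwargs)
        v = simulate_macro_itv(species, cfg, config.conditions)
        unit = "uA"
    config.output_dir.mkdir(parents=True, exist_ok=True)
    out = config.output_dir / "simulated_itv.csv"
    v.metadata["config_hash"] = config.config_hash
    v.metadata["itieskit_version"] = _version
    write_voltammogram(v, out, current_unit=unit)
    logger.info("stage simulate -> %s", out)
    return out
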