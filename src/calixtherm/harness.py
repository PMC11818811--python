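"""File formats, configuration and the pipeline driver.

All tabular I/O is UTF-8 delimited text with explicit headers (decimal
point, no locale).  Spectra: first column the wavelength grid in nm,
remaining columns one titration point each.  ITC: injection index, volume
(mm^3), heat (mJ).  Trajectories: an extended-XYZ dialect whose per-atom
lines carry ``element x y z role molecule-id`` and whose comment line is
``t=<time/ps>``.  Run configuration is YAML validated against a strict
schema (unknown keys rejected) before any computation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from calixtherm import equilibria, itcfit, mdcoord, spectrofit, synthgen, thermo
from calixtherm.equilibria import BindingModel, Species, TitrationSeries, build_titration_series
from calixtherm.itcfit import ITCExperiment
from calixtherm.mdcoord import Frame, LabeledTrajectory
from calixtherm.spectrofit import SpectralDataset

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_itc_table",
    "write_itc_table",
    "read_trajectory",
    "write_trajectory",
    "RunConfig",
    "load_config",
    "model_from_config",
    "series_from_config",
    "run_pipeline",
]

logger = logging.getLogger("calixtherm")


# ---------------------------------------------------------------- spectra

def read_spectra(
    path: "str | Path",
    series: TitrationSeries | None = None,
    kind: str = "absorbance",
    path_length: float = 1.0,
    dilution_corrected: bool = False,
    sep: str = "\t",
) -> "SpectralDataset | tuple[np.ndarray, np.ndarray]":
    """Read a delimited spectral table (wavelength + one column per point).

    Returns a :class:`SpectralDataset` when a titration series is supplied,
    otherwise the raw ``(wavelengths, responses)`` arrays.  Ragged rows,
    non-numeric cells and duplicate wavelengths are parse errors naming
    the offending line.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        ncol = len(header.rstrip("\n").split(sep))
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(sep)
            if len(parts) != ncol:
                raise ValueError(f"{path.name}:{lineno}: ragged row ({len(parts)} fields, expected {ncol})")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-numeric cell") from exc
    data = np.array(rows)
    wl = data[:, 0]
    if len(np.unique(wl)) != len(wl):
        dup = wl[np.where(np.diff(np.sort(wl)) == 0)[0][0]]
        line = int(np.where(wl == dup)[0][-1]) + 2
        raise ValueError(f"{path.name}:{line}: duplicate wavelength {dup:g}")
    responses = data[:, 1:].T  # (points, wavelengths)
    if series is None:
        return wl, responses
    return SpectralDataset(
        kind=kind, wavelengths=wl, responses=responses, series=series,
        path_length=path_length, dilution_corrected=dilution_corrected,
    )


def write_spectra(path: "str | Path", dataset: SpectralDataset, sep: str = "\t") -> None:
    cols = {"wavelength_nm": dataset.wavelengths}
    for i in range(dataset.series.n_points):
        cols[f"point_{i}"] = dataset.responses[i]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.10g")


# -------------------------------------------------------------------- ITC

def read_itc_table(
    path: "str | Path",
    cell_volume: float,
    cell_conc: dict[str, float],
    syringe_conc: dict[str, float],
    temperature: float = 298.15,
    discard_first: bool = True,
    sep: str = "\t",
) -> ITCExperiment:
    """Read per-injection (index, volume/mm^3, heat/mJ) plus metadata."""
    df = pd.read_csv(path, sep=sep)
    required = {"injection", "volume_mm3", "heat_mJ"}
    if not required.issubset(df.columns):
        raise ValueError(f"ITC table must have columns {sorted(required)}")
    return ITCExperiment(
        cell_volume=cell_volume,
        injection_volumes=df["volume_mm3"].to_numpy(float),
        heats=df["heat_mJ"].to_numpy(float),
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        temperature=temperature,
        discard_first=discard_first,
    )


def write_itc_table(path: "str | Path", experiment: ITCExperiment, sep: str = "\t") -> None:
    pd.DataFrame(
        {
            "injection": np.arange(1, experiment.n_injections + 1),
            "volume_mm3": experiment.injection_volumes,
            "heat_mJ": experiment.heats,
        }
    ).to_csv(path, sep=sep, index=False, float_format="%.10g")


# ------------------------------------------------------------ trajectories

def write_trajectory(path: "str | Path", traj: LabeledTrajectory) -> None:
    """Extended-XYZ dialect: count line, 't=<ps>' comment, then per atom
    ``element x y z role molecule-id``."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for fr in traj.frames:
            fh.write(f"{len(traj.elements)}\n")
            fh.write(f"t={fr.time_ps:g}\n")
            for el, role, mid, xyz in zip(traj.elements, traj.roles, traj.mol_ids, fr.coords):
                fh.write(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f} {role} {mid}\n")


def read_trajectory(path: "str | Path", role_counts: dict[str, int] | None = None) -> LabeledTrajectory:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    i = 0
    frames: list[Frame] = []
    elements: list[str] = []
    roles: list[str] = []
    mol_ids: list[str] = []
    first = True
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i])
        except ValueError as exc:
            raise ValueError(f"{path}:{i+1}: expected atom count") from exc
        comment = lines[i + 1]
        t = float(comment.split("=", 1)[1]) if "=" in comment else 0.0
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            parts = lines[i + 2 + a].split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{i+3+a}: expected 6 fields (element x y z role mol-id)")
            el, x, y, z, role, mid = parts
            coords[a] = (float(x), float(y), float(z))
            if first:
                elements.append(el)
                roles.append(role)
                mol_ids.append(mid)
            elif roles[a] != role or elements[a] != el or mol_ids[a] != mid:
                raise ValueError(f"{path}:{i+3+a}: atom labels change between frames")
        frames.append(Frame(coords=coords, time_ps=t))
        first = False
        i += 2 + natoms
    kwargs = {} if role_counts is None else {"role_counts": role_counts}
    return LabeledTrajectory(elements, roles, mol_ids, frames, **kwargs)


# ------------------------------------------------------------ configuration

class SpeciesConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    stoich: dict[str, int]
    logBeta: float
    fixed: bool = False


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    components: list[str]
    species: list[SpeciesConfig] = Field(default_factory=list)


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cell: dict[str, float]
    titrant: dict[str, float] = Field(default_factory=dict)
    V0: float
    mode: Literal["cuvette", "itc_displacement"] = "cuvette"
    volumes: list[float] = Field(default_factory=list)
    temperature: float = 298.15


class RunConfig(BaseModel):
    """Schema-validated description of one pipeline run."""

    model_config = ConfigDict(extra="forbid")
    stage: Literal[
        "speciate", "fit_uv", "fit_fluor", "fit_itc", "itc_dh",
        "md_coord", "md_cluster", "plane", "simulate", "thermo_table",
    ]
    inputs: dict[str, str] = Field(default_factory=dict)
    model: ModelConfig | None = None
    protocol: ProtocolConfig | None = None
    options: dict[str, Any] = Field(default_factory=dict)
    output_dir: str = "results"


def load_config(path: "str | Path") -> RunConfig:
    import yaml

    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def model_from_config(cfg: ModelConfig) -> BindingModel:
    return BindingModel(
        list(cfg.components),
        [Species(s.name, dict(s.stoich), s.logBeta, s.fixed) for s in cfg.species],
    )


def series_from_config(cfg: ProtocolConfig) -> TitrationSeries:
    if not cfg.volumes:
        raise ValueError("protocol requires a volume schedule")
    if cfg.mode == "itc_displacement":
        # volumes given per-injection in mm^3 for calorimetry protocols
        return build_titration_series(
            cfg.cell, cfg.V0, cfg.titrant, [v / 1000.0 for v in cfg.volumes], mode=cfg.mode
        )
    return build_titration_series(cfg.cell, cfg.V0, cfg.titrant, cfg.volumes, mode=cfg.mode)


# ------------------------------------------------------------ pipeline

def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def run_pipeline(config: RunConfig, seed: int = 0) -> dict:
    """Execute one configured stage and write its result bundle.

    Writes ``results.json`` (machine readable), stage-specific delimited
    reports and ``run.log`` into the output directory; any stage error
    aborts before partial outputs are committed.  Deterministic given the
    seed.
    """
    t0 = time.monotonic()
    outdir = Path(config.output_dir)
    results: dict[str, Any] = {"stage": config.stage, "seed": seed}
    input_hashes = {}
    for key, p in config.inputs.items():
        path = Path(p)
        if not path.exists():
            raise FileNotFoundError(f"input {key!r}: {p} does not exist")
        input_hashes[key] = _hash_file(path)
    results["input_hashes"] = input_hashes

    stage = config.stage
    if stage == "speciate":
        model = model_from_config(config.model)
        series = series_from_config(config.protocol)
        prof = equilibria.speciation_profile(model, series, tol=config.options.get("tol", 1e-12))
        cols = [f"free_{c}" for c in model.components] + [sp.name for sp in model.species]
        df = pd.DataFrame(prof, columns=cols)
        df.insert(0, "volume_cm3", series.volumes)
        results["speciation"] = df
    elif stage in ("fit_uv", "fit_fluor"):
        model = model_from_config(config.model)
        series = series_from_config(config.protocol)
        kind = "absorbance" if stage == "fit_uv" else "fluorescence"
        dataset = read_spectra(
            config.inputs["spectra"], series=series, kind=kind,
            path_length=config.options.get("path_length", 1.0),
            dilution_corrected=config.options.get("dilution_corrected", False),
        )
        if not dataset.dilution_corrected:
            dataset = spectrofit.dilution_correct(dataset)
        if config.options.get("competitive", False):
            fit = spectrofit.fit_competitive(
                dataset, model,
                ligand=config.options.get("ligand", "L"),
                reference_component=config.options.get("reference", "Na"),
            )
        else:
            fit = spectrofit.fit_direct(dataset, model, ligand=config.options.get("ligand", "L"))
        results["fit"] = {
            "log_betas": fit.log_betas,
            "std_errors": fit.std_errors,
            "ssq": fit.ssq,
            "unidentifiable": fit.unidentifiable,
        }
    elif stage in ("fit_itc", "itc_dh"):
        proto = config.protocol
        exp = read_itc_table(
            config.inputs["heats"],
            cell_volume=proto.V0,
            cell_conc=proto.cell,
            syringe_conc=proto.titrant,
            temperature=proto.temperature,
            discard_first=config.options.get("discard_first", True),
        )
        if "blank_constant" in config.options:
            exp = itcfit.correct_dilution(exp, float(config.options["blank_constant"]))
        ligand = config.options.get("ligand", "L")
        titrant = config.options.get("titrant", "M")
        if stage == "itc_dh":
            dh, se = itcfit.fit_enthalpy_only(
                exp, ratio_cutoff=config.options.get("ratio_cutoff", 0.8),
                ligand=ligand, titrant=titrant,
                log_k=config.options.get("logK"),
            )
            results["fit"] = {"delta_h": dh, "delta_h_se": se}
        elif config.options.get("competitive", False):
            fit = itcfit.fit_competitive_itc(
                exp,
                reference_log_k=config.options.get("reference_logK"),
                reference_delta_h=config.options.get("reference_dH"),
                ligand=ligand, titrant=titrant,
                reference=config.options.get("reference", "Na"),
            )
            results["fit"] = _itc_result_dict(fit)
        else:
            fit = itcfit.fit_itc_1to1(exp, ligand=ligand, titrant=titrant,
                                      float_n=config.options.get("float_n", False))
            results["fit"] = _itc_result_dict(fit)
    elif stage == "md_coord":
        traj = read_trajectory(config.inputs["trajectory"])
        cutoffs = config.options.get("cutoffs")
        coord = mdcoord.coordination_series(traj, cutoffs)
        timeline = mdcoord.classify_inclusion(
            traj, max_distance=config.options.get("cavity_distance", 7.5)
        )
        distinct, exchanges = mdcoord.count_exchanges(timeline)
        results["coordination"] = {"mean": coord["mean"], "se": coord["se"]}
        results["inclusion"] = {
            "fractions": timeline.fractions(),
            "distinct_occupants": distinct,
            "exchanges": exchanges,
        }
        results["timeline"] = pd.DataFrame(
            {"frame": np.arange(traj.n_frames), "state": timeline.states,
             "occupant": [o or "" for o in timeline.occupants]}
        )
    elif stage == "md_cluster":
        traj = read_trajectory(config.inputs["trajectory"])
        matrix = mdcoord.build_coordination_matrix(traj)
        k_max = int(config.options.get("k_max", 6))
        clusters = mdcoord.pca_cluster_representatives(matrix, range(1, k_max + 1), seed=seed)
        results["clusters"] = {
            "k": clusters["k"],
            "representatives": clusters["representatives"],
            "populations": clusters["populations"],
        }
    elif stage == "plane":
        traj = read_trajectory(config.inputs["trajectory"])
        rep = mdcoord.geometry_report(
            traj, frame=int(config.options.get("frame", 0)),
            solvent_mol=config.options.get("solvent_mol"),
        )
        results["geometry"] = rep
    elif stage == "simulate":
        results["simulated"] = _run_simulate(config, seed, outdir)
    elif stage == "thermo_table":
        results.update(_run_thermo_table(config))

    outdir.mkdir(parents=True, exist_ok=True)
    elapsed = time.monotonic() - t0
    results["elapsed_s"] = round(elapsed, 4)
    with (outdir / "results.json").open("w", encoding="utf-8") as fh:
        json.dump(_jsonable(results), fh, indent=2)
    for key in ("speciation", "timeline"):
        if isinstance(results.get(key), pd.DataFrame):
            results[key].to_csv(outdir / f"{key}.tsv", sep="\t", index=False)
    with (outdir / "run.log").open("a", encoding="utf-8") as fh:
        fh.write(
            f"stage={config.stage} seed={seed} inputs={json.dumps(input_hashes)} "
            f"elapsed_s={elapsed:.4f}\n"
        )
    logger.info("stage %s done in %.3f s", config.stage, elapsed)
    return results


def _itc_result_dict(fit) -> dict:
    return {
        "logK": fit.log_k, "logK_se": fit.log_k_se,
        "delta_h": fit.delta_h, "delta_h_se": fit.delta_h_se,
        "offset": fit.offset, "n": fit.n_sites, "c_value": fit.c_value,
        "k_unidentifiable": fit.k_unidentifiable,
    }


def _run_simulate(config: RunConfig, seed: int, outdir: Path) -> dict:
    what = config.options.get("what", "spectra")
    outdir.mkdir(parents=True, exist_ok=True)
    if what == "spectra":
        model = model_from_config(config.model)
        series = series_from_config(config.protocol)
        dataset, truth = synthgen.gen_titration_spectra(
            model, series, noise_sd=float(config.options.get("noise_sd", 0.0)), seed=seed,
        )
        write_spectra(outdir / "spectra.tsv", dataset)
        (outdir / "truth.json").write_text(json.dumps(_jsonable(truth.to_dict()), indent=2))
        return {"file": str(outdir / "spectra.tsv"), "n_points": dataset.series.n_points}
    if what == "itc":
        model = model_from_config(config.model)
        proto = config.protocol
        shell = ITCExperiment(
            cell_volume=proto.V0,
            injection_volumes=np.asarray(proto.volumes, dtype=float),
            heats=np.zeros(len(proto.volumes)),
            cell_conc=proto.cell,
            syringe_conc=proto.titrant,
            temperature=proto.temperature,
        )
        sim, truth = synthgen.gen_itc(
            model, shell,
            delta_h={k: float(v) for k, v in config.options.get("delta_h", {}).items()},
            offset=float(config.options.get("offset", 0.0)),
            noise_sd=float(config.options.get("noise_sd", 0.0)),
            seed=seed,
        )
        write_itc_table(outdir / "itc.tsv", sim)
        (outdir / "truth.json").write_text(json.dumps(_jsonable(truth.to_dict()), indent=2))
        return {"file": str(outdir / "itc.tsv"), "n_injections": sim.n_injections}
    if what == "trajectory":
        schedule = [tuple(s) for s in config.options.get("schedule", [["HEAD_IN", "S1"]] * 50)]
        schedule = [(st, occ if occ else None) for st, occ in schedule]
        traj, truth = synthgen.gen_trajectory(
            schedule, jitter_sd=float(config.options.get("jitter_sd", 0.05)), seed=seed,
        )
        write_trajectory(outdir / "trajectory.xyz", traj)
        (outdir / "truth.json").write_text(json.dumps(_jsonable(truth.to_dict()), indent=2))
        return {"file": str(outdir / "trajectory.xyz"), "n_frames": traj.n_frames}
    raise ValueError(f"unknown simulation target {what!r}")


def _run_thermo_table(config: RunConfig) -> dict:
    from calixtherm import reference_data

    if "records" in config.options:
        records = [
            thermo.ThermoRecord(**{k: (tuple(v) if k == "methods" else v) for k, v in r.items()})
            for r in config.options["records"]
        ]
    else:
        records = reference_data.thermo_records()
    table = thermo.records_table(records)
    comparison = thermo.compare_solvents(records)
    out = {
        "table": table,
        "rankings": comparison["rankings"],
        "pairwise": comparison["pairwise"],
    }
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "thermo_table.tsv", sep="\t", index=False)
    return out
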