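"""Reproducible generate → analyze → report pipeline.

A run config (YAML or dict) declares a grid of systems (chain types),
salt conditions and replicates, the generator/simulator parameters, and
the analyses to run.  Every replicate gets a deterministic seed derived
from the global seed through ``numpy.random.SeedSequence`` mixing of
(global_seed, system index, condition index, replicate index), so
replicates are independent yet the whole grid is reproducible from one
integer.  Outputs are tidy CSVs (one per analysis) plus a JSON manifest
carrying parameters, seeds and file checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adsorption import adsorption_series
from .chain import CHAIN_FACTORIES, SaltSpec
from .generators import sample_ideal_chain
from .mc import DEFAULT_BOX_EDGE, MCParams, run_cg_simulation
from .metrics import rg_series
from .pca import align_frames, fit_pca, pc_bounding_area
from .relaxation import relaxation_time
from .scaling import DEFAULT_FIT_RANGE, flory_exponent

__all__ = ["RunConfig", "run_pipeline", "summarize_conditions",
           "replicate_seed"]

KNOWN_ANALYSES = ("rg", "flory", "tau", "ions", "pca")


@dataclass
class RunConfig:
    systems: list[dict]
    conditions: list[dict]
    analyses: list[str]
    outdir: str = "polyion_out"
    seed: int = 0
    replicates: int = 1
    box_edge: float = DEFAULT_BOX_EDGE
    mc: dict = field(default_factory=dict)
    analysis_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be ≥ 1")
        unknown = [a for a in self.analyses if a not in KNOWN_ANALYSES]
        if unknown:
            raise ValueError(
                f"unknown analyses {unknown}; available: {KNOWN_ANALYSES}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def replicate_seed(global_seed: int, system_index: int, condition_index: int,
                   replicate: int) -> int:
    """Deterministic per-replicate seed below 2³¹."""
    ss = np.random.SeedSequence(
        [global_seed, system_index, condition_index, replicate]
    )
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _build_ensemble(system: dict, condition: dict, box_edge: float,
                    mc_options: dict, seed: int):
    chain_name = system.get("chain", system.get("name"))
    if chain_name not in CHAIN_FACTORIES:
        raise ValueError(f"unknown chain type {chain_name!r}")
    kwargs = {}
    if "n_residues" in system:
        kwargs["n"] = int(system["n_residues"])
    if "bead_diameter" in system:
        kwargs["bead_diameter"] = float(system["bead_diameter"])
    spec = CHAIN_FACTORIES[chain_name](**kwargs)
    generator = system.get("generator", "cg_mc")
    if generator == "ideal":
        return sample_ideal_chain(spec, int(system.get("n_frames", 1000)), seed)
    salt = SaltSpec(
        cation_valence=int(condition.get("cation_valence", 1)),
        concentration=float(condition.get("concentration", 0.0)),
        neutralize_chain=bool(condition.get("neutralize_chain", True)),
    )
    params = MCParams(seed=seed, **mc_options)
    return run_cg_simulation(spec, salt, box_edge=box_edge, params=params)


def _analyze(ensemble, analyses: list[str], options: dict) -> dict:
    row: dict = {}
    tables: dict[str, pd.DataFrame] = {}
    rg = None
    if "rg" in analyses or "tau" in analyses or "ions" in analyses:
        rg = rg_series(ensemble)
    if "rg" in analyses:
        row["mean_rg"] = rg.mean
        row["std_rg"] = rg.summary["std"]
        tables["rg"] = rg.to_frame()
    if "flory" in analyses:
        opts = options.get("flory", {})
        result = flory_exponent(
            ensemble,
            fit_range=tuple(opts.get("fit_range", DEFAULT_FIT_RANGE)),
            estimator=opts.get("estimator", "rms_distance"),
        )
        row["nu"] = result.nu
        row["nu_stderr"] = result.stderr_nu
        tables["flory"] = pd.DataFrame({
            "separation": result.separations,
            "rms_distance": result.rms_distance,
        })
    if "tau" in analyses:
        result = relaxation_time(rg.values, spacing=rg.spacing, unit=rg.unit)
        row["tau"] = result.tau_physical
        row["tau_converged"] = result.converged
        tables["tau"] = pd.DataFrame({"lag": result.lags, "acf": result.acf})
    if "ions" in analyses:
        opts = options.get("ions", {})
        result = adsorption_series(
            ensemble, cutoff=float(opts.get("cutoff", 4.0)),
            species_filter=opts.get("species", "counterions"),
        )
        row["mean_adsorbed"] = result.mean_count
        tables["ions"] = pd.DataFrame({
            "frame": np.arange(len(result.per_frame_counts)),
            "adsorbed": result.per_frame_counts,
        })
    if "pca" in analyses:
        aligned = align_frames(ensemble)
        result = fit_pca(aligned)
        row["pc_area"] = pc_bounding_area(result.projections)
        row["pc1_var"] = float(result.eigenvalues[0])
        tables["pca"] = pd.DataFrame(result.projections,
                                     columns=["PC1", "PC2"])
    return {"summary": row, "tables": tables}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full grid; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "runs": [], "failures": []}
    summary_rows = []
    for si, system in enumerate(config.systems):
        for ci, condition in enumerate(config.conditions):
            for rep in range(config.replicates):
                seed = replicate_seed(config.seed, si, ci, rep)
                run_id = (f"{system.get('name', system.get('chain'))}_"
                          f"{condition.get('name', ci)}_r{rep}")
                try:
                    ens = _build_ensemble(system, condition, config.box_edge,
                                          config.mc, seed)
                    out = _analyze(ens, config.analyses,
                                   config.analysis_options)
                except Exception as exc:   # partial failure: keep going
                    manifest["failures"].append(
                        {"run": run_id, "error": f"{type(exc).__name__}: {exc}"}
                    )
                    continue
                rundir = outdir / run_id
                rundir.mkdir(exist_ok=True)
                files = {}
                for name, table in out["tables"].items():
                    fp = rundir / f"{name}.csv"
                    table.to_csv(fp, index=False)
                    files[name] = {"path": str(fp), "sha256": _checksum(fp)}
                row = {"system": system.get("name", system.get("chain")),
                       "condition": condition.get("name", str(ci)),
                       "replicate": rep, "seed": seed, **out["summary"]}
                summary_rows.append(row)
                manifest["runs"].append({"run": run_id, "seed": seed,
                                         "files": files})
    summary = pd.DataFrame(summary_rows)
    sp = outdir / "replicates.csv"
    summary.to_csv(sp, index=False)
    manifest["summary_table"] = {"path": str(sp), "sha256": _checksum(sp)}
    if not summary.empty:
        cond = summarize_conditions(summary)
        cp = outdir / "conditions.csv"
        cond.to_csv(cp, index=False)
        manifest["condition_table"] = {"path": str(cp),
                                       "sha256": _checksum(cp)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def summarize_conditions(replicate_table: pd.DataFrame) -> pd.DataFrame:
    """Per (system, condition) mean ± sd across replicates.

    With a single replicate the sd is reported as missing (NaN), not zero.
    """
    required = {"system", "condition", "replicate"}
    missing = required - set(replicate_table.columns)
    if missing:
        raise ValueError(f"replicate table lacks columns {sorted(missing)}")
    metrics = [c for c in replicate_table.columns
               if c not in required | {"seed"}
               and pd.api.types.is_numeric_dtype(replicate_table[c])]
    grouped = replicate_table.groupby(["system", "condition"], sort=False)
    rows = []
    for (system, condition), grp in grouped:
        row = {"system": system, "condition": condition,
               "n_replicates": len(grp)}
        for m in metrics:
            row[f"{m}_mean"] = float(grp[m].mean())
            row[f"{m}_sd"] = (float(grp[m].std(ddof=1))
                              if len(grp) > 1 else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
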