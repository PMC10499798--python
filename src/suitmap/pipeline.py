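"""End-to-end orchestration: simulate -> fit -> project -> account.

A single YAML config drives the run. Every stage writes its artifacts under
``outdir`` and the run finishes with a manifest (config hash, seeds, package
version, per-artifact checksums). All randomness derives from ``base_seed``
(and the synthetic section's ``seed``), so rerunning an identical config
reproduces byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brt import (BRTConfig, ensemble_curves, ensemble_predict, ensemble_rc,
                  fit_ensemble, load_ensemble, save_ensemble)
from .errors import SuitmapError, ValidationError
from .raster import (CovariateStack, LandCoverMap, Raster, RegionMap,
                     SuitabilityMap, read_points, read_raster, write_points,
                     write_raster)
from .sampling import (bootstrap_reference, draw_background, grid_presences,
                       screen_background_candidates)
from .accounting import scenario_report
from . import synthetic

log = logging.getLogger("suitmap")

STAGES = ("simulate", "fit", "project", "account")

_KNOWN_KEYS = {"outdir", "base_seed", "B", "tau", "allowed_landcover", "brt",
               "synthetic", "paths"}


@dataclass
class RunConfig:
    outdir: Path
    base_seed: int = 0
    B: int = 25
    tau: float = 0.5
    allowed_landcover: tuple[int, ...] = tuple(sorted(synthetic.MARGINAL_CLASSES))
    brt: BRTConfig = field(default_factory=BRTConfig)
    synthetic: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        if not 0 < self.tau < 1:
            raise ValidationError("tau must be in (0, 1)")

    @property
    def world_dir(self) -> Path:
        return Path(self.outdir) / "world"

    def config_hash(self) -> str:
        doc = asdict(self)
        doc["outdir"] = str(doc["outdir"])
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()


def validate_config(path) -> RunConfig:
    """Parse, default, and validate a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
    problems = []
    if "outdir" not in doc:
        problems.append("config must set 'outdir'")
    brt_cfg = BRTConfig(**doc.get("brt", {}))
    paths = {k: Path(v) for k, v in (doc.get("paths") or {}).items()
             if v is not None}
    for key, p in paths.items():
        if not p.exists():
            problems.append(f"paths.{key}: {p} does not exist")
    if problems:
        raise ValidationError("invalid configuration:\n  " + "\n  ".join(problems))
    return RunConfig(outdir=Path(doc["outdir"]),
                     base_seed=int(doc.get("base_seed", 0)),
                     B=int(doc.get("B", 25)),
                     tau=float(doc.get("tau", 0.5)),
                     allowed_landcover=tuple(doc.get(
                         "allowed_landcover",
                         sorted(synthetic.MARGINAL_CLASSES))),
                     brt=brt_cfg, synthetic=doc.get("synthetic", {}),
                     paths=paths)


def _write_world(world: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    stack: CovariateStack = world["stack"]
    for name, layer in stack.layers.items():
        write_raster(layer, out / f"{name}.tif")
    write_raster(world["truth"].mean, out / "truth.tif")
    write_points(world["points"], out / "occurrences.csv")
    write_raster(world["landcover"].raster, out / "landcover.tif")
    (out / "landcover_legend.json").write_text(
        json.dumps({str(k): v for k, v in world["landcover"].legend.items()}))
    write_raster(world["regions"].raster, out / "regions.tif")
    world["regions"].table.to_csv(out / "regions.csv", index=False)
    synthetic.save_scenarios(world["scenarios"], out / "scenarios.yaml")
    meta = {"layer_order": stack.names,
            "climate_layers": list(stack.climate_layers),
            "categorical_layers": list(stack.categorical_layers)}
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def _load_world(cfg: RunConfig):
    wd = cfg.world_dir
    meta_path = Path(cfg.paths.get("world_meta", wd / "meta.json"))
    if not meta_path.exists():
        raise SuitmapError(f"missing artifact: {meta_path} (run 'simulate' "
                           "first or point paths at real layers)")
    meta = json.loads(meta_path.read_text())
    layers = {}
    for name in meta["layer_order"]:
        r = read_raster(wd / f"{name}.tif")
        if name in meta["categorical_layers"]:
            r = Raster(r.grid, r.values.astype(np.int32), r.mask)
        layers[name] = r
    stack = CovariateStack(next(iter(layers.values())).grid, layers,
                           tuple(meta["climate_layers"]),
                           tuple(meta["categorical_layers"]))
    legend = {int(k): v for k, v in json.loads(
        (wd / "landcover_legend.json").read_text()).items()}
    lc = LandCoverMap(read_raster(wd / "landcover.tif"), legend)
    regions = RegionMap(read_raster(wd / "regions.tif"),
                        pd.read_csv(wd / "regions.csv"))
    shifts = synthetic.load_scenarios(wd / "scenarios.yaml")
    return stack, lc, regions, shifts


def stage_simulate(cfg: RunConfig) -> None:
    syn = dict(cfg.synthetic)
    seed = int(syn.pop("seed", cfg.base_seed))
    world = synthetic.default_world(seed=seed, **syn)
    _write_world(world, cfg.world_dir)
    log.info("simulate: wrote synthetic world to %s", cfg.world_dir)


def stage_fit(cfg: RunConfig) -> None:
    stack, _, _, _ = _load_world(cfg)
    occ_path = cfg.paths.get("occurrences", cfg.world_dir / "occurrences.csv")
    points, dropped = read_points(occ_path)
    presences = grid_presences(points, stack)
    log.info("fit: %d points -> %d presence cells (%d dropped)",
             len(points), len(presences), dropped)
    if "reference" in cfg.paths:
        reference = SuitabilityMap(read_raster(cfg.paths["reference"]))
        log.info("fit: screening with external reference %s",
                 cfg.paths["reference"])
    else:
        reference = bootstrap_reference(stack, presences, cfg.brt,
                                        seed=cfg.base_seed)
        log.info("fit: screening with bootstrap reference")
    candidates = screen_background_candidates(reference, presences, stack)
    draws = draw_background(candidates, len(presences), cfg.B, cfg.base_seed)
    cfg_brt = BRTConfig(**{**asdict(cfg.brt), "base_seed": cfg.base_seed})
    ens = fit_ensemble(presences, draws, stack, cfg_brt)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_ensemble(ens, out / "model.json")
    rc = ensemble_rc(ens)
    rc.table.to_csv(out / "relative_contributions.csv", index=False)
    top = rc.table["variable"].head(4).tolist()
    top = [v for v in top if v not in stack.categorical_layers]
    rows = []
    for curve in ensemble_curves(ens, top, n_points=50):
        for xv, yv in zip(curve.grid_values, curve.mean_response):
            rows.append({"variable": curve.variable, "x": xv, "response": yv})
    pd.DataFrame(rows).to_csv(out / "effect_curves.csv", index=False)
    smap = ensemble_predict(ens, stack)
    write_raster(smap.mean, out / "suitability_mean.tif")
    write_raster(smap.sd, out / "suitability_sd.tif")
    auc = ens.cv_auc_summary()
    (out / "cv_auc.json").write_text(json.dumps(auc["formatted"], indent=1))
    log.info("fit: CV AUC %s", auc["formatted"])


def _scenario_stacks(cfg: RunConfig):
    stack, lc, regions, shifts = _load_world(cfg)
    stacks = {s.label: synthetic.perturb_scenario(stack, s) for s in shifts}
    return stack, lc, regions, stacks


def stage_project(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    model_path = out / "model.json"
    if not model_path.exists():
        raise SuitmapError(f"missing artifact: {model_path} (run 'fit' first)")
    stack, _, _, stacks = _scenario_stacks(cfg)
    ens = load_ensemble(model_path, stack)
    proj = out / "projections"
    proj.mkdir(parents=True, exist_ok=True)
    for label, s in stacks.items():
        smap = ensemble_predict(ens, s)
        write_raster(smap.mean, proj / f"suitability_{label}.tif")
        log.info("project: wrote %s", proj / f"suitability_{label}.tif")


def stage_account(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    model_path = out / "model.json"
    if not model_path.exists():
        raise SuitmapError(f"missing artifact: {model_path} (run 'fit' first)")
    stack, lc, regions, stacks = _scenario_stacks(cfg)
    ens = load_ensemble(model_path, stack)
    report = scenario_report(ens, stacks, lc, regions, stack, tau=cfg.tau,
                             allowed=set(cfg.allowed_landcover))
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    report.current_areas.rounded().to_csv(tables / "area_current.csv",
                                          index=False)
    for label, at in report.areas.items():
        at.rounded().to_csv(tables / f"area_{label}.csv", index=False)
    for label, dt in report.deltas.items():
        df = pd.concat([dt.table, dt.global_row.to_frame().T],
                       ignore_index=True)
        for col in ("expansion_mha", "contraction_mha", "net_mha"):
            df[col] = df[col].astype(float).round(2)
        df.to_csv(tables / f"delta_{label}.csv", index=False)
    log.info("account: wrote area/delta tables to %s "
             "(current total %.2f Mha)", tables,
             report.current_areas.total_mha)


def write_manifest(cfg: RunConfig, stages: list[str]) -> Path:
    out = Path(cfg.outdir)
    artifacts = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            artifacts[str(p.relative_to(out))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    manifest = {"config_hash": cfg.config_hash(), "base_seed": cfg.base_seed,
                "version": __version__, "stages": stages,
                "artifacts": artifacts}
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


_STAGE_FNS = {"simulate": stage_simulate, "fit": stage_fit,
              "project": stage_project, "account": stage_account}


def run(cfg: RunConfig, stages=STAGES) -> Path:
    """Execute the requested stages in canonical order; returns the manifest."""
    ordered = [s for s in STAGES if s in set(stages)]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    for stage in ordered:
        log.info("--- stage %s ---", stage)
        _STAGE_FNS[stage](cfg)
    return write_manifest(cfg, ordered)
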