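"""Orchestration, file formats and the demo workflow.

Rasters travel as ESRI ASCII grids (.asc), tables as RFC-4180 CSV.  The
pipeline runs simulate -> assign -> catchment -> fit -> vulnerability ->
report from a single seeded configuration; per-species failures are
isolated and recorded in the run manifest rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catchment_population import (
    MissingEstimateError,
    aggregate_surface,
    continental_fallback,
    delineate_catchment,
    range_only_catchment,
    subpopulation_size,
)
from .demographic_model import (
    ConstraintLevel,
    DemographicPriors,
    MCMCConfig,
    fit_demographic_model,
    select_model,
)
from .isotope_assignment import assignment_surface, classify_origin
from .synthetic_world import (
    TrueDemography,
    WorldConfig,
    generate_isoscape,
    generate_population_estimates,
    generate_region_map,
    simulate_feathers,
    simulate_index_series,
)
from .vulnerability_analysis import (
    assess_vulnerability,
    relative_risk,
    summarize_correlates,
)

__all__ = [
    "read_grid",
    "write_grid",
    "read_table",
    "write_table",
    "ConfigError",
    "SpeciesConfig",
    "PipelineConfig",
    "RunManifest",
    "load_config",
    "demo_config",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# rasters and tables

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_grid(
    path,
    data: np.ndarray,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float = 1.0,
    nodata: float = -9999.0,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid (row-major, north-up)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("grid data must be 2-D")
    out = np.where(np.isnan(data), nodata, data)
    lines = [
        f"ncols {data.shape[1]}",
        f"nrows {data.shape[0]}",
        f"xllcorner {float(xllcorner)!r}",
        f"yllcorner {float(yllcorner)!r}",
        f"cellsize {float(cellsize)!r}",
        f"NODATA_value {float(nodata)!r}",
    ]
    for row in out:
        lines.append(" ".join(repr(float(v)) for v in row))
    _atomic_write_text(path, "\n".join(lines) + "\n")


def read_grid(path):
    """Read an ESRI ASCII grid; returns (array, meta dict).

    NODATA cells come back as NaN; meta holds the six header fields.
    Malformed headers raise with the offending line number.
    """
    text = Path(path).read_text().splitlines()
    meta = {}
    i = 0
    for i, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            key = "nodata" if parts[0].lower() == "nodata_value" else parts[0].lower()
            try:
                meta[key] = float(parts[1])
            except ValueError:
                raise ValueError(f"{path}: bad header value on line {i + 1}: {line!r}")
        else:
            break
    for key in ("ncols", "nrows"):
        if key not in meta:
            raise ValueError(f"{path}: missing required header field {key!r} (line {i + 1})")
    nrows, ncols = int(meta["nrows"]), int(meta["ncols"])
    body = text[i : i + nrows]
    try:
        data = np.array([[float(v) for v in line.split()] for line in body])
    except ValueError:
        raise ValueError(f"{path}: non-numeric raster value near line {i + 1}")
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: raster body is {data.shape}, header says {(nrows, ncols)}"
        )
    nodata = meta.get("nodata", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    meta.setdefault("xllcorner", 0.0)
    meta.setdefault("yllcorner", 0.0)
    meta.setdefault("cellsize", 1.0)
    meta.setdefault("nodata", -9999.0)
    meta["ncols"], meta["nrows"] = ncols, nrows
    return data, meta


def write_table(path, table: pd.DataFrame) -> None:
    _atomic_write_text(path, table.to_csv(index=False))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# configuration


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every problem found."""


@dataclass
class SpeciesConfig:
    name: str
    demography: TrueDemography
    priors: DemographicPriors
    n_local: int = 10
    n_nonlocal: int = 10
    bcr_means: Mapping[int, float] = field(default_factory=dict)
    cp: Optional[float] = None  # continental estimate for fallback paths
    index_years: int = 48
    q_scale: float = 0.05
    sigma_obs: float = 0.05
    n0_total: float = 2000.0
    traits: Mapping[str, str] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    world: WorldConfig
    species: Sequence[SpeciesConfig]
    odds_threshold: float = 5.0
    or_rule: str = "uniform_null"
    levels: Sequence[int] = (1, 2, 3)
    mcmc_preset: str = "desk"
    scenario_years: int = 48
    scenario_iters: int = 1000
    estimates_cv: Optional[float] = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["world"]["flyway_members"] = sorted(self.world.flyway_members)
        for sp in d["species"]:
            sp["bcr_means"] = {str(k): v for k, v in sp["bcr_means"].items()}
            sp["priors"]["survival"] = {
                k: list(v) for k, v in sp["priors"]["survival"].items()
            }
            sp["priors"]["fecundity"] = list(sp["priors"]["fecundity"])
            sp["demography"]["phi_by_age"] = list(sp["demography"]["phi_by_age"])
        d["levels"] = list(self.levels)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        problems = []
        world = None
        try:
            w = dict(d["world"])
            w["flyway_members"] = frozenset(int(m) for m in w.get("flyway_members", ()))
            if w.get("facility_cell") is not None:
                w["facility_cell"] = tuple(w["facility_cell"])
            if w.get("range_rows") is not None:
                w["range_rows"] = tuple(w["range_rows"])
            world = WorldConfig(**w)
        except (KeyError, TypeError, ValueError) as exc:
            problems.append(f"world: {exc}")
        species = []
        for i, sd in enumerate(d.get("species", [])):
            try:
                sd = dict(sd)
                demog = sd.pop("demography")
                priors = sd.pop("priors")
                sd["demography"] = TrueDemography(
                    phi_by_age=tuple(demog["phi_by_age"]),
                    fecundity=float(demog["fecundity"]),
                    n_ages=int(demog.get("n_ages", 2)),
                    age_first_breeding=demog.get("age_first_breeding"),
                    terminal_breeding_only=demog.get("terminal_breeding_only", True),
                )
                sd["priors"] = DemographicPriors(
                    survival={k: tuple(v) for k, v in priors["survival"].items()},
                    fecundity=tuple(priors["fecundity"]),
                    source=priors.get("source", "species"),
                )
                sd["bcr_means"] = {int(k): float(v) for k, v in sd.get("bcr_means", {}).items()}
                species.append(SpeciesConfig(**sd))
            except (KeyError, TypeError, ValueError) as exc:
                problems.append(f"species[{i}]: {exc}")
        if not species and not problems:
            problems.append("species: list is empty")
        extra = {
            k: d[k]
            for k in (
                "odds_threshold", "or_rule", "levels", "mcmc_preset",
                "scenario_years", "scenario_iters", "estimates_cv", "seed",
            )
            if k in d
        }
        if problems:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
        return cls(world=world, species=species, **extra)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def demo_config(seed: int = 0) -> PipelineConfig:
    """Bundled two-species demonstration cohort.

    One species is engineered with a small local catchment population and
    λ ≈ 1 (highly vulnerable to ~1000 added fatalities), the other with
    multi-million catchment populations (robust even to 5000).
    """
    world = WorldConfig(
        grid_rows=8,
        grid_cols=6,
        isoscape_slope=-8.0,
        isoscape_intercept=-40.0,
        cell_sd=3.0,
        n_bcrs=8,  # one-row BCR bands
        local_bcr_id=1,
        flyway_members=frozenset(range(6)),
        seed=seed,
    )
    demog = TrueDemography(phi_by_age=(0.5, 0.8), fecundity=0.4, n_ages=2)
    priors = DemographicPriors(
        survival={"phi_1": (0.5, 0.05), "phi_a": (0.8, 0.04)},
        fecundity=(0.4, 0.1),
    )
    small = SpeciesConfig(
        name="smallpop",
        demography=demog,
        priors=priors,
        n_local=12,
        n_nonlocal=8,
        bcr_means={0: 20000.0, 1: 2500.0, 2: 20000.0, 3: 20000.0, 4: 20000.0, 5: 20000.0},
        cp=100000.0,
        n0_total=2000.0,
        traits={"guild": "passerine", "migration": "resident", "habitat": "grassland"},
    )
    big = SpeciesConfig(
        name="bigpop",
        demography=demog,
        priors=priors,
        n_local=10,
        n_nonlocal=10,
        bcr_means={b: 6e6 for b in range(6)},
        cp=3e7,
        n0_total=50000.0,
        traits={"guild": "passerine", "migration": "migrant", "habitat": "scrub"},
    )
    return PipelineConfig(world=world, species=[small, big], seed=seed)


# ---------------------------------------------------------------------------
# run manifest and pipeline


_SEVERITY = {"not vulnerable": 0, "moderately vulnerable": 1, "highly vulnerable": 2}


@dataclass
class RunManifest:
    version: str
    config_hash: str
    species: dict = field(default_factory=dict)  # name -> {status, classification, detail}
    stages: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _stage_seed(base: int, stage: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base), stage, index])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Execute the five-step workflow end to end and write all artefacts.

    Outputs per run: world rasters, per-species sample/call/Np tables, fit
    diagnostics, vulnerability curves/classifications, relative risk, a
    correlate summary and ``manifest.json``.  A failure in one species is
    caught, recorded and does not abort the others.
    """
    outdir = Path(outdir)
    manifest = RunManifest(version=__version__, config_hash=config.config_hash())

    iso = generate_isoscape(config.world)
    region_map = generate_region_map(config.world)
    write_grid(outdir / "world" / "isoscape_mu.asc", iso.mu)
    write_grid(outdir / "world" / "isoscape_sd.asc", iso.sd)
    write_grid(outdir / "world" / "bcr.asc", region_map.bcr.astype(float))
    write_grid(outdir / "world" / "range.asc", region_map.range_mask.astype(float))
    write_grid(outdir / "world" / "flyway.asc", region_map.flyway_mask.astype(float))
    manifest.stages.append("simulate")

    all_calls, all_np, all_curves, all_class, all_rr, all_results = [], [], [], [], [], []
    traits_rows = []

    for j, sp in enumerate(config.species):
        try:
            status, classification = _run_species(
                config, sp, j, iso, region_map, outdir,
                all_calls, all_np, all_curves, all_class, all_rr, all_results,
            )
        except Exception as exc:  # isolation: one species never aborts others
            status, classification = f"failed: {exc}", None
        manifest.species[sp.name] = {
            "status": status,
            "classification": classification,
        }
        if sp.traits:
            traits_rows.append({"species": sp.name, **sp.traits})

    results_dir = outdir / "results"
    if all_calls:
        write_table(results_dir / "calls.csv", pd.concat(all_calls, ignore_index=True))
    if all_np:
        write_table(results_dir / "np.csv", pd.DataFrame(all_np))
    if all_curves:
        write_table(results_dir / "curves.csv", pd.concat(all_curves, ignore_index=True))
    if all_class:
        write_table(results_dir / "classifications.csv", pd.DataFrame(all_class))
    if all_rr:
        write_table(results_dir / "rr.csv", pd.DataFrame(all_rr))
    if traits_rows and all_results:
        traits = pd.DataFrame(traits_rows)
        results = pd.DataFrame(all_results)
        try:
            corr = summarize_correlates(results, traits)
            write_table(results_dir / "correlates.csv", corr)
        except KeyError:
            pass
    for stage in ("assign", "catchment", "fit", "vulnerability", "report"):
        manifest.stages.append(stage)
    _atomic_write_text(outdir / "manifest.json", manifest.to_json())
    return manifest


def _run_species(config, sp, j, iso, region_map, outdir,
                 all_calls, all_np, all_curves, all_class, all_rr, all_results):
    sp_dir = outdir / "species" / sp.name

    # --- step 1: feathers and origin assignment -------------------------
    samples, truth = simulate_feathers(
        sp.name, sp.n_local, sp.n_nonlocal, iso, region_map,
        seed=_stage_seed(config.seed, 1, j),
    )
    write_table(sp_dir / "samples.csv", samples)
    write_table(sp_dir / "samples_truth.csv", truth)  # hidden-truth sidecar

    surfaces, call_rows, calls = [], [], []
    for rec in samples.itertuples():
        surf = assignment_surface(
            rec.d2h_permil, iso, region_map.range_mask,
            sample_id=rec.sample_id, threshold=config.odds_threshold,
            rule=config.or_rule,
        )
        call = classify_origin(surf, region_map.facility_cell, region_map.range_mask)
        surfaces.append(surf)
        calls.append(call)
        call_rows.append(
            {
                "sample_id": call.sample_id,
                "species": sp.name,
                "origin_class": call.origin_class,
                "or_at_facility": call.or_at_facility,
            }
        )
    calls_df = pd.DataFrame(call_rows)
    write_table(sp_dir / "calls.csv", calls_df)
    all_calls.append(calls_df)

    # --- step 2: catchments and Np --------------------------------------
    estimates = generate_population_estimates(
        region_map, sp.bcr_means, cv=config.estimates_cv
    )
    write_table(sp_dir / "estimates.csv", estimates)
    subpops = {}
    for origin_class in ("local", "non-local"):
        agg = aggregate_surface(surfaces, calls, origin_class)
        catchment = delineate_catchment(agg, region_map, origin_class, species=sp.name)
        if catchment is None:
            continue
        try:
            size = subpopulation_size(catchment, estimates, region_map)
        except MissingEstimateError:
            if sp.cp is None:
                raise
            frac = float(catchment.cells.sum()) / float(region_map.range_mask.sum())
            size = continental_fallback(
                sp.cp, frac, species=sp.name, origin_class=origin_class
            )
        subpops[origin_class] = size
        all_np.append(asdict(size))
    if not subpops and sp.cp is not None:
        catchment, size = range_only_catchment(region_map, sp.cp, species=sp.name)
        if size is not None:
            subpops["non-local"] = size
            all_np.append(asdict(size))

    # --- step 3: demographic fit ----------------------------------------
    series = simulate_index_series(
        sp.demography, years=sp.index_years, q_scale=sp.q_scale,
        sigma_obs=sp.sigma_obs, n0_total=sp.n0_total,
        seed=_stage_seed(config.seed, 3, j),
    )
    write_table(sp_dir / "index.csv", series)
    mcmc = MCMCConfig.preset(config.mcmc_preset, seed=_stage_seed(config.seed, 4, j))
    candidates = [
        fit_demographic_model(series, sp.priors, ConstraintLevel(lv), sp.demography.model_spec(), mcmc)
        for lv in config.levels
    ]
    selection = select_model(candidates)
    diag = {
        "species": sp.name,
        "status": selection.status,
        "levels": selection.table.to_dict("records"),
        "warnings": selection.warnings,
    }
    _atomic_write_text(sp_dir / "fit_diagnostics.json", json.dumps(diag, indent=2, sort_keys=True))
    if selection.status == "excluded":
        return "excluded", None
    chosen = selection.chosen
    write_table(sp_dir / "draws.csv", chosen.draws)

    # --- step 4: vulnerability and relative risk ------------------------
    worst = "not vulnerable"
    for origin_class, size in sorted(subpops.items()):
        res = assess_vulnerability(
            chosen, size.np_mean, sp.name, origin_class,
            years=config.scenario_years, iters=config.scenario_iters,
            seed=_stage_seed(config.seed, 5, j),
        )
        curve = res.curve.copy()
        curve.insert(0, "origin_class", origin_class)
        curve.insert(0, "species", sp.name)
        all_curves.append(curve)
        all_class.append(
            {
                "species": sp.name,
                "origin_class": origin_class,
                "classification": res.classification,
                "np_mean": size.np_mean,
                "d_current": res.d_current,
                "lambda_original": res.lambda_original,
            }
        )
        all_results.append(
            {
                "species": sp.name,
                "origin_class": origin_class,
                "classification": res.classification,
                "vulnerability": float(res.curve["vulnerability"].iloc[-1]),
                "np_mean": size.np_mean,
            }
        )
        if _SEVERITY[res.classification] > _SEVERITY[worst]:
            worst = res.classification

    x_local = int((calls_df["origin_class"] == "local").sum())
    x_nonlocal = int((calls_df["origin_class"] == "non-local").sum())
    if "local" in subpops and "non-local" in subpops:
        rr = relative_risk(
            x_local, subpops["local"].np_mean,
            x_nonlocal, subpops["non-local"].np_mean,
            species=sp.name,
        )
        all_rr.append(asdict(rr))

    return "complete", worst
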