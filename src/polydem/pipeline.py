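"""Config-driven pipeline orchestration.

Stages (subcommands): ``simulate`` (synthetic census + truth), ``fit``
(vital-rate model sets + selection tables), ``surface`` (point lambda
surfaces), ``bootstrap`` (parametric-bootstrap ensembles + CIs), ``classify``
(polymorphism map, contributions, ambient overlay) and ``all``. Every stage
is a pure function of the config, so identical configs reproduce identical
artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .exceptions import ConfigError
from .kernel import make_mesh
from .selection import classify_cells, contribution_table, overlay_ambient
from .serialize import (load_modelset, modelset_to_dict, recruitment_to_dict,
                        save_modelset)
from .surface import bootstrap_ensemble, evaluate_surface, make_grid
from .synthetic import (GenotypeTruth, default_truth, read_census,
                        simulate_census, simulate_environment, write_census)
from .vital_rates import (RATE_KEYS, fit_genotype_modelset, predict_rate)

log = logging.getLogger("polydem")

MODES = ("simulate", "fit", "surface", "bootstrap", "classify", "all")


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticConfig(_Base):
    seed: int
    n_plants: int = 800
    n_years: int = 4
    n_blocks: int = 40
    moisture_range: tuple[float, float] = (4.0, 20.0)
    herbivory_dispersion: float = 8.0
    moisture_herbivory_corr: float = -0.4
    truth: Literal["default"] = "default"


class GridConfig(_Base):
    n_bins: int = 25
    max_obs_moisture: Optional[float] = None   # None -> from data
    herbivory_floor: float = 0.5


class MeshConfig(_Base):
    m: int = 100
    pad: Optional[float] = None                # None -> 3 x max growth SD


class BootstrapConfig(_Base):
    B: int = 1000
    seed: int


class RecruitmentConfig(_Base):
    germination: float
    seedbank_survival: float
    germinant_survival: float
    recruit_size_mean: float
    recruit_size_sd: float


class RunConfig(_Base):
    output_dir: str
    census_path: Optional[str] = None          # defaults to simulate output
    synthetic: Optional[SyntheticConfig] = None
    # per-genotype recruitment constants; None -> bundled truth values
    recruitment: Optional[dict[str, RecruitmentConfig]] = None
    grid: GridConfig = GridConfig()
    mesh: MeshConfig = MeshConfig()
    bootstrap: BootstrapConfig
    genotypes: tuple[str, str] = ("BB", "MM")


def load_config(path) -> RunConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _truth(config: RunConfig) -> dict[str, GenotypeTruth]:
    return default_truth()


def _default_pad(modelsets: dict, data: pd.DataFrame) -> float:
    """3 x the largest fitted growth SD over the observed census conditions."""
    z = data["size_t"].dropna().to_numpy(float)
    E = (data["moisture_t"].to_numpy(float)[: len(z)],
         data["herbivory_t"].to_numpy(float)[: len(z)])
    max_var = 0.0
    for ms in modelsets.values():
        for key in ("v00", "v01", "v10", "v11"):
            max_var = max(max_var, float(np.max(predict_rate(ms.fits[key], z, E))))
    return 3.0 * float(np.sqrt(max_var))


def _grid_and_mesh(config: RunConfig, modelsets: dict, census: pd.DataFrame):
    max_m = config.grid.max_obs_moisture
    if max_m is None:
        max_m = float(census["moisture_t"].max())
    grid = make_grid(max_m, config.grid.n_bins, config.grid.herbivory_floor)
    sizes = pd.concat([census["size_t"], census["size_t1"]]).dropna()
    pad = config.mesh.pad
    if pad is None:
        pad = _default_pad(modelsets, census)
    mesh = make_mesh(float(sizes.min()), float(sizes.max()),
                     m=config.mesh.m, pad=pad)
    return grid, mesh


def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(config: RunConfig) -> dict:
    if config.synthetic is None:
        raise ConfigError("mode 'simulate' requires a 'synthetic' block")
    sc = config.synthetic
    out = _outdir(config)
    truth = _truth(config)
    env = simulate_environment(
        n_blocks=sc.n_blocks, years=sc.n_years,
        moisture_range=sc.moisture_range,
        herbivory_dispersion=sc.herbivory_dispersion,
        moisture_herbivory_corr=sc.moisture_herbivory_corr, seed=sc.seed)
    census = simulate_census(truth, env, n_plants=sc.n_plants,
                             n_years=sc.n_years, seed=sc.seed + 1)
    write_census(census, out / "census.csv")
    env.table.to_csv(out / "environment.csv", index=False)
    truth_doc = {g: {"coefs": t.coefs, "seed_sd": t.seed_sd,
                     "recruitment": recruitment_to_dict(t.recruitment)}
                 for g, t in truth.items()}
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    log.info("simulate: %d census rows -> %s", len(census), out / "census.csv")
    return {"census": census, "env": env, "truth": truth}


def _load_census(config: RunConfig):
    path = config.census_path or str(Path(config.output_dir) / "census.csv")
    return read_census(path)


def stage_fit(config: RunConfig, census=None) -> dict:
    out = _outdir(config)
    if census is None:
        census = _load_census(config)
    truth = _truth(config)
    modelsets, tables = {}, []
    for g in config.genotypes:
        if config.recruitment is not None:
            from .vital_rates import RecruitmentConstants
            rec = RecruitmentConstants(**config.recruitment[g].model_dump())
        else:
            rec = truth[g].recruitment
        ms = fit_genotype_modelset(census, g, rec)
        modelsets[g] = ms
        save_modelset(ms, out / f"modelset_{g}.json")
        for key in RATE_KEYS:
            tab = ms.fits[key].selection_table
            if tab is not None:
                tab = tab.assign(genotype=g, vital_rate=key)
                tables.append(tab)
        log.info("fit: genotype %s, selected terms: %s", g,
                 {k: "+".join(ms.fits[k].terms) or "1" for k in RATE_KEYS})
    pd.concat(tables, ignore_index=True).to_csv(
        out / "selection_tables.csv", index=False)
    return {"census": census, "modelsets": modelsets}


def _load_modelsets(config: RunConfig) -> dict:
    out = Path(config.output_dir)
    return {g: load_modelset(out / f"modelset_{g}.json")
            for g in config.genotypes}


def stage_surface(config: RunConfig, census=None, modelsets=None) -> dict:
    out = _outdir(config)
    if census is None:
        census = _load_census(config)
    if modelsets is None:
        modelsets = _load_modelsets(config)
    grid, mesh = _grid_and_mesh(config, modelsets, census)
    surfaces = {g: evaluate_surface(ms, grid, mesh)
                for g, ms in modelsets.items()}
    pd.concat([s.as_frame() for s in surfaces.values()],
              ignore_index=True).to_csv(out / "lambda_surfaces.csv", index=False)
    log.info("surface: lambda ranges %s",
             {g: (round(float(s.values.min()), 3),
                  round(float(s.values.max()), 3))
              for g, s in surfaces.items()})
    return {"census": census, "modelsets": modelsets, "grid": grid,
            "mesh": mesh, "surfaces": surfaces}


def stage_bootstrap(config: RunConfig, **state) -> dict:
    out = _outdir(config)
    state = state or stage_surface(config)
    grid, mesh = state["grid"], state["mesh"]
    ensembles, long_rows = {}, []
    for i, (g, ms) in enumerate(state["modelsets"].items()):
        ens = bootstrap_ensemble(ms, grid, mesh, B=config.bootstrap.B,
                                 seed=config.bootstrap.seed + i)
        ensembles[g] = ens
        M, H = grid.cells()
        B, n = ens.draws.shape
        long_rows.append(pd.DataFrame({
            "genotype": g,
            "replicate": np.repeat(np.arange(B), n),
            "moisture": np.tile(M, B), "herbivory": np.tile(H, B),
            "lam": ens.draws.ravel()}))
    pd.concat([e.summary_frame() for e in ensembles.values()],
              ignore_index=True).to_csv(out / "lambda_percentiles.csv",
                                        index=False)
    pd.concat(long_rows, ignore_index=True).to_csv(
        out / "lambda_draws.csv", index=False, float_format="%.17g")
    state["ensembles"] = ensembles
    return state


def _load_ensembles(config: RunConfig, grid) -> dict | None:
    """Rebuild bootstrap ensembles from the long-format draws export."""
    path = Path(config.output_dir) / "lambda_draws.csv"
    if not path.exists():
        return None
    from .surface import BootstrapEnsemble

    long = pd.read_csv(path, float_precision="round_trip")
    ensembles = {}
    for g, sub in long.groupby("genotype", sort=False):
        B = sub["replicate"].nunique()
        draws = sub["lam"].to_numpy().reshape(B, grid.n_cells)
        ensembles[g] = BootstrapEnsemble(genotype=g, grid=grid, draws=draws,
                                         seed=config.bootstrap.seed)
    return ensembles


def stage_classify(config: RunConfig, **state) -> dict:
    out = _outdir(config)
    if not state:
        state = stage_surface(config)
        cached = _load_ensembles(config, state["grid"])
        if cached is not None and all(e.B == config.bootstrap.B
                                      for e in cached.values()):
            log.info("classify: reusing bootstrap draws from %s",
                     out / "lambda_draws.csv")
            state["ensembles"] = cached
        else:
            state = stage_bootstrap(config, **state)
    census = state["census"]
    g_bb, g_mm = config.genotypes
    pmap = classify_cells(state["ensembles"][g_mm], state["ensembles"][g_bb])
    pmap.as_frame().to_csv(out / "polymorphism_map.csv", index=False)
    refs = {"moisture": float(census["moisture_t"].mean()),
            "herbivory": float(census["herbivory_t"].mean())}
    contrib = contribution_table(state["modelsets"], state["grid"],
                                 state["mesh"], refs)
    contrib.to_csv(out / "contributions.csv", index=False)
    ambient = (census.groupby("year")
               .agg(moisture_mean=("moisture_t", "mean"),
                    moisture_sd=("moisture_t", "std"),
                    herbivory_mean=("herbivory_t", "mean"),
                    herbivory_sd=("herbivory_t", "std"))
               .reset_index().to_dict("records"))
    overlay = overlay_ambient(pmap, ambient)
    overlay.to_csv(out / "ambient_overlay.csv", index=False)
    summary = {"fractions": pmap.fractions,
               "references": refs,
               "ambient_inside_polymorphic":
                   overlay["inside_polymorphic"].astype(bool).tolist()}
    (out / "classification_summary.json").write_text(
        json.dumps(summary, indent=1))
    log.info("classify: fractions %s", pmap.fractions)
    state.update({"pmap": pmap, "contributions": contrib, "overlay": overlay})
    return state


def run(config: RunConfig, mode: str = "all") -> dict:
    """Run one stage (or the whole pipeline) and write its artifacts."""
    if mode not in MODES:
        raise ConfigError(f"unknown mode {mode!r}; expected one of {MODES}")
    out = _outdir(config)
    state: dict = {}
    if mode == "simulate":
        state = stage_simulate(config)
    elif mode == "fit":
        state = stage_fit(config)
    elif mode == "surface":
        state = stage_surface(config)
    elif mode == "bootstrap":
        state = stage_bootstrap(config)
    elif mode == "classify":
        state = stage_classify(config)
    else:  # all
        sim = stage_simulate(config)
        state = stage_fit(config, census=sim["census"])
        state = stage_surface(config, census=state["census"],
                              modelsets=state["modelsets"])
        state = stage_bootstrap(config, **state)
        state = stage_classify(config, **state)
    meta = {"version": __version__, "mode": mode,
            "config_hash": _config_hash(config),
            "config": config.model_dump(),
            "seeds": {"synthetic": (config.synthetic.seed
                                    if config.synthetic else None),
                      "bootstrap": config.bootstrap.seed}}
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=1,
                                                      default=str))
    return state
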