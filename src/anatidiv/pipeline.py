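"""End-to-end orchestration: simulate -> dendrogram -> diversity -> nulls ->
regions -> per-hemisphere driver models, with a reproducibility manifest.

Every stage is a pure function of (inputs, config, seed); the manifest
records the config snapshot and SHA-256 digests of all written tables so a
re-run can be checked for byte identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .diversity import diversity_map
from .env_drivers import (
    fit_driver_model,
    morans_i,
    ndvi_summary_table,
    vif_screen,
)
from .io_formats import (
    CommunityGrid,
    EnvTable,
    read_community_grid,
    read_newick_ensemble,
    read_trait_table,
    write_community_grid,
    write_env_table,
    write_newick_ensemble,
    write_trait_table,
)
from .null_models import run_null_analysis
from .regionalization import delineate_regions
from .synthetic import default_trait_schema, two_hemisphere_demo
from .trait_space import build_functional_dendrogram

log = logging.getLogger("anatidiv")

__all__ = ["PipelineError", "demo_config", "run_pipeline", "load_inputs", "simulate_inputs"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def demo_config(seed: int = 0) -> RunConfig:
    """Configuration of the miniature two-hemisphere study.

    Scaled to desk size: a 60-species pool, 10-tree ensemble, 199 null
    replicates (cutoffs 5 / 195, the same 5% two-sided rate as 25 / 975 of
    999), 4 faunal groups, and 300-tree forests.
    """
    return RunConfig(
        seed=seed,
        null_replicates=199,
        q_low=5,
        q_high=195,
        ensemble_size=10,
        k_groups=4,
        forest_trees=300,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2fs", stage, time.perf_counter() - self.t0)
            return False

    return _T()


def simulate_inputs(config: RunConfig, outdir: Path, **demo_kwargs):
    """Generate and write the four demo input files plus a ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with _timed("simulate"):
        demo = two_hemisphere_demo(seed=config.seed, n_trees=config.ensemble_size, **demo_kwargs)
        write_newick_ensemble(demo.trees, outdir / "trees.nwk")
        write_trait_table(demo.traits, outdir / "traits.csv")
        write_community_grid(demo.grid, outdir / "communities.csv")
        env_full = pd.concat(
            [
                demo.environment.env.data,
                ndvi_summary_table(demo.environment.ndvi, "NDVI"),
                ndvi_summary_table(demo.environment.aet, "AET"),
            ],
            axis=1,
        )
        families = dict(demo.environment.env.families)
        for c in env_full.columns:
            families.setdefault(c, "productivity")
        write_env_table(EnvTable(env_full, families), outdir / "environment.csv")
        sidecar = dict(demo.truth)
        sidecar["exhausted_cells"] = sorted(demo.exhausted.index[demo.exhausted])
        (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return demo


def load_inputs(indir: Path):
    indir = Path(indir)
    schema = default_trait_schema()
    try:
        trees = read_newick_ensemble(indir / "trees.nwk")
    except FileNotFoundError as exc:
        raise PipelineError("inputs", f"tree file missing: {exc}") from exc
    try:
        traits = read_trait_table(indir / "traits.csv", schema)
    except FileNotFoundError as exc:
        raise PipelineError("trait_space", f"trait file missing: {exc}") from exc
    try:
        grid = read_community_grid(indir / "communities.csv")
    except FileNotFoundError as exc:
        raise PipelineError("diversity", f"community file missing: {exc}") from exc
    try:
        env = pd.read_csv(indir / "environment.csv", index_col=0)
    except FileNotFoundError as exc:
        raise PipelineError("env_drivers", f"environment file missing: {exc}") from exc
    return trees, traits, grid, EnvTable(env, {})


@dataclass
class RunManifest:
    config: RunConfig
    digests: dict[str, str]
    version: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": json.loads(self.config.to_json()),
                "digests": self.digests,
                "version": self.version,
            },
            indent=2,
            sort_keys=True,
        )


def run_pipeline(config: RunConfig, outdir, indir=None, **demo_kwargs) -> RunManifest:
    """Run every stage; simulate inputs when no input directory is given.

    Writes all stage tables under ``outdir`` and returns the manifest
    (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if indir is None:
        simulate_inputs(config, outdir / "inputs", **demo_kwargs)
        indir = outdir / "inputs"
    trees, traits, grid, env = load_inputs(indir)

    with _timed("trait_space"):
        try:
            dendro = build_functional_dendrogram(traits, log_transform=config.log_transform_traits)
        except Exception as exc:
            raise PipelineError("trait_space", str(exc)) from exc
        (outdir / "functional_dendrogram.nwk").write_text(dendro.to_newick() + "\n")

    with _timed("diversity"):
        try:
            div = diversity_map(grid, trees, dendro, convention=config.pd_convention)
        except Exception as exc:
            raise PipelineError("diversity", str(exc)) from exc
        div.to_csv(outdir / "diversity.csv")

    with _timed("null_models"):
        try:
            nulls = run_null_analysis(grid, trees, dendro, config)
        except Exception as exc:
            raise PipelineError("null_models", str(exc)) from exc
        nulls.to_csv(outdir / "null_summary.csv")

    with _timed("regionalization"):
        try:
            regions = delineate_regions(
                grid,
                drop_species=config.drop_species,
                min_richness=config.min_richness,
                k=config.k_groups,
                k_max=config.k_max,
            )
        except Exception as exc:
            raise PipelineError("regionalization", str(exc)) from exc
        regions.table().to_csv(outdir / "regions.csv")
        regions.curve.to_csv(outdir / "region_curve.csv", index=False)

    with _timed("env_drivers"):
        try:
            tables = _driver_stage(config, div, env, regions)
        except Exception as exc:
            raise PipelineError("env_drivers", str(exc)) from exc
        for name, tab in tables.items():
            tab.to_csv(outdir / f"{name}.csv", index=False)

    digests = {
        p.name: _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.suffix in (".csv", ".nwk", ".json") and p.name != "manifest.json"
    }
    manifest = RunManifest(config=config, digests=digests, version=__version__)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _driver_stage(config: RunConfig, div: pd.DataFrame, env: EnvTable, regions) -> dict[str, pd.DataFrame]:
    """VIF screen, Moran's I, and one forest per hemisphere x diversity index."""
    retained_cells = regions.table().index
    div_r = div.loc[retained_cells]
    X_env = env.data.loc[retained_cells]
    retained, trace = vif_screen(X_env, threshold=config.vif_threshold)

    moran_rows = []
    rng = config.rng("moran")
    for resp in ("TD", "FD", "PD"):
        i_stat, p = morans_i(
            div_r[resp].to_numpy(float),
            div_r["lat"].to_numpy(float),
            div_r["lon"].to_numpy(float),
            rng=rng,
        )
        moran_rows.append((resp, i_stat, p))

    if config.hemisphere_rule == "regions":
        hemi = regions.hemisphere
    else:
        # cell-latitude rule: robust when community composition carries no
        # geographic signal (synthetic species have no range cohesion)
        hemi = pd.Series(
            np.where(div_r["lat"] >= 0, "north", "south"), index=retained_cells
        )
    model_rows, imp_rows, md_rows, pd_rows = [], [], [], []
    for hname in ("north", "south"):
        cells = hemi.index[hemi == hname]
        if len(cells) < 20:
            log.warning("hemisphere %s has only %d cells; skipped", hname, len(cells))
            continue
        X = pd.concat([X_env.loc[cells, retained], div_r.loc[cells, ["lat", "lon"]]], axis=1)
        for resp in ("TD", "FD", "PD"):
            model = fit_driver_model(
                div_r.loc[cells, resp],
                X,
                response=resp,
                hemisphere=hname,
                n_trees=config.forest_trees,
                mtry=config.mtry,
                seed=config.child_seed(f"forest-{hname}-{resp}"),
            )
            model_rows.append(
                (hname, resp, len(cells), len(retained), model.var_explained)
            )
            imp = model.importance()
            for pred, score in imp.items():
                imp_rows.append((hname, resp, pred, score))
            for pred, depth in model.minimal_depth_.sort_values().items():
                md_rows.append((hname, resp, pred, depth))
            for pred in model.top_predictors(5):
                curve = model.partial_dependence(pred, grid_size=config.pd_grid)
                for _, row in curve.iterrows():
                    pd_rows.append((hname, resp, pred, row["x"], row["partial"], row["se"]))
    return {
        "vif_trace": trace,
        "morans_i": pd.DataFrame(moran_rows, columns=["response", "I", "p"]),
        "driver_models": pd.DataFrame(
            model_rows, columns=["hemisphere", "response", "n_cells", "n_predictors", "oob_var_explained_pct"]
        ),
        "driver_importance": pd.DataFrame(
            imp_rows, columns=["hemisphere", "response", "predictor", "importance"]
        ),
        "driver_minimal_depth": pd.DataFrame(
            md_rows, columns=["hemisphere", "response", "predictor", "mean_minimal_depth"]
        ),
        "driver_partial_dependence": pd.DataFrame(
            pd_rows, columns=["hemisphere", "response", "predictor", "x", "partial", "se"]
        ),
    }
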