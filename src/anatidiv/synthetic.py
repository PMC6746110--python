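"""Synthetic study inputs with known ground truth.

Generates every input the pipeline consumes: birth-death tree ensembles,
mixed-type trait tables evolved on the first tree, a gridded environment
(bioclim-style climate fields, a dekadal vegetation-index stack consistent
with its target seasonality/peak fields, hydrogeomorphology columns, and
deliberately collinear predictors to exercise the VIF screen), and
communities assembled under one of three processes:

* ``neutral`` -- uniform random species subsets of the drawn richness;
* ``filtering`` -- species admitted with probability proportional to a
  Gaussian kernel between a designated niche trait and the cell's linked
  predictor (clusters communities in trait/phylogeny space);
* ``limiting-similarity`` -- sequential admission rejecting candidates
  within a Gower-distance radius of any resident (overdisperses them).

The two-hemisphere demo couples a strong seasonality gradient + filtering
in the northern half with a damped gradient + limiting similarity in the
southern half, a miniature of the contrast the pipeline is built to detect.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .config import substream, substream_seed
from .env_drivers import NDVIStack
from .io_formats import CommunityGrid, EnvTable, TraitSchema, TraitTable
from .trees import PhyloTree, TreeEnsemble

__all__ = [
    "default_trait_schema",
    "simulate_tree_ensemble",
    "simulate_bd_lineage_count",
    "simulate_traits",
    "SyntheticEnvironment",
    "simulate_environment",
    "AssemblyScenario",
    "assemble_communities",
    "DemoInputs",
    "two_hemisphere_demo",
]


def default_trait_schema() -> TraitSchema:
    """Fourteen mixed-type traits: 4 continuous, two percentage groups, 3 binary."""
    kinds = {
        "body_mass": "continuous",
        "wingspan": "continuous",
        "clutch_size": "continuous",
        "distribution_area": "continuous",
        "diet_invertebrates": "percentage",
        "diet_vertebrates": "percentage",
        "diet_fish": "percentage",
        "diet_plants": "percentage",
        "forage_surface": "percentage",
        "forage_underwater": "percentage",
        "forage_land": "percentage",
        "migratory": "binary",
        "nocturnal": "binary",
        "cavity_nesting": "binary",
    }
    groups = {
        "diet": ["diet_invertebrates", "diet_vertebrates", "diet_fish", "diet_plants"],
        "foraging": ["forage_surface", "forage_underwater", "forage_land"],
    }
    return TraitSchema(kinds, groups)


# ---------------------------------------------------------------------------
# trees


def _species_labels(n: int) -> list[str]:
    return [f"sp{i + 1:03d}" for i in range(n)]


def simulate_tree_ensemble(
    n_tips: int,
    n_trees: int,
    model: str = "yule",
    birth: float = 1.0,
    death: float = 0.0,
    seed: int = 0,
    normalize_depth: bool = True,
) -> TreeEnsemble:
    """Independent birth-death trees conditioned on the extant tip count.

    ``model="yule"`` forces the death rate to 0.  Tip labels sp001..spNNN
    are assigned in each tree's own leaf order, so the association between
    species and tree position varies across the ensemble, as it does across
    posterior tree samples.  With ``normalize_depth`` every tree is rescaled
    to unit root-to-tip depth, mimicking dated trees that share a common
    time scale; without it, independently simulated trees differ wildly in
    total length.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if model == "yule":
        death = 0.0
    elif model != "birth-death":
        raise ValueError(f"unknown model {model!r}")
    if death >= birth:
        raise ValueError(f"death rate {death} must be below birth rate {birth}")
    from dendropy.model import birthdeath

    labels = _species_labels(n_tips)
    trees = []
    for k in range(n_trees):
        rng = _random.Random(substream_seed(seed, f"tree-{k}"))
        dtree = birthdeath.birth_death_tree(
            birth_rate=birth,
            death_rate=death,
            num_extant_tips=n_tips,
            rng=rng,
        )
        pt = PhyloTree.from_dendropy(dtree)
        if normalize_depth:
            depth = 0.0
            v = 0  # any tip; extant trees are ultrametric
            while v != -1:
                depth += pt.length[v]
                v = pt.parent[v]
            pt = PhyloTree(pt.parent, pt.length / depth, pt.tip_labels)
        trees.append(pt.relabeled(labels))
    return TreeEnsemble(trees)


def simulate_bd_lineage_count(birth: float, death: float, t: float, rng: np.random.Generator) -> int:
    """Lineage count at time t of an unconditioned birth-death process from 1 lineage."""
    n, now = 1, 0.0
    while n > 0:
        now += rng.exponential(1.0 / (n * (birth + death))) if (birth + death) > 0 else np.inf
        if now >= t:
            break
        if rng.random() < birth / (birth + death):
            n += 1
        else:
            n -= 1
    return n


# ---------------------------------------------------------------------------
# traits


def simulate_traits(
    tree: PhyloTree,
    schema: TraitSchema | None = None,
    seed: int = 0,
    rate: float | dict[str, float] = 1.0,
) -> TraitTable:
    """Trait evolution by Brownian motion along the tree.

    Continuous traits are the Brownian tip values (variance ``rate x depth``
    around the root state); ``rate`` may be a scalar or a per-trait dict.
    Binary traits threshold a Brownian liability at its root value.  Each
    percentage group evolves one liability per category and maps them
    through a softmax scaled to 100, so compositions sum to 100 by
    construction.
    """
    schema = schema or default_trait_schema()
    rng = substream(seed, "traits")
    n_lia = len(schema.kinds)
    if isinstance(rate, dict):
        rates = np.array([rate.get(t, 1.0) for t in schema.kinds])
    else:
        rates = np.full(n_lia, float(rate))
    children: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    for i, p in enumerate(tree.parent):
        if p >= 0:
            children[p].append(i)
    vals = np.zeros((tree.n_nodes, n_lia))
    stack = [tree.root]
    order = []
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(children[v])
    for v in order:
        p = tree.parent[v]
        if p >= 0:
            vals[v] = vals[p] + rng.normal(0.0, 1.0, n_lia) * np.sqrt(rates * max(tree.length[v], 0.0))
    tip_vals = vals[: tree.n_tips]
    data = {}
    grouped = {c for cols in schema.percentage_groups.values() for c in cols}
    for j, (trait, kind) in enumerate(schema.kinds.items()):
        x = tip_vals[:, j]
        if kind == "continuous":
            data[trait] = x
        elif kind == "binary":
            data[trait] = (x > 0).astype(float)
        elif trait not in grouped:
            data[trait] = 50.0 + 50.0 * np.tanh(x)  # lone percentage trait
    cols = list(schema.kinds)
    for group, members in schema.percentage_groups.items():
        idx = [cols.index(m) for m in members]
        lia = tip_vals[:, idx]
        ex = np.exp(lia - lia.max(axis=1, keepdims=True))
        comp = 100.0 * ex / ex.sum(axis=1, keepdims=True)
        for m, col in zip(members, comp.T):
            data[m] = col
    df = pd.DataFrame(data, index=tree.tip_labels)[cols]
    return TraitTable(df, schema)


# ---------------------------------------------------------------------------
# environment


@dataclass
class SyntheticEnvironment:
    cells: pd.DataFrame                 # index cell_id; lat, lon
    env: EnvTable                       # climate + hydro predictors (no NDVI summaries)
    ndvi: NDVIStack
    aet: NDVIStack
    truth: dict = field(default_factory=dict)


def simulate_environment(
    n_lat: int = 20,
    n_lon: int = 15,
    seed: int = 0,
    pixels: int = 5,
    years: int = 10,
    dekads: int = 36,
    lat_range: tuple[float, float] = (-55.0, 70.0),
    plant_collinear: bool = True,
) -> SyntheticEnvironment:
    """Gridded environment with the study's qualitative latitudinal structure.

    Seasonality rises steeply with latitude in the northern half and only
    weakly in the southern half; peak productivity is unimodal in latitude.
    The dekadal NDVI stack is built so that the summary operators recover
    these target fields (cosine annual cycle with amplitude set from the
    target within-year SD, per-pixel baseline jitter for spatial
    heterogeneity, per-year offsets for interannual variation).  With
    ``plant_collinear`` an exact duplicate and a near-linear combination
    are appended to exercise the VIF screen.
    """
    if n_lat < 3 or n_lon < 3:
        raise ValueError("grid must be at least 3x3")
    rng = substream(seed, "environment")
    lat_centers = np.linspace(lat_range[0], lat_range[1], n_lat)
    lon_centers = np.linspace(-170.0, 170.0, n_lon)
    lat = np.repeat(lat_centers, n_lon)
    lon = np.tile(lon_centers, n_lat)
    n = n_lat * n_lon
    cell_ids = [f"c{i + 1:04d}" for i in range(n)]
    cells = pd.DataFrame({"lat": lat, "lon": lon}, index=pd.Index(cell_ids, name="cell_id"))

    north = lat >= 0
    season = np.where(
        north,
        0.04 + 0.22 * (np.abs(lat) / 70.0),
        0.04 + 0.05 * (np.abs(lat) / 55.0),
    ) + rng.normal(0, 0.004, n)
    season = np.clip(season, 0.01, 0.35)
    peak = 0.15 + 0.6 * np.exp(-((lat / 35.0) ** 2)) + rng.normal(0, 0.01, n)
    peak = np.clip(peak, 0.05, 0.92)

    # dekadal stack consistent with the target fields
    amp = season * np.sqrt(2.0)
    base = peak - amp * np.cos(0.05 * np.pi)   # 95th pct of a cosine cycle
    phase = rng.uniform(0, dekads, n)
    d_axis = np.arange(dekads)
    stack = np.empty((n, pixels, pixels, years, dekads))
    for c in range(n):
        px_base = base[c] + rng.normal(0, 0.02, (pixels, pixels))
        yr_off = rng.normal(0, 0.01, years)
        cyc = amp[c] * np.cos(2 * np.pi * (d_axis - phase[c]) / dekads)
        series = (
            px_base[:, :, None, None]
            + yr_off[None, None, :, None]
            + cyc[None, None, None, :]
            + rng.normal(0, 0.003, (pixels, pixels, years, dekads))
        )
        stack[c] = np.clip(series, -1.0, 1.0)
    ndvi = NDVIStack(stack, cell_ids)

    # AET-like stack: same generative recipe on a drier field, scaled to [0, 1]
    aet_peak = np.clip(0.2 + 0.5 * np.exp(-(((lat - 10) / 40.0) ** 2)) + rng.normal(0, 0.01, n), 0.05, 0.9)
    aet_season = np.clip(0.5 * season + rng.normal(0, 0.003, n), 0.005, 0.3)
    aet_stack = np.empty_like(stack)
    for c in range(n):
        a = aet_season[c] * np.sqrt(2.0)
        px_base = aet_peak[c] - a * np.cos(0.05 * np.pi) + rng.normal(0, 0.02, (pixels, pixels))
        cyc = a * np.cos(2 * np.pi * (d_axis - phase[c]) / dekads)
        aet_stack[c] = np.clip(
            px_base[:, :, None, None]
            + rng.normal(0, 0.008, (pixels, pixels, years, 1))
            + cyc[None, None, None, :],
            0.0, 1.0,
        )
    aet = NDVIStack(aet_stack, cell_ids)

    env_cols = {}
    fam = {}
    # bioclim-style means and within-cell SDs with known cross-correlations
    t_mean = 26.0 - 0.42 * np.abs(lat) + rng.normal(0, 1.0, n)
    env_cols["mn.Bio01"] = t_mean
    env_cols["mn.Bio11"] = t_mean - 8.0 - 0.15 * np.abs(lat) + rng.normal(0, 1.0, n)
    env_cols["mn.Bio04"] = 2.0 + 9.0 * (np.abs(lat) / 70.0) + rng.normal(0, 0.5, n)
    env_cols["mn.Bio12"] = 600 + 1400 * np.exp(-((lat / 25.0) ** 2)) + rng.normal(0, 60, n)
    env_cols["mn.Bio15"] = 20 + 60 * rng.random(n)
    env_cols["sd.Bio01"] = 0.5 + 0.15 * env_cols["mn.Bio04"] + rng.normal(0, 0.2, n)
    env_cols["sd.Bio12"] = 0.1 * env_cols["mn.Bio12"] + rng.normal(0, 15, n)
    for name in ("mn.Bio01", "mn.Bio11", "mn.Bio04", "mn.Bio12", "mn.Bio15"):
        fam[name] = "climate-mean"
    for name in ("sd.Bio01", "sd.Bio12"):
        fam[name] = "climate-heterogeneity"
    # hydrogeomorphology
    env_cols["Distance.w"] = rng.lognormal(2.0, 0.8, n)
    env_cols["Lake.den"] = np.clip(rng.exponential(3.0, n), 0, 60)
    env_cols["Wetland.den"] = np.clip(rng.exponential(5.0, n), 0, 80)
    env_cols["runoff"] = rng.lognormal(4.0, 1.0, n)
    env_cols["irrigation"] = np.clip(rng.exponential(2.0, n), 0, 50)
    for name in ("Distance.w", "Lake.den", "Wetland.den", "runoff", "irrigation"):
        fam[name] = "hydrogeomorphology"
    if plant_collinear:
        env_cols["dup.Bio01"] = env_cols["mn.Bio01"].copy()
        env_cols["combo.Bio"] = (
            env_cols["mn.Bio01"] + 0.01 * env_cols["mn.Bio12"] + rng.normal(0, 1e-3, n)
        )
        fam["dup.Bio01"] = "climate-mean"
        fam["combo.Bio"] = "climate-mean"
    env = EnvTable(pd.DataFrame(env_cols, index=cells.index), fam)
    truth = {
        "season_field": pd.Series(season, index=cells.index),
        "peak_field": pd.Series(peak, index=cells.index),
        "planted_collinear": ["dup.Bio01", "combo.Bio"] if plant_collinear else [],
    }
    return SyntheticEnvironment(cells, env, ndvi, aet, truth)


# ---------------------------------------------------------------------------
# community assembly


@dataclass
class AssemblyScenario:
    """Parameters of one community-assembly process."""

    mode: str = "neutral"               # neutral | filtering | limiting-similarity
    richness_mean: float = 10.0
    sigma: float = 0.5                  # filtering kernel width, trait-SD units
    delta: float = 0.25                 # limiting-similarity radius, Gower units
    niche_trait: str = "body_mass"
    env_predictor: str | None = None    # column of the env values passed in
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("neutral", "filtering", "limiting-similarity"):
            raise ValueError(f"unknown assembly mode {self.mode!r}")
        if self.mode == "filtering" and self.sigma <= 0:
            raise ValueError("filtering requires sigma > 0")
        if self.mode == "limiting-similarity" and not (0 < self.delta < 1):
            raise ValueError("limiting similarity requires 0 < delta < 1")


def assemble_communities(
    traits: TraitTable,
    cells: pd.DataFrame,
    scenario: AssemblyScenario,
    env_values: pd.Series | None = None,
    gower_distance: pd.DataFrame | None = None,
    richness: pd.Series | None = None,
) -> tuple[CommunityGrid, pd.Series]:
    """Assemble one community per cell; returns (grid, exhausted-flags).

    Richness per cell is 1 + Poisson(mean - 1) truncated at the pool size
    unless an explicit richness series is given.  Filtering standardizes
    both the niche trait and the linked predictor to z-scores before the
    Gaussian kernel, so sigma is in trait-SD units.  Limiting similarity
    admits candidates in random order, rejecting any within Gower distance
    delta of a resident; cells that exhaust the pool early are flagged.
    """
    rng = substream(scenario.seed, f"assembly-{scenario.mode}")
    pool = np.array(traits.species)
    n_pool = len(pool)
    if richness is None:
        lam = max(scenario.richness_mean - 1.0, 0.0)
        richness = pd.Series(
            1 + rng.poisson(lam, len(cells.index)), index=cells.index
        ).clip(upper=n_pool)
    richness = richness.clip(1, n_pool).astype(int)

    if scenario.mode == "filtering":
        if env_values is None:
            raise ValueError("filtering assembly needs env_values")
        z = traits.data[scenario.niche_trait].to_numpy(float)
        zs = (z - z.mean()) / z.std()
        e = env_values.reindex(cells.index).to_numpy(float)
        es = (e - e.mean()) / e.std()
    if scenario.mode == "limiting-similarity":
        if gower_distance is None:
            raise ValueError("limiting-similarity assembly needs a Gower distance matrix")
        Dm = gower_distance.loc[pool, pool].to_numpy(float)

    presence = np.zeros((len(cells.index), n_pool), dtype=np.int8)
    exhausted = pd.Series(False, index=cells.index)
    for i, cid in enumerate(cells.index):
        r = int(richness.loc[cid])
        if scenario.mode == "neutral":
            chosen = rng.choice(n_pool, size=r, replace=False)
        elif scenario.mode == "filtering":
            d2 = (zs - es[i]) ** 2
            logw = -d2 / (2.0 * scenario.sigma**2)
            w = np.exp(logw - logw.max())
            if int((w > 0).sum()) < r:
                # sigma -> 0 limit: kernel underflows; take the nearest traits
                chosen = np.argsort(d2, kind="stable")[:r]
            else:
                chosen = rng.choice(n_pool, size=r, replace=False, p=w / w.sum())
        else:
            order = rng.permutation(n_pool)
            residents: list[int] = []
            for cand in order:
                if not residents or Dm[cand, residents].min() >= scenario.delta:
                    residents.append(int(cand))
                    if len(residents) == r:
                        break
            if len(residents) < r:
                exhausted.loc[cid] = True
            chosen = np.array(residents, dtype=int)
        presence[i, chosen] = 1
    grid = CommunityGrid(
        cells.copy(),
        pd.DataFrame(presence, index=cells.index, columns=list(pool)),
    )
    return grid, exhausted


# ---------------------------------------------------------------------------
# the two-hemisphere demo


@dataclass
class DemoInputs:
    trees: TreeEnsemble
    traits: TraitTable
    environment: SyntheticEnvironment
    grid: CommunityGrid
    exhausted: pd.Series
    truth: dict


def two_hemisphere_demo(
    seed: int = 0,
    n_species: int = 60,
    n_trees: int = 10,
    n_lat: int = 20,
    n_lon: int = 15,
    richness_mean_north: float = 16.0,
    richness_mean_south: float = 9.0,
    sigma: float = 0.4,
    delta: float = 0.22,
) -> DemoInputs:
    """The default miniature study: filtering in the north, limiting
    similarity in the south, seasonality-linked niche trait."""
    from .trait_space import build_functional_dendrogram, gower_similarity, to_dissimilarity

    trees = simulate_tree_ensemble(n_species, n_trees, seed=substream_seed(seed, "demo-trees"))
    traits = simulate_traits(trees[0], seed=substream_seed(seed, "demo-traits"))
    envir = simulate_environment(n_lat=n_lat, n_lon=n_lon, seed=substream_seed(seed, "demo-env"))
    cells = envir.cells
    north = cells["lat"] >= 0
    D = to_dissimilarity(gower_similarity(traits))

    rng = substream(seed, "demo-richness")
    # richness rises with latitude toward the boreal north and only weakly
    # toward the southern high latitudes, echoing the real diversity gradient
    lat_vals = cells["lat"].to_numpy(float)
    mean_r = np.where(
        north,
        4.0 + (richness_mean_north - 4.0) * (lat_vals / 70.0),
        4.0 + (richness_mean_south - 4.0) * (np.abs(lat_vals) / 55.0),
    )
    richness = pd.Series(
        1 + rng.poisson(np.maximum(mean_r - 1, 0)), index=cells.index
    ).clip(upper=n_species)

    sc_n = AssemblyScenario(
        mode="filtering", sigma=sigma, niche_trait="body_mass",
        env_predictor="season", seed=substream_seed(seed, "demo-north"),
    )
    grid_n, ex_n = assemble_communities(
        traits, cells.loc[north], sc_n,
        env_values=envir.truth["season_field"].loc[north],
        richness=richness.loc[north],
    )
    sc_s = AssemblyScenario(
        mode="limiting-similarity", delta=delta,
        seed=substream_seed(seed, "demo-south"),
    )
    grid_s, ex_s = assemble_communities(
        traits, cells.loc[~north], sc_s,
        gower_distance=D, richness=richness.loc[~north],
    )
    presence = pd.concat([grid_n.presence, grid_s.presence]).loc[cells.index]
    grid = CommunityGrid(cells.copy(), presence)
    exhausted = pd.concat([ex_n, ex_s]).loc[cells.index]
    truth = {
        "north_mode": "filtering",
        "south_mode": "limiting-similarity",
        "niche_trait": "body_mass",
        "linked_field": "season_field",
        "sigma": sigma,
        "delta": delta,
        "seed": seed,
    }
    return DemoInputs(trees, traits, envir, grid, exhausted, truth)
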