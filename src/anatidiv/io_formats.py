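"""Tabular input formats: trait tables, community grids, environment tables.

Everything is delimited text (comma by default) with a mandatory header row,
read into pandas and validated eagerly so downstream stages can assume
clean data.  Missing trait values are allowed and survive the round trip;
they are handled by pairwise deletion in the Gower computation, never
imputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import read_newick_ensemble, write_newick_ensemble  # noqa: F401 (re-export)

__all__ = [
    "ValidationError",
    "TraitSchema",
    "TraitTable",
    "CommunityGrid",
    "EnvTable",
    "read_trait_table",
    "write_trait_table",
    "read_community_grid",
    "write_community_grid",
    "read_env_table",
    "write_env_table",
]

PCT_TOL = 1e-6

TRAIT_KINDS = ("continuous", "percentage", "binary")


class ValidationError(ValueError):
    pass


@dataclass
class TraitSchema:
    """Per-trait kinds plus the percentage-composition groups.

    ``kinds`` maps trait name -> one of {continuous, percentage, binary}.
    ``percentage_groups`` maps a group name (e.g. ``"diet"``) to the trait
    columns that must sum to 100 per species.
    """

    kinds: dict[str, str]
    percentage_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait, kind in self.kinds.items():
            if kind not in TRAIT_KINDS:
                raise ValidationError(f"unknown trait kind {kind!r} for trait {trait!r}")
        for group, cols in self.percentage_groups.items():
            for c in cols:
                if self.kinds.get(c) != "percentage":
                    raise ValidationError(
                        f"group {group!r} member {c!r} is not declared as a percentage trait"
                    )

    @property
    def traits(self) -> list[str]:
        return list(self.kinds)


@dataclass
class TraitTable:
    """Species x trait matrix of mixed type with its schema."""

    data: pd.DataFrame  # index: species, columns: traits; NaN = missing
    schema: TraitSchema

    def __post_init__(self) -> None:
        missing = [c for c in self.schema.traits if c not in self.data.columns]
        if missing:
            raise ValidationError(f"trait columns missing from data: {missing}")
        self.data = self.data[self.schema.traits].astype(float)
        self.data.index.name = "species"
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate species ids in trait table")
        self._validate()

    def _validate(self) -> None:
        for trait, kind in self.schema.kinds.items():
            col = self.data[trait]
            vals = col.dropna()
            if kind == "binary":
                bad = vals[~vals.isin([0.0, 1.0])]
                if len(bad):
                    raise ValidationError(
                        f"binary trait {trait!r} has non-0/1 values for species "
                        f"{list(bad.index[:5])}"
                    )
            elif kind == "percentage":
                if ((vals < 0) | (vals > 100)).any():
                    raise ValidationError(f"percentage trait {trait!r} outside [0, 100]")
            else:
                if not np.isfinite(vals.to_numpy()).all():
                    raise ValidationError(f"continuous trait {trait!r} has non-finite values")
        for group, cols in self.schema.percentage_groups.items():
            sums = self.data[cols].sum(axis=1, skipna=False)
            bad = sums.index[(~sums.isna()) & (np.abs(sums - 100.0) > PCT_TOL)]
            if len(bad):
                raise ValidationError(
                    f"percentage group {group!r} does not sum to 100 for species "
                    f"{list(bad[:5])}"
                )

    @property
    def species(self) -> list[str]:
        return list(self.data.index)


@dataclass
class CommunityGrid:
    """Grid cells (with center coordinates) x species presence/absence."""

    cells: pd.DataFrame      # index: cell_id; columns lat, lon
    presence: pd.DataFrame   # index: cell_id; columns: species; values 0/1

    def __post_init__(self) -> None:
        self.cells.index.name = "cell_id"
        self.presence.index.name = "cell_id"
        if self.cells.index.has_duplicates:
            dups = sorted(set(self.cells.index[self.cells.index.duplicated()]))
            raise ValidationError(f"duplicate cell ids: {dups[:5]}")
        if not self.cells.index.equals(self.presence.index):
            raise ValidationError("cell ids of coordinates and presence matrix differ")
        lat = self.cells["lat"].to_numpy(float)
        lon = self.cells["lon"].to_numpy(float)
        if ((lat < -90) | (lat > 90)).any():
            raise ValidationError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon >= 180)).any():
            raise ValidationError("longitude outside [-180, 180)")
        vals = self.presence.to_numpy(float)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValidationError("presence values must be 0 or 1")
        self.presence = self.presence.astype(np.int8)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def cell_ids(self) -> list:
        return list(self.cells.index)

    def richness(self) -> pd.Series:
        return self.presence.sum(axis=1).astype(int)

    def species_in(self, cell_id) -> list[str]:
        row = self.presence.loc[cell_id]
        return list(row.index[row.to_numpy() == 1])

    def check_against_pool(self, pool: frozenset[str]) -> None:
        extra = sorted(set(self.species) - set(pool))
        if extra:
            raise ValidationError(f"species not in tree tip set: {extra[:10]}")

    def subset_cells(self, keep) -> "CommunityGrid":
        return CommunityGrid(self.cells.loc[keep].copy(), self.presence.loc[keep].copy())


@dataclass
class EnvTable:
    """Cell x environmental-predictor matrix with a predictor-family map."""

    data: pd.DataFrame
    families: dict[str, str] = field(default_factory=dict)

    FAMILIES = ("climate-mean", "climate-heterogeneity", "productivity",
                "hydrogeomorphology", "coordinate")

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate cell ids in environment table")
        vals = self.data.to_numpy(float)
        if not np.isfinite(vals).all():
            raise ValidationError("environment table contains non-finite values")
        for name, fam in self.families.items():
            if fam not in self.FAMILIES:
                raise ValidationError(f"unknown predictor family {fam!r} for {name!r}")

    @property
    def predictors(self) -> list[str]:
        return list(self.data.columns)

    def align_to(self, grid: CommunityGrid) -> "EnvTable":
        if set(self.data.index) != set(grid.cell_ids):
            raise ValidationError("environment cell set differs from community grid")
        return EnvTable(self.data.loc[grid.cell_ids].copy(), dict(self.families))


# ---------------------------------------------------------------------------
# readers / writers


def read_trait_table(path, schema: TraitSchema, sep: str = ",") -> TraitTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return TraitTable(df, schema)


def write_trait_table(table: TraitTable, path, sep: str = ",") -> None:
    table.data.to_csv(path, sep=sep, index_label="species")


def read_community_grid(path, sep: str = ",") -> CommunityGrid:
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in ("lat", "lon"):
        if col not in df.columns:
            raise ValidationError(f"community grid file lacks required column {col!r}")
    sp_cols = [c for c in df.columns if c not in ("lat", "lon")]
    return CommunityGrid(df[["lat", "lon"]].copy(), df[sp_cols].copy())


def write_community_grid(grid: CommunityGrid, path, sep: str = ",") -> None:
    out = pd.concat([grid.cells, grid.presence], axis=1)
    out.to_csv(path, sep=sep, index_label="cell_id")


def read_env_table(path, families: dict[str, str] | None = None, sep: str = ",") -> EnvTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return EnvTable(df, families or {})


def write_env_table(env: EnvTable, path, sep: str = ",") -> None:
    env.data.to_csv(path, sep=sep, index_label="cell_id")
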