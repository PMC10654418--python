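"""Survey filtering: from raw records to a binary occurrence matrix.

The chain is: average replicate quantities -> binarize (quantity > 0 is
presence, irrespective of magnitude) -> temporal de-duplication (keep
each site's most recent sampling year) -> spatial de-duplication on a
25 m square grid (keep the latest-year site per cell, random seeded
tie-break) -> drop species seen at fewer than 100 sites.  The chain is
idempotent: applying it twice equals applying it once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rasters import EnvStack

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["site_id", "x", "y", "year", "method", "species", "quantity"]
_KEY = ["site_id", "x", "y", "year", "method", "species"]


@dataclass
class OccurrenceMatrix:
    """Binary sites x species matrix with site metadata and group labels.

    ``values`` is indexed by site_id with one column per species;
    ``sites`` carries (site_id, x, y, year); ``groups`` maps species ->
    {"charophyte", "angiosperm"}.
    """

    values: pd.DataFrame
    sites: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = ~self.values.isin([0, 1]).all()
        if bad.any():
            raise ValueError(f"non-binary occurrence values in {list(self.values.columns[bad])}")

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_sites(self) -> int:
        return len(self.values)

    def presence_counts(self) -> pd.Series:
        return self.values.sum(axis=0)

    def to_wide_csv(self, path) -> None:
        self.sites.set_index("site_id").join(self.values).to_csv(path)


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"survey table is missing columns {missing}")
    if (table["quantity"] < 0).any():
        raise ValueError("negative quantities are not valid survey records")


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean quantity over replicate samples of the same
    (site, year, method, species); a no-op for tables without replicates."""
    _check_table(table)
    return table.groupby(_KEY, as_index=False, sort=False)["quantity"].mean()


def binarize(table: pd.DataFrame) -> pd.DataFrame:
    """Map quantity to presence: any positive quantity (biomass or
    cover) becomes 1, zero stays 0."""
    _check_table(table)
    out = table.copy()
    out["quantity"] = (out["quantity"] > 0).astype(float)
    return out


def temporal_dedup(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only each site's most recent sampling year."""
    _check_table(table)
    latest = table.groupby("site_id")["year"].transform("max")
    return table[table["year"] == latest].reset_index(drop=True)


def spatial_dedup(
    table: pd.DataFrame,
    cell: float = 25.0,
    seed: int = 0,
    origin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Thin sites to at most one per square grid cell of side ``cell`` m.

    Cells are half-open intervals [x0 + i*cell, x0 + (i+1)*cell); the
    grid origin defaults to the floor of the minimum coordinates.
    Within a cell the latest-year site wins; same-year ties are broken
    by a seeded uniform draw.
    """
    _check_table(table)
    if cell <= 0:
        raise ValueError(f"cell must be > 0, got {cell}")
    sites = table[["site_id", "x", "y", "year"]].drop_duplicates("site_id")
    if origin is None:
        origin = (float(np.floor(sites["x"].min())), float(np.floor(sites["y"].min())))
    x0, y0 = origin
    ix = np.floor((sites["x"].to_numpy() - x0) / cell).astype(int)
    iy = np.floor((sites["y"].to_numpy() - y0) / cell).astype(int)
    rng = np.random.default_rng(seed)
    tie = rng.uniform(size=len(sites))
    choice = (
        sites.assign(_ix=ix, _iy=iy, _tie=tie)
        .sort_values(["year", "_tie"], ascending=[False, False], kind="stable")
        .drop_duplicates(["_ix", "_iy"], keep="first")
    )
    keep = set(choice["site_id"])
    out = table[table["site_id"].isin(keep)].reset_index(drop=True)
    log.info("spatial_dedup: %d -> %d sites (%.0f m cells)", sites.shape[0], len(keep), cell)
    return out


def build_occurrence_matrix(
    table: pd.DataFrame, groups: dict[str, str] | None = None
) -> OccurrenceMatrix:
    """Pivot a binarized record table into a sites x species matrix.
    A species absent from a site's records counts as an absence."""
    _check_table(table)
    if not table["quantity"].isin([0, 1]).all():
        raise ValueError("table must be binarized first")
    wide = (
        table.pivot_table(index="site_id", columns="species", values="quantity",
                          aggfunc="max", fill_value=0)
        .astype(int)
    )
    wide.columns.name = None
    sites = (
        table[["site_id", "x", "y", "year"]]
        .drop_duplicates("site_id")
        .set_index("site_id")
        .loc[wide.index]
        .reset_index()
    )
    return OccurrenceMatrix(values=wide, sites=sites, groups=dict(groups or {}))


def filter_rare_species(matrix: OccurrenceMatrix, min_occurrence: int = 100) -> OccurrenceMatrix:
    """Drop species present at fewer than ``min_occurrence`` sites
    (strict: exactly ``min_occurrence`` presences is kept).  Sites are
    retained even if every remaining species is absent there."""
    counts = matrix.presence_counts()
    kept = counts.index[counts >= min_occurrence]
    dropped = sorted(set(matrix.species) - set(kept))
    if dropped:
        log.info("filter_rare_species: dropping %s (< %d presences)", dropped, min_occurrence)
    return OccurrenceMatrix(
        values=matrix.values[list(kept)],
        sites=matrix.sites,
        groups={s: g for s, g in matrix.groups.items() if s in set(kept)},
    )


def extract_env(matrix: OccurrenceMatrix, env: EnvStack) -> pd.DataFrame:
    """Per-site predictor values by nearest-cell lookup.

    Sites outside the raster extent or hitting nodata in any layer are
    dropped with a warning; the returned frame is indexed by site_id.
    """
    x = matrix.sites["x"].to_numpy()
    y = matrix.sites["y"].to_numpy()
    sampled = env.sample(x, y)
    feats = pd.DataFrame(sampled, index=pd.Index(matrix.sites["site_id"], name="site_id"))
    ok = ~feats.isna().any(axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        warnings.warn(
            f"extract_env: dropped {n_drop} site(s) outside the extent or on nodata cells",
            stacklevel=2,
        )
    return feats[ok]


def prepare_survey(
    table: pd.DataFrame,
    groups: dict[str, str] | None = None,
    cell: float = 25.0,
    min_occurrence: int = 100,
    seed: int = 0,
) -> OccurrenceMatrix:
    """Full filter chain; stage-by-stage record counts go to the log."""
    n0 = len(table)
    table = binarize(average_replicates(table))
    table = temporal_dedup(table)
    n1 = table["site_id"].nunique()
    table = spatial_dedup(table, cell=cell, seed=seed)
    matrix = build_occurrence_matrix(table, groups=groups)
    log.info("prepare_survey: %d records -> %d sites after temporal -> %d after spatial",
             n0, n1, matrix.n_sites)
    return filter_rare_species(matrix, min_occurrence=min_occurrence)
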