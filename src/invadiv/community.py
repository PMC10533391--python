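"""Forest-inventory ingestion, filtering, status assignment and aggregation.

The unit of measurement is one stem (tree id, plot id, coordinates, species
binomial, DBH in cm, optional height, a trees-per-hectare expansion factor
and a census year); the unit of analysis is a plot community.  The standard
preparation sequence is:

1. keep only each plot's most recent census;
2. keep stems with DBH >= 5 cm and height >= 1.3 m (missing height passes:
   a recorded DBH implies breast height was reached);
3. resolve each species' native status as the consensus of two independent
   status sources, dropping any plot that contains a species on which the
   sources disagree;
4. aggregate to plot communities (>= 3 species; replicate plots at
   identical coordinates collapsed to the replicate with the most stems),
   computing the three invasion metrics: presence of any non-native,
   relative non-native richness, and relative non-native basal area;
5. optionally down-sample plots proportionally to biome land area, with
   invaded plots preferentially retained up to half of each biome's quota.

Species found in neither status source are "unknown": they count toward
whole-community richness and basal area but never toward non-native counts.
Every row removed at any step lands in a drop log with a reason code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    InvalidArgumentError,
    IOFailure,
    SchemaError,
)
from .rng import stream

__all__ = [
    "INVENTORY_COLUMNS",
    "load_inventory",
    "select_latest_census",
    "filter_trees",
    "assign_native_status",
    "compute_basal_area",
    "PlotCommunity",
    "build_plot_communities",
    "downsample_by_biome",
    "largest_remainder_quotas",
]

INVENTORY_COLUMNS = [
    "tree_id", "plot_id", "lat", "lon", "species",
    "dbh_cm", "height_m", "tph", "year",
]

_NUMERIC = ["lat", "lon", "dbh_cm", "height_m", "tph", "year"]


def load_inventory(path, strict: bool = True) -> pd.DataFrame:
    """Read a delimited stem table, validating schema and numeric fields.

    In strict mode (default) a malformed numeric value raises
    :class:`SchemaError` naming the first offending row; otherwise bad rows
    are dropped and their count attached as ``df.attrs['n_malformed']``.
    ``height_m`` may be empty (optional field).
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except FileNotFoundError as exc:
        raise IOFailure(f"cannot read inventory: {path}") from exc
    missing = [c for c in INVENTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"inventory missing required columns: {missing}")
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    required = [c for c in _NUMERIC if c != "height_m"]
    bad = df[required].isna().any(axis=1)
    bad |= (df["dbh_cm"] <= 0) | (df["tph"] <= 0)
    bad |= (df["lat"].abs() > 90) | (df["lon"].abs() > 180)
    if bad.any():
        if strict:
            row = int(df.index[bad][0])
            raise SchemaError(f"malformed inventory row {row}: {df.loc[row].to_dict()}")
        df = df[~bad].copy()
    df.attrs["n_malformed"] = int(bad.sum())
    df["species"] = df["species"].astype(str).str.replace(" ", "_")
    return df.reset_index(drop=True)


def select_latest_census(records: pd.DataFrame) -> pd.DataFrame:
    """Keep, per plot, only rows from that plot's most recent census year."""
    latest = records.groupby("plot_id")["year"].transform("max")
    return records[records["year"] == latest].reset_index(drop=True)


def filter_trees(
    records: pd.DataFrame, min_dbh_cm: float = 5.0, min_height_m: float = 1.3
) -> pd.DataFrame:
    """Size filter: DBH and height thresholds, inclusive; missing height passes."""
    keep = records["dbh_cm"] >= min_dbh_cm
    keep &= records["height_m"].isna() | (records["height_m"] >= min_height_m)
    out = records[keep].reset_index(drop=True)
    out.attrs["n_dropped_size"] = int(len(records) - len(out))
    return out


def compute_basal_area(dbh_cm, tph):
    """Stand-level basal area of a stem record, m^2 per hectare.

    pi * (dbh/200)^2 scales the diameter (cm) to a cross-sectional area in
    m^2; the trees-per-hectare expansion factor converts to per-hectare.
    """
    dbh = np.asarray(dbh_cm, dtype=float)
    t = np.asarray(tph, dtype=float)
    if np.any(dbh <= 0) or np.any(t <= 0):
        raise InvalidArgumentError("dbh_cm and tph must be positive")
    out = math.pi * (dbh / 200.0) ** 2 * t
    return float(out) if np.isscalar(dbh_cm) else out


# --------------------------------------------------------------------------
# native status
# --------------------------------------------------------------------------

def assign_native_status(
    pairs: pd.DataFrame, table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[pd.DataFrame, list]:
    """Consensus native status per (species, region) plus a plot drop-list.

    ``pairs`` holds one row per (plot_id, species, region_id) occurrence;
    each status table holds (species, region_id, status) with status in
    {native, non-native}.  Agreement yields the shared value; a species
    listed by only one source takes that source's value; a species in
    neither is "unknown".  Any plot containing a species on which the two
    sources *conflict* goes on the drop-list.  The consensus is symmetric
    in the table order.
    """
    for name, t in (("table_a", table_a), ("table_b", table_b)):
        missing = {"species", "region_id", "status"} - set(t.columns)
        if missing:
            raise SchemaError(f"{name} missing columns: {sorted(missing)}")
    regions = set(pairs["region_id"])
    for name, t in (("table_a", table_a), ("table_b", table_b)):
        absent = regions - set(t["region_id"])
        if absent:
            raise CoverageError(f"{name} lacks regions: {sorted(map(str, absent))}")

    def lookup(t):
        return t.set_index(["species", "region_id"])["status"]

    la, lb = lookup(table_a), lookup(table_b)
    keys = pairs[["species", "region_id"]].drop_duplicates()
    sa = la.reindex(pd.MultiIndex.from_frame(keys)).to_numpy()
    sb = lb.reindex(pd.MultiIndex.from_frame(keys)).to_numpy()
    status = np.where(
        pd.isna(sa) & pd.isna(sb), "unknown",
        np.where(pd.isna(sa), sb,
                 np.where(pd.isna(sb), sa,
                          np.where(sa == sb, sa, "conflict"))),
    )
    resolved = keys.assign(status=status)
    conflicted = resolved[resolved["status"] == "conflict"]
    merged = pairs.merge(conflicted[["species", "region_id"]],
                         on=["species", "region_id"], how="inner")
    drop_plots = sorted(merged["plot_id"].unique().tolist())
    return resolved, drop_plots


# --------------------------------------------------------------------------
# plot communities
# --------------------------------------------------------------------------

@dataclass
class PlotCommunity:
    plot_id: str
    lat: float
    lon: float
    biome: str
    year: int
    species: dict = field(default_factory=dict)
    #: per-species: {"native": True|False|None, "stems": int, "basal_area": float}
    covariates: dict = field(default_factory=dict)

    @property
    def native_species(self) -> list:
        return sorted(s for s, v in self.species.items() if v["native"] is True)

    @property
    def nonnative_species(self) -> list:
        return sorted(s for s, v in self.species.items() if v["native"] is False)

    @property
    def all_species(self) -> list:
        return sorted(self.species)

    def metrics(self) -> dict:
        nn = self.nonnative_species
        total_ba = sum(v["basal_area"] for v in self.species.values())
        nn_ba = sum(self.species[s]["basal_area"] for s in nn)
        n_total = len(self.species)
        return {
            "plot_id": self.plot_id,
            "presence": len(nn) >= 1,
            "nn_species": len(nn),
            "total_species": n_total,
            "nn_basal_area": nn_ba,
            "total_basal_area": total_ba,
            "rel_richness": len(nn) / n_total if n_total else 0.0,
            "rel_abundance": nn_ba / total_ba if total_ba > 0 else 0.0,
        }


def build_plot_communities(
    records: pd.DataFrame,
    statuses: pd.DataFrame,
    covariates: pd.DataFrame,
    drop_plots: list | None = None,
    min_species: int = 3,
) -> tuple[list[PlotCommunity], pd.DataFrame, pd.DataFrame]:
    """Aggregate stem records into plot communities and invasion metrics.

    ``statuses`` is the consensus table from :func:`assign_native_status`;
    ``covariates`` is a per-plot table indexed by plot_id carrying at least
    region_id, biome and the model covariates.  Returns the community list,
    a per-plot metrics frame, and a drop log with reason codes
    (status-conflict, min-species, collapsed).
    """
    drop_rows = []
    records = records.copy()
    if drop_plots:
        dropped = records["plot_id"].isin(set(drop_plots))
        drop_rows += [
            {"plot_id": p, "reason": "status-conflict"}
            for p in sorted(records.loc[dropped, "plot_id"].unique())
        ]
        records = records[~dropped]

    cov = covariates.set_index("plot_id") if "plot_id" in covariates.columns else covariates
    missing_cov = set(records["plot_id"].unique()) - set(cov.index)
    if missing_cov:
        raise CoverageError(f"covariates missing for plots: {sorted(map(str, missing_cov))[:10]}")

    status_map = statuses.set_index(["species", "region_id"])["status"]
    records["basal_area"] = compute_basal_area(records["dbh_cm"], records["tph"])

    # collapse replicate plots at identical coordinates: keep the replicate
    # with the most stems, ties broken by plot_id sort order
    stems = records.groupby("plot_id").size().rename("n_stems")
    coords = records.groupby("plot_id")[["lat", "lon"]].first()
    info = coords.join(stems).reset_index().sort_values(
        ["n_stems", "plot_id"], ascending=[False, True]
    )
    keep_ids = info.drop_duplicates(subset=["lat", "lon"], keep="first")["plot_id"]
    collapsed = sorted(set(info["plot_id"]) - set(keep_ids))
    drop_rows += [{"plot_id": p, "reason": "collapsed"} for p in collapsed]
    records = records[records["plot_id"].isin(set(keep_ids))]

    communities = []
    for plot_id, grp in records.groupby("plot_id", sort=True):
        sp_counts = grp.groupby("species").agg(
            stems=("tree_id", "size"), basal_area=("basal_area", "sum")
        )
        if len(sp_counts) < min_species:
            drop_rows.append({"plot_id": plot_id, "reason": "min-species"})
            continue
        row = cov.loc[plot_id]
        region = row.get("region_id", row.get("biome"))
        species = {}
        for sp, sprow in sp_counts.iterrows():
            st = status_map.get((sp, region), "unknown")
            native = {"native": True, "non-native": False}.get(st)
            species[sp] = {
                "native": native,
                "stems": int(sprow["stems"]),
                "basal_area": float(sprow["basal_area"]),
            }
        communities.append(
            PlotCommunity(
                plot_id=str(plot_id),
                lat=float(grp["lat"].iloc[0]),
                lon=float(grp["lon"].iloc[0]),
                biome=str(row.get("biome", "unknown")),
                year=int(grp["year"].iloc[0]),
                species=species,
                covariates=row.to_dict(),
            )
        )
    metrics = pd.DataFrame([c.metrics() for c in communities])
    drop_log = pd.DataFrame(drop_rows, columns=["plot_id", "reason"])
    return communities, metrics, drop_log


# --------------------------------------------------------------------------
# biome-proportional down-sampling
# --------------------------------------------------------------------------

def largest_remainder_quotas(areas: dict, target_n: int) -> dict:
    """Hamilton (largest-remainder) apportionment of ``target_n`` by area share."""
    names = sorted(areas)
    w = np.array([areas[b] for b in names], dtype=float)
    if np.any(w <= 0):
        raise InvalidArgumentError("biome areas must be positive")
    shares = target_n * w / w.sum()
    base = np.floor(shares).astype(int)
    remainder = shares - base
    short = target_n - int(base.sum())
    order = np.lexsort((names, -remainder))  # largest remainder, name-stable
    for k in order[:short]:
        base[k] += 1
    return dict(zip(names, base.tolist()))


def downsample_by_biome(
    plots: pd.DataFrame,
    biome_areas: dict,
    target_n: int,
    seed: int = 0,
    preserve_biomes: tuple = (),
) -> pd.DataFrame:
    """Down-sample plots proportionally to biome land area.

    ``plots`` needs columns plot_id, biome, presence.  Per-biome quota is
    the largest-remainder apportionment of ``target_n`` by area share,
    capped at availability.  Within a biome, invaded plots are retained
    first, up to min(available invaded, floor(quota/2)) — at most half the
    quota — and the remainder is filled with uninvaded plots.  Biomes named
    in ``preserve_biomes`` (e.g. tropical ones) keep all their plots.
    Selection within each stratum is a seeded uniform draw.
    """
    biomes_present = [b for b in sorted(biome_areas) if (plots["biome"] == b).any()]
    if target_n < len(biomes_present):
        raise InvalidArgumentError(
            f"target_n={target_n} below the number of occupied biomes"
        )
    quotas = largest_remainder_quotas(biome_areas, target_n)
    rng = stream(seed, "downsample-by-biome")
    kept = []
    for biome in sorted(biome_areas):
        sub = plots[plots["biome"] == biome]
        if sub.empty:
            continue
        if biome in preserve_biomes:
            kept.append(sub)
            continue
        quota = min(quotas[biome], len(sub))
        invaded = sub[sub["presence"].astype(bool)]
        uninvaded = sub[~sub["presence"].astype(bool)]
        n_inv = min(len(invaded), quota // 2)
        n_uninv = min(len(uninvaded), quota - n_inv)
        kept.append(_draw(invaded, n_inv, rng))
        kept.append(_draw(uninvaded, n_uninv, rng))
    out = pd.concat(kept, axis=0) if kept else plots.iloc[:0]
    return out.sort_values("plot_id").reset_index(drop=True)


def _draw(frame: pd.DataFrame, k: int, rng) -> pd.DataFrame:
    if k >= len(frame):
        return frame
    idx = rng.choice(len(frame), size=k, replace=False)
    return frame.iloc[np.sort(idx)]
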