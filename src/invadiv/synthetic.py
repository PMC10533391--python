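"""Synthetic forest-inventory worlds with recorded ground truth.

The real analysis runs on an access-restricted global inventory joined to
naturalized-flora registers and climate rasters.  This module builds a
complete, self-consistent substitute with *known* generating parameters so
every downstream stage — filtering, diversity, spatial regression,
cross-validation, sensitivity — can be tested for parameter recovery:

* a pure-birth (Yule) ultrametric phylogeny whose genera are clades
  obtained by cutting the tree at a fixed depth fraction;
* eight positive traits evolving by geometric Brownian motion on that tree;
* a planar landscape mapped to the sphere, with a smooth temperature
  gradient, an independent precipitation gradient, random shipping ports,
  population density and four soil covariates, and biome bands sized by
  configurable land-area weights;
* native communities assembled by environmental filtering on a per-species
  thermal optimum (each species is "native" to the biome band holding its
  optimum, which also yields the two emulated status registers);
* an invasion process with three planted, tunable effects — presence
  decaying with distance to ports (plus spatially correlated noise),
  per-candidate establishment suppressed by native phylogenetic diversity
  (biotic resistance), and donor species chosen phylogenetically near the
  native community with a probability quadratic in temperature, so the
  invasion-strategy statistic is concave in MAT when ``gamma_T2 < 0``.

All randomness flows from ``config.seed`` through named child streams
(:mod:`invadiv.rng`), so any stage is reproducible in isolation and the
whole dataset is byte-identical under a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.special import expit

from .community import PlotCommunity, compute_basal_area
from .diversity import TRAIT_NAMES
from .errors import GenerationFailure, InvalidArgumentError
from .rng import stream
from .spatial import pairwise_haversine_km
from .trees import TreeIndex, genus_of

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_phylogeny",
    "simulate_traits",
    "simulate_landscape",
    "assemble_native_communities",
    "simulate_invasion",
    "simulate_richness_change",
    "gaussian_kernel_field",
    "generate_dataset",
    "write_dataset",
]

#: realistic log-scale baselines for the eight traits (units in comments)
_TRAIT_BASELINES = {
    "wood_density": math.log(0.6),     # g cm^-3
    "root_depth": math.log(2.0),       # m
    "leaf_nitrogen": math.log(20.0),   # mg g^-1
    "leaf_phosphorus": math.log(1.2),  # mg g^-1
    "leaf_area": math.log(30.0),       # cm^2
    "tree_height": math.log(20.0),     # m
    "seed_dry_mass": math.log(50.0),   # mg
    "bark_thickness": math.log(5.0),   # mm
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world; defaults are the study conditions."""

    seed: int = 0
    n_species: int = 150
    n_plots: int = 500
    n_biomes: int = 4
    biome_areas: tuple = (0.4, 0.3, 0.2, 0.1)
    birth_rate: float = 1.0
    trait_sigma2: tuple = (0.05,) * 8
    landscape_extent_km: float = 3000.0
    n_ports: int = 5
    alpha_presence: float = -1.0     # baseline log-odds of plot invasion
    beta_port: float = -0.8          # effect of z(log distance-to-port) on presence
    establish_intercept: float = -1.5
    beta_div: float = -0.8           # effect of z(native PD) on establishment
    gamma_T2: float = -1.0           # quadratic MAT effect on invasion strategy
    noise_sd: float = 0.2            # residual SD of the strategy/richness responses
    spatial_range_km: float = 250.0
    spatial_noise_sd: float = 1.0    # SD of the correlated presence noise
    filter_strength: float = 1.0     # environmental-filtering intensity
    mean_richness: float = 12.0      # mean native richness above the 3-species floor
    n_candidates: int = 8            # non-native candidates per invaded plot
    status_disagreement: float = 0.0 # fraction of species discordant between registers

    def __post_init__(self):
        if self.n_species < 10:
            raise InvalidArgumentError("n_species must be >= 10")
        if self.n_plots < 50:
            raise InvalidArgumentError("n_plots must be >= 50")
        areas = np.asarray(self.biome_areas, dtype=float)
        if areas.size != self.n_biomes or np.any(areas <= 0):
            raise InvalidArgumentError(
                "biome_areas must hold one positive weight per biome"
            )
        for name in ("birth_rate", "spatial_range_km", "landscape_extent_km",
                     "noise_sd"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if len(self.trait_sigma2) != 8 or any(s < 0 for s in self.trait_sigma2):
            raise InvalidArgumentError("trait_sigma2 needs 8 nonnegative rates")


@dataclass
class GroundTruth:
    """Per-plot generating expectations plus the parameters that made them."""

    table: pd.DataFrame  # plot_id, true_native_richness, true_preinvasion_richness,
                         # presence_prob, severity_expectation, strategy_near_prob
    params: dict

    def __post_init__(self):
        p = self.table
        for col in ("presence_prob", "severity_expectation", "strategy_near_prob"):
            vals = p[col].to_numpy()
            assert np.all((vals >= 0) & (vals <= 1)), f"{col} outside [0,1]"
        assert np.all(
            p["true_preinvasion_richness"] >= p["true_native_richness"]
        ), "pre-invasion richness below native richness"


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    tree: TreeIndex
    traits: pd.DataFrame
    landscape: pd.DataFrame
    communities: list
    inventory: pd.DataFrame
    status_a: pd.DataFrame
    status_b: pd.DataFrame
    ground_truth: GroundTruth
    species_home_biome: pd.Series


# --------------------------------------------------------------------------
# phylogeny
# --------------------------------------------------------------------------

def simulate_phylogeny(n_species: int, birth_rate: float, seed: int) -> TreeIndex:
    """Pure-birth (Yule) tree conditioned on tip count, ultrametric.

    Tips are labelled ``G<k>_s<i>``: genera are the clades hanging below the
    slice of the tree at 20% of the root depth, so congeners are clades and
    most tips have congeneric partners.
    """
    if n_species < 2:
        raise InvalidArgumentError("need at least 2 species")
    if birth_rate <= 0:
        raise InvalidArgumentError("birth_rate must be positive")
    rng = stream(seed, "simulate-phylogeny")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    t = 0.0
    active: list = []
    birth: dict = {}
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
        birth[id(child)] = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        nd = active.pop(rng.integers(k))
        nd.edge.length = t - birth[id(nd)]
        for _ in range(2):
            child = dendropy.Node()
            nd.add_child(child)
            active.append(child)
            birth[id(child)] = t
    t += rng.exponential(1.0 / (birth_rate * n_species))  # extend to the present
    order = rng.permutation(len(active))
    for pos, nd in enumerate(active):
        nd.edge.length = t - birth[id(nd)]
        nd.taxon = taxa.new_taxon(f"tmp{order[pos]}")
    tree.is_rooted = True

    _assign_genus_labels(tree, t)
    return TreeIndex(tree)


def _assign_genus_labels(tree: dendropy.Tree, depth: float) -> None:
    """Relabel tips so that genera are the clades below a depth-fraction cut."""
    frac = 0.2
    leaves = list(tree.leaf_node_iter())
    while True:
        cut = frac * depth
        genus_root: dict = {}
        counter = [0]

        def assign(nd, d):
            top = d - (nd.edge.length or 0.0)
            if nd.is_leaf() or (top < cut <= d) or (nd.parent_node is None and d >= cut):
                counter[0] += 1
                gid = counter[0]
                for leaf in nd.leaf_iter():
                    genus_root[id(leaf)] = gid
                return
            for ch in nd.child_nodes():
                assign(ch, d + (ch.edge.length or 0.0))

        for ch in tree.seed_node.child_nodes():
            assign(ch, ch.edge.length or 0.0)
        counts: dict = {}
        for leaf in leaves:
            counts[genus_root[id(leaf)]] = counts.get(genus_root[id(leaf)], 0) + 1
        share = sum(c for c in counts.values() if c >= 2) / len(leaves)
        if share >= 0.2 or frac <= 0.01:
            break
        frac /= 2.0  # cut closer to the root -> fewer, larger genera

    per_genus: dict = {}
    for i, leaf in enumerate(sorted(leaves, key=lambda x: genus_root[id(x)])):
        gid = genus_root[id(leaf)]
        per_genus[gid] = per_genus.get(gid, 0) + 1
        leaf.taxon.label = f"G{gid}_s{per_genus[gid]}"


# --------------------------------------------------------------------------
# traits
# --------------------------------------------------------------------------

def simulate_traits(tree: TreeIndex, sigma2, seed: int) -> pd.DataFrame:
    """Brownian motion on the log scale along the tree, exponentiated.

    One column per trait (the eight standard trait names), one row per tip;
    raw values are strictly positive with log-normal marginals.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if sigma2.size != 8 or np.any(sigma2 < 0):
        raise InvalidArgumentError("sigma2 must hold 8 nonnegative rates")
    if np.all(tree.edge_lengths[1:] == 0):
        raise InvalidArgumentError("tree has no branch lengths")
    rng = stream(seed, "simulate-traits")
    n_nodes = tree.edge_lengths.size
    values = np.zeros((n_nodes, 8))
    values[0] = [_TRAIT_BASELINES[t] for t in TRAIT_NAMES]
    scale = np.sqrt(np.outer(tree.edge_lengths, sigma2))
    steps = rng.normal(0.0, 1.0, size=(n_nodes, 8)) * scale
    for k in range(1, n_nodes):  # preorder: parents precede children
        values[k] = values[tree.parent[k]] + steps[k]
    tips = values[tree.tip_node_indices]
    return pd.DataFrame(np.exp(tips), index=list(tree.taxa), columns=TRAIT_NAMES)


# --------------------------------------------------------------------------
# landscape
# --------------------------------------------------------------------------

def gaussian_kernel_field(lat, lon, range_km: float, rng, n_centers: int = 40):
    """Smooth random field: sum of Gaussian kernels at random centres.

    Standardized to zero mean / unit SD.  Cheaper than an exact Gaussian
    random field but carries autocorrelation with the requested range,
    which is all the residual-autocovariate machinery needs.
    """
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    idx = rng.integers(0, lat.size, size=n_centers)
    jitter_lat = rng.normal(0, 0.5, n_centers)
    jitter_lon = rng.normal(0, 0.5, n_centers)
    weights = rng.normal(0, 1, n_centers)
    d = pairwise_haversine_km(lat, lon,
                              np.clip(lat[idx] + jitter_lat, -90, 90),
                              np.clip(lon[idx] + jitter_lon, -180, 180))
    f = (np.exp(-0.5 * (d / range_km) ** 2) * weights).sum(axis=1)
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f * 0.0


def simulate_landscape(config: SyntheticConfig) -> pd.DataFrame:
    """Plot coordinates and covariates on a square region near the equator.

    MAT runs as a smooth latitudinal gradient (plus kernel noise), MAP as
    an independent longitudinal gradient; biome bands are MAT quantile
    slices sized by ``config.biome_areas``.  Distance to ports is the
    great-circle distance to the nearest of ``n_ports`` random ports.
    """
    rng = stream(config.seed, "simulate-landscape")
    half_deg = config.landscape_extent_km / 2.0 / 111.32
    n = config.n_plots
    lat = rng.uniform(-half_deg, half_deg, n)
    lon = rng.uniform(-half_deg, half_deg, n)

    lat_norm = (lat + half_deg) / (2 * half_deg)
    lon_norm = (lon + half_deg) / (2 * half_deg)
    mat = 25.0 - 20.0 * lat_norm + 1.5 * gaussian_kernel_field(
        lat, lon, config.spatial_range_km, rng
    )
    map_mm = 400.0 + 1800.0 * lon_norm + 150.0 * gaussian_kernel_field(
        lat, lon, config.spatial_range_km, rng
    )
    map_mm = np.clip(map_mm, 50.0, None)

    port_lat = rng.uniform(-half_deg, half_deg, config.n_ports)
    port_lon = rng.uniform(-half_deg, half_deg, config.n_ports)
    dist_ports = pairwise_haversine_km(lat, lon, port_lat, port_lon).min(axis=1)

    pop_density = np.exp(rng.normal(math.log(50.0), 1.0, n))
    soil_depth = np.exp(rng.normal(math.log(150.0), 0.4, n))
    soil_coarse = np.clip(rng.normal(15.0, 8.0, n), 0.0, 80.0)
    soil_sand = np.clip(rng.normal(40.0, 15.0, n), 1.0, 99.0)
    soil_ph = np.clip(rng.normal(6.0, 0.8, n), 3.5, 9.0)

    areas = np.asarray(config.biome_areas, float)
    edges = np.quantile(mat, np.cumsum(areas / areas.sum())[:-1])
    biome_idx = np.searchsorted(edges, mat, side="right")
    biome = np.array([f"biome_{k + 1}" for k in biome_idx])

    df = pd.DataFrame(
        {
            "plot_id": [f"p{str(i).zfill(5)}" for i in range(n)],
            "lat": lat,
            "lon": lon,
            "mat": mat,
            "map": map_mm,
            "dist_ports_km": dist_ports,
            "pop_density": pop_density,
            "soil_depth": soil_depth,
            "soil_coarse": soil_coarse,
            "soil_sand": soil_sand,
            "soil_ph": soil_ph,
            "biome": biome,
        }
    )
    df["region_id"] = df["biome"]
    df.attrs["ports"] = np.column_stack([port_lat, port_lon])
    df.attrs["biome_area_weights"] = {
        f"biome_{k + 1}": float(a / areas.sum()) for k, a in enumerate(areas)
    }
    df.attrs["mat_band_edges"] = edges
    return df


# --------------------------------------------------------------------------
# community assembly
# --------------------------------------------------------------------------

def _species_optima(tree: TreeIndex, landscape: pd.DataFrame, seed: int):
    rng = stream(seed, "species-optima")
    mat = landscape["mat"].to_numpy()
    lo, hi = mat.min(), mat.max()
    optima = rng.uniform(lo, hi, tree.n_tips)
    edges = landscape.attrs["mat_band_edges"]
    home = np.searchsorted(edges, optima, side="right")
    # every biome needs >=3 resident species so any plot can reach the
    # 3-species floor: move the closest-optimum species from crowded bands
    n_biomes = len(edges) + 1
    centers = np.concatenate([[lo], edges, [hi]])
    centers = (centers[:-1] + centers[1:]) / 2.0
    for b in range(n_biomes):
        while np.sum(home == b) < 3:
            counts = np.bincount(home, minlength=n_biomes)
            donors = np.flatnonzero(counts > 3)
            cand = np.flatnonzero(np.isin(home, donors))
            move = cand[np.argmin(np.abs(optima[cand] - centers[b]))]
            home[move] = b
    home_biome = pd.Series(
        [f"biome_{k + 1}" for k in home], index=list(tree.taxa), name="home_biome"
    )
    return pd.Series(optima, index=list(tree.taxa)), home_biome


def _draw_stems(rng, plot_id, lat, lon, year, species_list, start_id):
    rows = []
    tid = start_id
    for sp in species_list:
        n_stems = 1 + rng.poisson(2.0)
        dbh = 5.0 + rng.lognormal(mean=2.3, sigma=0.6, size=n_stems)
        height = 1.3 + dbh * rng.uniform(0.4, 0.8, size=n_stems)
        tph = rng.uniform(5.0, 25.0, size=n_stems)
        for d, h, t in zip(dbh, height, tph):
            rows.append(
                {
                    "tree_id": f"t{tid}", "plot_id": plot_id, "lat": lat,
                    "lon": lon, "species": sp, "dbh_cm": round(float(d), 3),
                    "height_m": round(float(h), 3), "tph": round(float(t), 3),
                    "year": year,
                }
            )
            tid += 1
    return rows, tid


def assemble_native_communities(
    tree: TreeIndex,
    traits: pd.DataFrame,
    landscape: pd.DataFrame,
    seed: int,
    filter_strength: float = 1.0,
    mean_richness: float = 12.0,
):
    """Native communities by thermal environmental filtering.

    Each plot samples its richness (3 + Poisson, so richness varies across
    plots) from the species pool native to its biome, weighted by
    ``exp(-filter_strength * (optimum - MAT)^2 / (2 * tau^2))`` with
    ``tau`` the SD of MAT over the landscape.  Returns the community list,
    a stem-level inventory frame and the per-species home-biome series.
    """
    rng = stream(seed, "assemble-communities")
    optima, home_biome = _species_optima(tree, landscape, seed)
    tau = landscape["mat"].std()
    species = np.array(list(tree.taxa))
    by_biome = {b: species[(home_biome == b).to_numpy()] for b in home_biome.unique()}

    communities, stem_rows = [], []
    tid = 0
    year = 2015
    for _, row in landscape.iterrows():
        pool = by_biome.get(row["biome"], np.array([]))
        if pool.size < 3:
            raise GenerationFailure(
                f"plot {row['plot_id']}: only {pool.size} native candidates"
            )
        w = np.exp(
            -filter_strength
            * (optima[pool].to_numpy() - row["mat"]) ** 2
            / (2.0 * tau**2)
        )
        w = w / w.sum()
        target = min(pool.size, 3 + rng.poisson(max(mean_richness - 3.0, 0.0)))
        chosen = rng.choice(pool, size=target, replace=False, p=w)
        rows, tid = _draw_stems(
            rng, row["plot_id"], row["lat"], row["lon"], year, sorted(chosen), tid
        )
        stem_rows.extend(rows)
        comm = PlotCommunity(
            plot_id=row["plot_id"], lat=row["lat"], lon=row["lon"],
            biome=row["biome"], year=year,
            covariates=row.drop(["plot_id"]).to_dict(),
        )
        for sp in sorted(chosen):
            sp_rows = [r for r in rows if r["species"] == sp]
            comm.species[sp] = {
                "native": True,
                "stems": len(sp_rows),
                "basal_area": float(
                    sum(compute_basal_area(r["dbh_cm"], r["tph"]) for r in sp_rows)
                ),
            }
        communities.append(comm)
    inventory = pd.DataFrame(stem_rows)
    return communities, inventory, home_biome


# --------------------------------------------------------------------------
# invasion
# --------------------------------------------------------------------------

def simulate_invasion(
    communities: list,
    tree: TreeIndex,
    landscape: pd.DataFrame,
    config: SyntheticConfig,
    inventory: pd.DataFrame,
    home_biome: pd.Series,
):
    """Plant the three estimands into the native communities (see module doc).

    Returns updated communities, the extended stem inventory and a
    :class:`GroundTruth` record of every plot's generating expectations.
    """
    rng = stream(config.seed, "simulate-invasion")
    n = len(communities)
    lat = landscape["lat"].to_numpy()
    lon = landscape["lon"].to_numpy()

    logdist = np.log(landscape["dist_ports_km"].to_numpy() + 1.0)
    z_port = (logdist - logdist.mean()) / logdist.std()
    noise = config.spatial_noise_sd * gaussian_kernel_field(
        lat, lon, config.spatial_range_km, rng
    )
    presence_prob = expit(config.alpha_presence + config.beta_port * z_port + noise)
    invaded = rng.random(n) < presence_prob

    pd_native = np.array(
        [tree.faiths_pd(c.native_species) for c in communities]
    )
    z_pd = (pd_native - pd_native.mean()) / pd_native.std()
    establish_prob = expit(config.establish_intercept + config.beta_div * z_pd)

    mat = landscape["mat"].to_numpy()
    z_mat = (mat - mat.mean()) / mat.std()
    near_prob = expit(0.0 - config.gamma_T2 * z_mat**2)

    dist_matrix = tree.patristic_matrix()
    tip_pos = {t: i for i, t in enumerate(tree.taxa)}
    species = np.array(list(tree.taxa))
    stem_rows = []
    tid = int(inventory["tree_id"].str.lstrip("t").astype(int).max()) + 1

    for i, comm in enumerate(communities):
        if not invaded[i]:
            continue
        foreign = species[(home_biome != comm.biome).to_numpy()]
        foreign = np.array([s for s in foreign if s not in comm.species])
        if foreign.size == 0:
            raise GenerationFailure(f"plot {comm.plot_id}: no non-native pool")
        k = min(config.n_candidates, foreign.size)
        candidates = rng.choice(foreign, size=k, replace=False)
        n_est = int(rng.binomial(k, establish_prob[i]))
        n_est = max(n_est, 1)  # an invaded plot holds >= 1 non-native
        native_idx = [tip_pos[s] for s in comm.native_species]
        cand_idx = np.array([tip_pos[s] for s in candidates])
        d_to_native = dist_matrix[np.ix_(cand_idx, native_idx)].min(axis=1)
        nearest_order = np.argsort(d_to_native, kind="stable")
        chosen: list = []
        for slot in range(n_est):
            if rng.random() < near_prob[i]:
                pick = next(
                    j for j in nearest_order if candidates[j] not in chosen
                )
            else:
                remaining = [
                    j for j in range(k) if candidates[j] not in chosen
                ]
                pick = remaining[rng.integers(len(remaining))]
            chosen.append(candidates[pick])
            if len(chosen) == k:
                break
        rows, tid = _draw_stems(
            rng, comm.plot_id, comm.lat, comm.lon, comm.year, sorted(chosen), tid
        )
        stem_rows.extend(rows)
        for sp in sorted(chosen):
            sp_rows = [r for r in rows if r["species"] == sp]
            comm.species[sp] = {
                "native": False,
                "stems": len(sp_rows),
                "basal_area": float(
                    sum(compute_basal_area(r["dbh_cm"], r["tph"]) for r in sp_rows)
                ),
            }

    inventory = pd.concat(
        [inventory, pd.DataFrame(stem_rows)], ignore_index=True
    ) if stem_rows else inventory

    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "plot_id": [c.plot_id for c in communities],
                "true_native_richness": [len(c.native_species) for c in communities],
                "true_preinvasion_richness": [
                    len(c.native_species) for c in communities
                ],
                "presence_prob": presence_prob,
                "severity_expectation": establish_prob,
                "strategy_near_prob": near_prob,
                "invaded": invaded.astype(int),
            }
        ),
        params={
            "alpha_presence": config.alpha_presence,
            "beta_port": config.beta_port,
            "establish_intercept": config.establish_intercept,
            "beta_div": config.beta_div,
            "gamma_T2": config.gamma_T2,
            "spatial_range_km": config.spatial_range_km,
            "spatial_noise_sd": config.spatial_noise_sd,
            "seed": config.seed,
        },
    )
    return communities, inventory, truth


# --------------------------------------------------------------------------
# two-census richness change (sensitivity machinery input)
# --------------------------------------------------------------------------

def simulate_richness_change(
    n_plots: int,
    c: float = -0.05,
    invasion_rate: float = 0.3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-census plots with a planted richness-loss effect of invasion.

    The first census is fully native with richness ``S1``; the fractional
    richness change to the second census is ``c`` for plots that become
    invaded, plus covariate effects and Gaussian noise.  Used to test the
    pre-invasion sensitivity correction.
    """
    rng = stream(seed, "richness-change")
    s1 = 3 + rng.poisson(12.0, n_plots)
    invaded = (rng.random(n_plots) < invasion_rate).astype(int)
    mat = rng.normal(15.0, 5.0, n_plots)
    map_mm = rng.normal(1200.0, 300.0, n_plots)
    z = lambda x: (x - x.mean()) / x.std()
    pct_change = (
        c * invaded
        + 0.01 * z(mat)
        - 0.005 * z(map_mm)
        + rng.normal(0.0, noise_sd, n_plots)
    )
    s2 = np.maximum(1, np.round(s1 * (1.0 + pct_change)).astype(int))
    return pd.DataFrame(
        {
            "plot_id": [f"tc{idx}" for idx in range(n_plots)],
            "richness_t1": s1,
            "richness_t2": s2,
            "pct_change": pct_change,
            "invaded": invaded,
            "mat": mat,
            "map": map_mm,
        }
    )


# --------------------------------------------------------------------------
# dataset orchestration and serialization
# --------------------------------------------------------------------------

def _status_tables(home_biome: pd.Series, biomes: list, disagreement: float,
                   seed: int):
    rows = []
    for sp, home in home_biome.items():
        for b in biomes:
            rows.append(
                {"species": sp, "region_id": b,
                 "status": "native" if b == home else "non-native"}
            )
    a = pd.DataFrame(rows)
    b = a.copy()
    if disagreement > 0:
        rng = stream(seed, "status-disagreement")
        species = home_biome.index.to_numpy()
        n_flip = int(round(disagreement * species.size))
        flips = rng.choice(species, size=n_flip, replace=False)
        for sp in flips:
            region = biomes[rng.integers(len(biomes))]
            mask = (b["species"] == sp) & (b["region_id"] == region)
            b.loc[mask, "status"] = np.where(
                b.loc[mask, "status"] == "native", "non-native", "native"
            )
    return a.sort_values(["species", "region_id"]).reset_index(drop=True), \
        b.sort_values(["species", "region_id"]).reset_index(drop=True)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run the full generator under one config (one child stream per stage)."""
    tree = simulate_phylogeny(config.n_species, config.birth_rate, config.seed)
    traits = simulate_traits(tree, config.trait_sigma2, config.seed)
    landscape = simulate_landscape(config)
    communities, inventory, home_biome = assemble_native_communities(
        tree, traits, landscape, config.seed,
        filter_strength=config.filter_strength,
        mean_richness=config.mean_richness,
    )
    communities, inventory, truth = simulate_invasion(
        communities, tree, landscape, config, inventory, home_biome
    )
    biomes = sorted(landscape["biome"].unique())
    status_a, status_b = _status_tables(
        home_biome, biomes, config.status_disagreement, config.seed
    )
    return SyntheticDataset(
        config=config, tree=tree, traits=traits, landscape=landscape,
        communities=communities, inventory=inventory,
        status_a=status_a, status_b=status_b, ground_truth=truth,
        species_home_biome=home_biome,
    )


_FLOAT_FMT = "%.10g"


def write_dataset(dataset: SyntheticDataset, directory) -> dict:
    """Serialize every table as delimited text plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str) -> tuple[str, int]:
        path = directory / name
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        return name, len(df)

    files = dict(
        [
            tsv(dataset.inventory, "inventory.tsv"),
            tsv(dataset.traits.rename_axis("species").reset_index(), "traits.tsv"),
            tsv(dataset.landscape.drop(columns=[], errors="ignore"),
                "covariates.tsv"),
            tsv(dataset.status_a, "status_glonaf_like.tsv"),
            tsv(dataset.status_b, "status_kew_like.tsv"),
            tsv(dataset.ground_truth.table, "ground_truth.tsv"),
        ]
    )
    tree_path = directory / "phylogeny.nwk"
    tree_path.write_text(dataset.tree.to_newick() + "\n")
    files["phylogeny.nwk"] = dataset.tree.n_tips
    manifest = {
        "files": files,
        "params": dataset.ground_truth.params,
        "config": dataclasses.asdict(dataset.config),
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, np.ndarray)):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
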