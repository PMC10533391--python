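"""Inventory preparation: census/size filters, status consensus, down-sampling.

Writes a synthetic dataset to disk, reads it back through the same loaders a
real inventory would use, and applies the preparation chain: latest census,
5 cm DBH / 1.3 m height size filter, two-register consensus native status
(plots with conflicting species dropped), >=3-species plot filter, and
biome-proportional down-sampling with invaded plots kept first up to half of
each biome's quota.
"""

import tempfile
from pathlib import Path

import pandas as pd

from invadiv import (
    SyntheticConfig,
    assign_native_status,
    build_plot_communities,
    downsample_by_biome,
    filter_trees,
    generate_dataset,
    load_inventory,
    select_latest_census,
    write_dataset,
)

cfg = SyntheticConfig(seed=7, n_plots=300, n_species=100,
                      status_disagreement=0.05)
with tempfile.TemporaryDirectory() as tmp:
    write_dataset(generate_dataset(cfg), tmp)
    records = load_inventory(Path(tmp) / "inventory.tsv")
    covariates = pd.read_csv(Path(tmp) / "covariates.tsv", sep="\t")
    status_a = pd.read_csv(Path(tmp) / "status_glonaf_like.tsv", sep="\t")
    status_b = pd.read_csv(Path(tmp) / "status_kew_like.tsv", sep="\t")

print(f"stems read: {len(records)}")
records = filter_trees(select_latest_census(records))
print(f"after census + size filters: {len(records)}")

pairs = records.merge(covariates[["plot_id", "region_id"]], on="plot_id")[
    ["plot_id", "species", "region_id"]
].drop_duplicates()
statuses, drop_plots = assign_native_status(pairs, status_a, status_b)
print(f"plots dropped for status conflicts: {len(drop_plots)} "
      "(5% of species were deliberately discordant between the registers)")

communities, metrics, drop_log = build_plot_communities(
    records, statuses, covariates, drop_plots=drop_plots
)
print(f"plot communities kept: {len(communities)}; "
      f"invaded: {int(metrics['presence'].sum())}")

table = metrics.merge(
    pd.DataFrame({"plot_id": [c.plot_id for c in communities],
                  "biome": [c.biome for c in communities]}),
    on="plot_id",
)
areas = {b: w for b, w in zip(sorted(table["biome"].unique()),
                              (0.4, 0.3, 0.2, 0.1))}
kept = downsample_by_biome(table, areas, target_n=150, seed=0)
print("down-sampled to", len(kept), "plots; per-biome invaded fractions:")
for biome, grp in kept.groupby("biome"):
    print(f"  {biome}: {len(grp)} plots, {grp['presence'].mean():.2f} invaded"
          " (capped at one half of the quota)")
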