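"""Inventory filtering, status consensus, metrics and biome down-sampling."""

import math

import numpy as np
import pandas as pd
import pytest

from invadiv import (
    assign_native_status,
    build_plot_communities,
    compute_basal_area,
    downsample_by_biome,
    filter_trees,
    load_inventory,
    select_latest_census,
)
from invadiv.community import largest_remainder_quotas
from invadiv.errors import (
    CoverageError,
    InvalidArgumentError,
    SchemaError,
)


class TestLoadInventory:
    def test_round_trip(self, inventory_frame, tmp_path):
        path = tmp_path / "inv.tsv"
        inventory_frame.to_csv(path, sep="\t", index=False)
        got = load_inventory(path)
        assert len(got) == 4
        pd.testing.assert_frame_equal(
            got, inventory_frame, check_dtype=False
        )

    def test_missing_column_is_schema_error(self, inventory_frame, tmp_path):
        path = tmp_path / "inv.tsv"
        inventory_frame.drop(columns=["tph"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="tph"):
            load_inventory(path)

    def test_malformed_row_strict_names_row(self, inventory_frame, tmp_path):
        bad = inventory_frame.copy()
        bad["dbh_cm"] = bad["dbh_cm"].astype(object)
        bad.loc[2, "dbh_cm"] = "NA"
        path = tmp_path / "inv.tsv"
        bad.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="row 2"):
            load_inventory(path, strict=True)

    def test_malformed_row_lenient_drops_and_counts(self, inventory_frame, tmp_path):
        bad = inventory_frame.copy()
        bad["dbh_cm"] = bad["dbh_cm"].astype(object)
        bad.loc[2, "dbh_cm"] = "NA"
        path = tmp_path / "inv.tsv"
        bad.to_csv(path, sep="\t", index=False)
        got = load_inventory(path, strict=False)
        assert len(got) == 3
        assert got.attrs["n_malformed"] == 1


class TestCensusAndSizeFilters:
    def test_latest_census_per_plot(self):
        df = pd.DataFrame(
            {
                "plot_id": ["a", "a", "b", "b"],
                "year": [2001, 2009, 1999, 2005],
                "dbh_cm": [10.0] * 4,
            }
        )
        got = select_latest_census(df)
        assert set(got["year"]) == {2009, 2005}
        assert len(got) == 2

    def test_single_year_unchanged(self):
        df = pd.DataFrame({"plot_id": ["a"], "year": [2000], "dbh_cm": [10.0]})
        pd.testing.assert_frame_equal(select_latest_census(df), df)

    @pytest.mark.parametrize(
        "dbh,height,kept",
        [
            (4.9, 5.0, False),   # below the DBH minimum
            (5.0, 1.3, True),    # thresholds inclusive
            (6.0, 1.2, False),   # below the height minimum
            (6.0, np.nan, True), # missing height passes
        ],
    )
    def test_size_thresholds(self, dbh, height, kept):
        df = pd.DataFrame(
            {"plot_id": ["p"], "dbh_cm": [dbh], "height_m": [height]}
        )
        assert (len(filter_trees(df)) == 1) is kept

    def test_filters_idempotent(self, inventory_frame):
        once = filter_trees(select_latest_census(inventory_frame))
        twice = filter_trees(select_latest_census(once))
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )


class TestBasalArea:
    def test_hand_value(self):
        # pi * (20/200)^2 * 10 = 0.1 pi
        assert compute_basal_area(20.0, 10.0) == pytest.approx(
            math.pi * 0.01 * 10.0
        )

    def test_doubling_dbh_quadruples(self):
        assert compute_basal_area(40.0, 10.0) == pytest.approx(
            4.0 * compute_basal_area(20.0, 10.0)
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compute_basal_area(20.0, 0.0)


def _status_table(rows):
    return pd.DataFrame(rows, columns=["species", "region_id", "status"])


class TestStatusConsensus:
    def test_agreement_and_conflict(self):
        pairs = pd.DataFrame(
            {
                "plot_id": ["p1", "p1", "p2"],
                "species": ["A_a", "B_b", "B_b"],
                "region_id": ["r1", "r1", "r1"],
            }
        )
        a = _status_table([("A_a", "r1", "native"), ("B_b", "r1", "native")])
        b = _status_table([("A_a", "r1", "native"), ("B_b", "r1", "non-native")])
        resolved, drops = assign_native_status(pairs, a, b)
        lut = resolved.set_index("species")["status"]
        assert lut["A_a"] == "native"
        assert lut["B_b"] == "conflict"
        assert drops == ["p1", "p2"]  # every plot holding the conflicted species

    def test_unknown_species_retained(self):
        pairs = pd.DataFrame(
            {"plot_id": ["p1"], "species": ["C_c"], "region_id": ["r1"]}
        )
        a = _status_table([("A_a", "r1", "native")])
        b = _status_table([("A_a", "r1", "native")])
        resolved, drops = assign_native_status(pairs, a, b)
        assert resolved["status"].iloc[0] == "unknown"
        assert drops == []

    def test_symmetric_in_table_order(self):
        pairs = pd.DataFrame(
            {
                "plot_id": ["p1", "p2"],
                "species": ["A_a", "B_b"],
                "region_id": ["r1", "r1"],
            }
        )
        a = _status_table([("A_a", "r1", "native"), ("B_b", "r1", "non-native")])
        b = _status_table([("A_a", "r1", "native"), ("B_b", "r1", "native")])
        r1, d1 = assign_native_status(pairs, a, b)
        r2, d2 = assign_native_status(pairs, b, a)
        pd.testing.assert_frame_equal(r1, r2)
        assert d1 == d2

    def test_missing_region_is_coverage_error(self):
        pairs = pd.DataFrame(
            {"plot_id": ["p1"], "species": ["A_a"], "region_id": ["r9"]}
        )
        a = _status_table([("A_a", "r1", "native")])
        with pytest.raises(CoverageError, match="r9"):
            assign_native_status(pairs, a, a)


class TestPlotCommunities:
    def _inputs(self):
        rows = []
        # p1: 3 natives + 1 non-native with basal areas 9.0 vs 1.0
        for i, (sp, dbh) in enumerate(
            [("N1_a", 40.0), ("N2_a", 40.0), ("N3_a", 20.0), ("X1_a", 20.0)]
        ):
            # tph chosen so that N basal areas sum to 9 and X to 1
            area_unit = math.pi * (dbh / 200.0) ** 2
            target = {0: 4.0, 1: 4.0, 2: 1.0, 3: 1.0}[i]
            rows.append(
                ("t%d" % i, "p1", 0.0, 0.0, sp, dbh, 10.0, target / area_unit, 2020)
            )
        # p2: only 2 species -> excluded
        rows += [
            ("t10", "p2", 1.0, 1.0, "N1_a", 20.0, 10.0, 10.0, 2020),
            ("t11", "p2", 1.0, 1.0, "N2_a", 20.0, 10.0, 10.0, 2020),
        ]
        records = pd.DataFrame(
            rows,
            columns=["tree_id", "plot_id", "lat", "lon", "species",
                     "dbh_cm", "height_m", "tph", "year"],
        )
        statuses = pd.DataFrame(
            {
                "species": ["N1_a", "N2_a", "N3_a", "X1_a"],
                "region_id": ["r"] * 4,
                "status": ["native", "native", "native", "non-native"],
            }
        )
        covariates = pd.DataFrame(
            {"plot_id": ["p1", "p2"], "region_id": ["r", "r"],
             "biome": ["b1", "b1"]}
        )
        return records, statuses, covariates

    def test_metrics_and_min_species(self):
        records, statuses, covariates = self._inputs()
        comms, metrics, drop_log = build_plot_communities(
            records, statuses, covariates
        )
        assert [c.plot_id for c in comms] == ["p1"]
        m = metrics.iloc[0]
        assert m["presence"]
        assert m["nn_species"] == 1
        assert m["rel_richness"] == pytest.approx(0.25)
        assert m["rel_abundance"] == pytest.approx(0.10)
        assert set(drop_log["reason"]) == {"min-species"}

    def test_presence_consistency(self, small_dataset):
        for c in small_dataset.communities:
            m = c.metrics()
            assert m["presence"] == (m["rel_richness"] > 0)
            assert m["presence"] == (m["rel_abundance"] > 0)

    def test_replicate_coordinates_collapsed(self):
        records, statuses, covariates = self._inputs()
        # clone p1 at identical coordinates with fewer stems
        clone = records[records["plot_id"] == "p1"].iloc[:3].copy()
        clone["plot_id"] = "p0"
        clone["tree_id"] = ["c1", "c2", "c3"]
        records = pd.concat([records, clone], ignore_index=True)
        covariates = pd.concat(
            [covariates, pd.DataFrame(
                {"plot_id": ["p0"], "region_id": ["r"], "biome": ["b1"]})],
            ignore_index=True,
        )
        comms, _, drop_log = build_plot_communities(records, statuses, covariates)
        assert [c.plot_id for c in comms] == ["p1"]  # p1 has more stems
        assert ("p0" == drop_log["plot_id"]).any()
        assert "collapsed" in set(drop_log["reason"])

    def test_missing_covariates_is_coverage_error(self):
        records, statuses, covariates = self._inputs()
        with pytest.raises(CoverageError):
            build_plot_communities(records, statuses, covariates.iloc[:1])


class TestDownsampling:
    def _plots(self, n_inv, n_uninv, biome="b1"):
        n = n_inv + n_uninv
        return pd.DataFrame(
            {
                "plot_id": [f"{biome}_{i}" for i in range(n)],
                "biome": [biome] * n,
                "presence": [True] * n_inv + [False] * n_uninv,
            }
        )

    def test_proportional_quotas(self):
        assert largest_remainder_quotas({"a": 0.7, "b": 0.3}, 100) == {
            "a": 70, "b": 30,
        }

    def test_largest_remainder_handles_fractions(self):
        quotas = largest_remainder_quotas({"a": 1, "b": 1, "c": 1}, 100)
        assert sum(quotas.values()) == 100
        assert sorted(quotas.values()) == [33, 33, 34]

    def test_half_cap_binding(self):
        plots = self._plots(80, 40)
        kept = downsample_by_biome(plots, {"b1": 1.0}, 60, seed=0)
        assert len(kept) == 60
        assert int(kept["presence"].sum()) == 30

    def test_half_cap_not_binding(self):
        plots = self._plots(10, 100)
        kept = downsample_by_biome(plots, {"b1": 1.0}, 60, seed=0)
        assert int(kept["presence"].sum()) == 10
        assert len(kept) == 60

    def test_invaded_fraction_invariant(self):
        rng = np.random.default_rng(0)
        plots = pd.concat(
            [
                self._plots(int(rng.integers(0, 40)), int(rng.integers(10, 60)),
                            biome=f"b{k}")
                for k in range(4)
            ],
            ignore_index=True,
        )
        areas = {f"b{k}": w for k, w in enumerate([0.4, 0.3, 0.2, 0.1])}
        kept = downsample_by_biome(plots, areas, 80, seed=1)
        for biome, grp in kept.groupby("biome"):
            quota = max(len(grp), 1)
            assert grp["presence"].mean() <= 0.5 + 1.0 / quota

    def test_seed_reproducibility(self):
        plots = self._plots(50, 200)
        a = downsample_by_biome(plots, {"b1": 1.0}, 100, seed=7)
        b = downsample_by_biome(plots, {"b1": 1.0}, 100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_target_below_biome_count_rejected(self):
        plots = pd.concat(
            [self._plots(1, 5, biome=f"b{k}") for k in range(3)],
            ignore_index=True,
        )
        with pytest.raises(InvalidArgumentError):
            downsample_by_biome(plots, {f"b{k}": 1.0 for k in range(3)}, 2, seed=0)
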