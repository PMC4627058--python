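"""Feature table assembly, group comparisons and regressions."""

import numpy as np
import pandas as pd
import pytest

from utrscape.stats import (
    build_feature_table,
    compare_groups,
    regress_expression,
    report,
    significance_stars,
    write_report,
)


@pytest.fixture(scope="module")
def table(sim_annotated, sim_dataset):
    return build_feature_table(
        sim_annotated,
        expression=sim_dataset.expression,
        mirnas=sim_dataset.mirnas,
    )


class TestFeatureTable:
    def test_one_row_per_complete_transcript(self, table, sim_annotated):
        usable = [t for t in sim_annotated if t.complete and not t.excluded]
        assert len(table) == len(usable)
        assert table["transcript_id"].is_unique

    def test_densities_consistent_with_counts(self, table):
        dens = 1000.0 * table["are_pentamer_count"] / table["utr3_len"]
        assert np.allclose(dens, table["are_pentamer_density"])

    def test_duplicate_transcripts_rejected(self, sim_annotated):
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(list(sim_annotated) + [sim_annotated[0]])

    def test_missing_expression_drops_row_with_warning(self, sim_annotated, sim_dataset):
        expr = sim_dataset.expression.iloc[:-3]
        with pytest.warns(UserWarning, match="dropped 3"):
            t = build_feature_table(sim_annotated, expression=expr)
        assert len(t) == len(sim_annotated) - 3

    def test_disjoint_expression_gives_empty_table(self, sim_annotated):
        expr = pd.DataFrame({"gene_id": ["zzz"], "fpkm": [1.0]})
        with pytest.warns(UserWarning):
            t = build_feature_table(sim_annotated, expression=expr)
        assert len(t) == 0


class TestGroupComparison:
    def test_identical_groups_not_significant(self, rng):
        vals = rng.normal(size=100)
        df = pd.DataFrame(
            {"group": ["a"] * 50 + ["b"] * 50, "x": np.concatenate([vals[:50], vals[:50]])}
        )
        cmp = compare_groups(df, "x")
        assert cmp.pairwise["p_value"].iloc[0] > 0.9
        s = cmp.summary.set_index("group")
        assert s.loc["a", "median"] == s.loc["b", "median"]

    def test_large_shift_highly_significant(self, rng):
        df = pd.DataFrame(
            {
                "group": ["a"] * 100 + ["b"] * 100,
                "x": np.concatenate([rng.normal(0, 1, 100), rng.normal(10, 1, 100)]),
            }
        )
        cmp = compare_groups(df, "x")
        assert cmp.pairwise["p_value"].iloc[0] < 1e-4
        assert cmp.pairwise["stars"].iloc[0] == "****"

    def test_utr3_length_contrast_recovered(self, table):
        # olfr-like group planted with shorter 3'UTRs than control
        cmp = compare_groups(table, "utr3_len")
        s = cmp.summary.set_index("group")
        assert s.loc["olfr", "median"] < s.loc["ctrl", "median"]
        assert cmp.pairwise["p_value"].iloc[0] < 1e-4

    def test_degenerate_all_ties_handled(self):
        df = pd.DataFrame({"group": ["a"] * 5 + ["b"] * 5, "x": [1.0] * 10})
        cmp = compare_groups(df, "x")
        assert cmp.pairwise["p_value"].iloc[0] == 1.0

    def test_small_group_rejected(self):
        df = pd.DataFrame({"group": ["a", "a", "a", "b", "b"], "x": range(5)})
        with pytest.raises(ValueError):
            compare_groups(df, "x")

    def test_star_tiers(self):
        assert [significance_stars(p) for p in (0.5, 0.04, 0.004, 4e-4, 4e-5)] == [
            "ns", "*", "**", "***", "****",
        ]


class TestRegression:
    def test_exact_linear_relationship(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame(
            {
                "group": "g",
                "gene_id": [f"g{i}" for i in range(10)],
                "fpkm": 10 ** (2 * x),
                "x": x,
            }
        )
        res = regress_expression(df, "x")
        assert res.slope == pytest.approx(2.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_nonpositive_fpkm_excluded(self):
        df = pd.DataFrame(
            {
                "group": "g",
                "gene_id": [f"g{i}" for i in range(6)],
                "fpkm": [1.0, 10.0, 100.0, 0.0, -5.0, 1000.0],
                "x": [0, 1, 2, 50, 60, 3],
            }
        )
        res = regress_expression(df, "x")
        assert res.n == 4 and res.slope == pytest.approx(1.0)

    def test_zero_variance_feature_rejected(self):
        df = pd.DataFrame(
            {"group": "g", "gene_id": list("abcd"), "fpkm": [1, 2, 3, 4], "x": 1.0}
        )
        with pytest.raises(ValueError, match="zero-variance"):
            regress_expression(df, "x")

    def test_gene_level_dedup_takes_max_expression_isoform(self):
        df = pd.DataFrame(
            {
                "group": "g",
                "gene_id": ["a", "a", "b", "c", "d"],
                "fpkm": [1.0, 100.0, 10.0, 5.0, 2.0],
                "x": [9.0, 2.0, 1.0, 0.7, 0.3],
            }
        )
        res = regress_expression(df, "x")
        assert res.n == 4  # one row per gene

    def test_permuted_feature_uncorrelated(self, table, rng):
        t = table.copy()
        t["shuffled"] = rng.permutation(t["are_pentamer_density"].to_numpy())
        res = regress_expression(t, "shuffled")
        assert abs(res.pearson_r) < 0.35


class TestReport:
    def test_medians_match_direct_recomputation(self, table):
        bundle = report(table)
        for g, sub in table.groupby("group"):
            assert bundle["groups"][g]["median_utr3_len"] == pytest.approx(
                float(sub["utr3_len"].median())
            )
            assert bundle["groups"][g]["pct_with_uorf"] == pytest.approx(
                100 * sub["has_uorf"].mean()
            )

    def test_empty_sections_are_valid(self, table, tmp_path):
        bundle = report(table, comparisons=(), regressions={})
        assert bundle["comparisons"] == [] and bundle["regressions"] == {}
        write_report(bundle, tmp_path / "r.json")
        assert (tmp_path / "r.json").read_text().startswith("{")

    def test_report_serialisation_deterministic(self, table, tmp_path):
        cmp = compare_groups(table, "utr3_len")
        reg = {"olfr:are": regress_expression(table, "are_pentamer_density", group="olfr")}
        b1 = report(table, [cmp], reg)
        b2 = report(table, [cmp], reg)
        write_report(b1, tmp_path / "a.json")
        write_report(b2, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
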