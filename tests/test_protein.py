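import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granulecall.io import ValidationError
from granulecall.protein import (
    FLAG_IMPUTED_BASEMENT,
    FLAG_IMPUTED_NN,
    FLAG_OBSERVED,
    ProteinQuantTable,
    adjust_benjamini_hochberg,
    adjust_benjamini_yekutieli,
    classify_protein_components,
    filter_unreliable_proteins,
    global_proteome_de,
    impute_ibaq,
    mean_normalize,
    rapms_enrichment,
)

from conftest import make_protein_table, make_sheet
from oracles import brute_protein_calls

NA = np.nan


def wt_sheet(replicates=3):
    return make_sheet(genotypes=("wildtype",), replicates=replicates)


def full_sheet(replicates=3):
    return make_sheet(replicates=replicates)


class TestImputeIbaq:
    def test_single_missing_filled_from_nearest_replicate(self):
        # Columns r2 and r3 are near-identical; r1 is far from both, so the
        # missing r2 value of p0 must come from r3 (12.0), not r1 (10.0).
        sheet = make_sheet(genotypes=("wildtype",), fractions=("tissue_lysate",))
        table = make_protein_table(
            {
                "wildtype_tissue_lysate_r1": [10.0, 20.0, 21.0, 22.0],
                "wildtype_tissue_lysate_r2": [NA, 25.0, 26.0, 27.0],
                "wildtype_tissue_lysate_r3": [12.0, 25.1, 26.1, 27.1],
            },
            sheet,
        )
        out = impute_ibaq(table)
        assert out.values.loc["p0", "wildtype_tissue_lysate_r2"] == 12.0
        assert out.flags.loc["p0", "wildtype_tissue_lysate_r2"] == FLAG_IMPUTED_NN

    def test_two_missing_get_basement_value(self):
        sheet = make_sheet(genotypes=("wildtype",), fractions=("tissue_lysate",))
        table = make_protein_table(
            {
                "wildtype_tissue_lysate_r1": [10.0, 15.0],
                "wildtype_tissue_lysate_r2": [NA, 15.0],
                "wildtype_tissue_lysate_r3": [NA, 15.0],
            },
            sheet,
        )
        out = impute_ibaq(table, basement_value=8.0)
        assert out.values.loc["p0", "wildtype_tissue_lysate_r2"] == 8.0
        assert out.values.loc["p0", "wildtype_tissue_lysate_r3"] == 8.0
        assert (out.flags.loc["p0"] == [FLAG_OBSERVED, FLAG_IMPUTED_BASEMENT,
                                        FLAG_IMPUTED_BASEMENT]).all()

    def test_complete_table_unchanged_and_observed_never_altered(self):
        sheet = full_sheet()
        rng = np.random.default_rng(0)
        table = make_protein_table(
            {s: rng.normal(15, 2, 5) for s in sheet["sample_id"]}, sheet
        )
        out = impute_ibaq(table)
        pd.testing.assert_frame_equal(out.values, table.values)
        assert (out.flags == FLAG_OBSERVED).all(axis=None)

    def test_observed_cells_preserved_under_imputation(self):
        sheet = full_sheet()
        rng = np.random.default_rng(1)
        vals = {s: rng.normal(15, 2, 20) for s in sheet["sample_id"]}
        table = make_protein_table(vals, sheet)
        table.values[rng.random(table.values.shape) < 0.2] = np.nan
        table = ProteinQuantTable(table.values, None, sheet)  # rebuild flags
        out = impute_ibaq(table)
        observed = table.values.notna()
        pd.testing.assert_frame_equal(out.values[observed], table.values[observed])
        assert not out.values.isna().any().any()

    def test_condition_with_single_replicate_raises(self):
        sheet = make_sheet(genotypes=("wildtype",), fractions=("tissue_lysate",),
                           replicates=1)
        table = make_protein_table({"wildtype_tissue_lysate_r1": [10.0]}, sheet)
        with pytest.raises(ValidationError, match="fewer than 2"):
            impute_ibaq(table)


class TestReliabilityFilters:
    def _table(self, values):
        return make_protein_table(values, full_sheet())

    def test_rule_i_wildtype_pair_missing_in_both_fractions(self):
        vals = {s: [15.0, 15.0] for s in full_sheet()["sample_id"]}
        vals["wildtype_granules_1_r2"] = [NA, 15.0]
        vals["wildtype_tissue_lysate_r2"] = [NA, 15.0]
        out, log = filter_unreliable_proteins(impute_ibaq(self._table(vals)))
        assert list(out.protein_ids) == ["p1"]
        assert log.to_dict("records") == [{"protein_id": "p0", "rule": "i"}]

    def test_rule_ii_imputed_replicate_with_opposite_trend(self):
        vals = {s: [15.0] for s in full_sheet()["sample_id"]}
        # wildtype fully observed replicates 1,2: granule > lysate
        vals["wildtype_granules_1_r1"] = [18.0]
        vals["wildtype_granules_1_r2"] = [18.0]
        vals["wildtype_tissue_lysate_r1"] = [15.0]
        vals["wildtype_tissue_lysate_r2"] = [15.0]
        # replicate 3: granule missing; NN imputation will copy a value that
        # leaves granule < lysate there
        vals["wildtype_granules_1_r3"] = [NA]
        vals["wildtype_tissue_lysate_r3"] = [19.0]
        table = impute_ibaq(self._table(vals))
        assert table.flags.loc["p0", "wildtype_granules_1_r3"] == FLAG_IMPUTED_NN
        assert (
            table.values.loc["p0", "wildtype_granules_1_r3"]
            < table.values.loc["p0", "wildtype_tissue_lysate_r3"]
        )
        out, log = filter_unreliable_proteins(table)
        assert len(out.protein_ids) == 0
        assert log["rule"].tolist() == ["ii"]

    def test_concordant_fully_observed_protein_retained(self):
        vals = {s: [16.0 if "granules" in s else 14.0] for s in full_sheet()["sample_id"]}
        out, log = filter_unreliable_proteins(impute_ibaq(self._table(vals)))
        assert list(out.protein_ids) == ["p0"]
        assert log.empty


class TestMeanNormalize:
    def test_output_columns_centered(self):
        sheet = full_sheet()
        rng = np.random.default_rng(2)
        table = make_protein_table({s: rng.normal(15, 2, 50) for s in sheet["sample_id"]}, sheet)
        out = mean_normalize(table)
        assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-9)

    def test_idempotent_and_shift_invariant(self):
        sheet = full_sheet()
        rng = np.random.default_rng(3)
        table = make_protein_table({s: rng.normal(0, 1, 10) for s in sheet["sample_id"]}, sheet)
        centered = mean_normalize(table)
        twice = mean_normalize(centered)
        pd.testing.assert_frame_equal(centered.values, twice.values)
        shifted = table.copy()
        shifted.values[shifted.values.columns[0]] += 3.7
        pd.testing.assert_frame_equal(mean_normalize(shifted).values, centered.values)


class TestClassifyProteinComponents:
    def _table(self, lfc_wt, lfc_mut, mut_missing=False):
        vals = {}
        for s in full_sheet()["sample_id"]:
            base = 10.0
            if "granules" in s:
                base += lfc_wt if s.startswith("wildtype") else lfc_mut
            vals[s] = [NA if (mut_missing and s.startswith("mutant")) else base]
        return make_protein_table(vals, full_sheet())

    def test_delta_route(self):
        calls = classify_protein_components(self._table(6.0, 1.0))
        assert calls["called"].iloc[0] and calls["route"].iloc[0] == "delta_ge_4.8"

    def test_delta_exactly_at_threshold_is_called(self):
        calls = classify_protein_components(self._table(5.8, 1.0))
        assert calls["called"].iloc[0]  # "at least 4.8" is inclusive

    def test_absent_in_mutant_route_requires_positive_wildtype_lfc(self):
        up = classify_protein_components(self._table(0.3, 0.0, mut_missing=True))
        assert up["called"].iloc[0] and up["route"].iloc[0] == "absent_in_mutant"
        down = classify_protein_components(self._table(-0.2, 0.0, mut_missing=True))
        assert not down["called"].iloc[0]

    def test_agrees_with_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        sheet = full_sheet()
        sample_rows = [tuple(r) for r in sheet.itertuples(index=False)]
        for _ in range(200):
            n = 8
            vals = {s: rng.uniform(0, 20, n) for s in sheet["sample_id"]}
            table = make_protein_table(vals, sheet)
            # random missingness pattern, incl. some all-mutant-missing rows
            miss = rng.random(table.values.shape) < 0.15
            mut_cols = [i for i, s in enumerate(table.values.columns) if s.startswith("mutant")]
            for row in rng.choice(n, 2, replace=False):
                miss[row, mut_cols] = True
            flags = np.where(miss, "imputed_basement", "observed")
            table = ProteinQuantTable(
                table.values,
                pd.DataFrame(flags, index=table.values.index, columns=table.values.columns),
                sheet,
            )
            got = classify_protein_components(table).set_index("protein_id")
            expected = brute_protein_calls(
                {p: dict(table.values.loc[p]) for p in table.protein_ids},
                {p: {s: not m for s, m in zip(table.values.columns, miss[i])}
                 for i, p in enumerate(table.protein_ids)},
                sample_rows,
            )
            for pid, (called, route) in expected.items():
                assert bool(got.loc[pid, "called"]) == called
                assert got.loc[pid, "route"] == route

    def test_row_order_never_affects_calls(self):
        rng = np.random.default_rng(5)
        sheet = full_sheet()
        table = make_protein_table({s: rng.uniform(0, 20, 12) for s in sheet["sample_id"]}, sheet)
        base = classify_protein_components(table)
        perm = rng.permutation(len(table.values))
        shuffled = ProteinQuantTable(table.values.iloc[perm], table.flags.iloc[perm], sheet)
        pd.testing.assert_frame_equal(base, classify_protein_components(shuffled))


class TestGlobalProteomeDe:
    def _lysate_table(self, wt_vals, mut_vals):
        sheet = make_sheet(fractions=("tissue_lysate",))
        vals = {}
        for s in sheet["sample_id"]:
            rep = int(s[-1]) - 1
            vals[s] = [wt_vals[rep] if s.startswith("wildtype") else mut_vals[rep]]
        return make_protein_table(vals, sheet)

    def test_matches_hand_computed_pooled_t(self):
        """Groups [1,2,3] vs [3,4,5]: pooled t = -2.449, df = 4, p = 0.0705."""
        de = global_proteome_de(self._lysate_table([1.0, 2.0, 3.0], [3.0, 4.0, 5.0]))
        assert de["log2fc"].iloc[0] == pytest.approx(-2.0)
        assert de["t_statistic"].iloc[0] == pytest.approx(-2.449, abs=1e-3)
        assert de["p_value"].iloc[0] == pytest.approx(0.0705, abs=2e-4)
        assert not de["significant"].iloc[0]

    def test_identical_groups_not_significant(self):
        de = global_proteome_de(self._lysate_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert de["log2fc"].iloc[0] == 0.0
        assert de["p_value"].iloc[0] == 1.0
        assert not de["significant"].iloc[0]

    def test_zero_variance_unequal_means_reports_p_zero(self, caplog):
        with caplog.at_level("WARNING"):
            de = global_proteome_de(self._lysate_table([2.0, 2.0, 2.0], [5.0, 5.0, 5.0]))
        assert de["p_value"].iloc[0] == 0.0
        assert "zero variance" in caplog.text

    def test_significance_needs_both_p_and_lfc(self):
        table = self._lysate_table([10.0, 10.1, 9.9], [10.4, 10.5, 10.3])
        de = global_proteome_de(table)  # |lfc| = 0.4 < 0.5 despite tiny p
        assert de["p_value"].iloc[0] < 0.05
        assert not de["significant"].iloc[0]


class TestMultipleTesting:
    def test_benjamini_yekutieli_hand_example(self):
        adj = adjust_benjamini_yekutieli([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.055, 0.055, 0.0733], atol=1e-3)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_by_dominates_bh_dominates_raw(self, pvals):
        p = np.asarray(pvals)
        bh = adjust_benjamini_hochberg(p)
        by = adjust_benjamini_yekutieli(p)
        assert (by >= bh - 1e-12).all()
        assert (bh >= p - 1e-12).all()
        assert (by <= 1.0 + 1e-12).all()


class TestRapmsEnrichment:
    def _values(self, rows, missing=()):
        df = pd.DataFrame(
            rows, columns=["x1", "x2", "x3", "c1", "c2", "c3"],
            index=[f"p{i}" for i in range(len(rows))], dtype=float,
        )
        for r, c in missing:
            df.iloc[r, c] = np.nan
        return df

    def test_insufficient_valid_values_excluded(self):
        rows = [[100, NA, NA, 200, NA, NA], [100, 110, 120, 200, 210, 220]]
        out = rapms_enrichment(self._values(rows), ["x1", "x2", "x3"], ["c1", "c2", "c3"])
        assert list(out["protein_id"]) == ["p1"]

    def test_complete_data_independent_of_seed(self):
        rng = np.random.default_rng(8)
        vals = self._values(rng.uniform(50, 500, (10, 6)))
        a = rapms_enrichment(vals, ["x1", "x2", "x3"], ["c1", "c2", "c3"], seed=1)
        b = rapms_enrichment(vals, ["x1", "x2", "x3"], ["c1", "c2", "c3"], seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_data_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        vals = self._values(rng.uniform(50, 500, (10, 6)))
        vals.iloc[0, 1] = np.nan
        vals.iloc[3, 4] = np.nan
        a = rapms_enrichment(vals, ["x1", "x2", "x3"], ["c1", "c2", "c3"], seed=5)
        b = rapms_enrichment(vals, ["x1", "x2", "x3"], ["c1", "c2", "c3"], seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = rapms_enrichment(vals, ["x1", "x2", "x3"], ["c1", "c2", "c3"], seed=6)
        assert not a["p_value"].equals(c["p_value"])

    def test_enrichment_requires_positive_direction(self):
        # p0 strongly higher in cross-linked, p1 strongly lower; with only
        # two proteins BY-adjusted p stays small for both.
        rows = [[800, 810, 790, 100, 105, 95], [100, 105, 95, 800, 810, 790]]
        out = rapms_enrichment(self._values(rows), ["x1", "x2", "x3"], ["c1", "c2", "c3"])
        out = out.set_index("protein_id")
        assert out.loc["p0", "log2fc"] > 0.5 and out.loc["p1", "log2fc"] < -0.5
        assert bool(out.loc["p0", "enriched"])
        assert not bool(out.loc["p1", "enriched"])

    def test_group_size_validation(self):
        vals = self._values([[1, 2, 3, 4, 5, 6]])
        with pytest.raises(ValidationError):
            rapms_enrichment(vals, ["x1"], ["c1", "c2"])
        with pytest.raises(ValidationError):
            rapms_enrichment(vals, ["x1", "x2"], ["x2", "c1"])
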