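import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import skincorrect as sc
from skincorrect.correction import STATUS_UNIQUE
from skincorrect.data_model import ValidationError

from conftest import swab_present_features


def two_group_table(swab_rows, water_rows, features):
    rows = swab_rows + water_rows
    ids = [f"sw{i}" for i in range(len(swab_rows))] + \
          [f"wa{i}" for i in range(len(water_rows))]
    table = sc.FeatureTable(pd.DataFrame(rows, index=ids, columns=features))
    meta = sc.validate_metadata(pd.DataFrame(
        {"sample_type": ["swab"] * len(swab_rows) + ["water"] * len(water_rows)},
        index=ids))
    return table, meta


class TestRelativeAbundance:
    def test_closed_forms(self):
        table = sc.FeatureTable(pd.DataFrame(
            [[2, 2], [5, 0]], index=["a", "b"], columns=["f1", "f2"]))
        rel = sc.relative_abundance(table)
        assert rel.loc["a"].tolist() == [0.5, 0.5]
        assert rel.loc["b"].tolist() == [1.0, 0.0]

    def test_zero_total_sample_errors(self):
        table = sc.FeatureTable(pd.DataFrame(
            [[0, 0]], index=["a"], columns=["f1", "f2"]))
        with pytest.raises(ValidationError):
            sc.relative_abundance(table)

    def test_rows_sum_to_one(self, sim_default):
        rel = sc.relative_abundance(sim_default.table)
        assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-12)


class TestMannWhitney:
    def test_exact_enumeration_value(self):
        """4-vs-3 with all x above all y: U = 12 and the one-sided p is the
        probability of the single most extreme arrangement, 1/C(7,3)."""
        u, p = sc.mann_whitney_greater([0.3, 0.4, 0.35, 0.5],
                                       [0.01, 0.02, 0.0])
        assert u == 12
        assert p == pytest.approx(1 / 35)

    def test_symmetric_null_not_significant(self):
        _, p = sc.mann_whitney_greater([1, 2, 3], [1, 2, 3])
        assert p >= 0.5

    def test_u_plus_u_prime_identity(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(6), rng.random(5)
        u1, _ = sc.mann_whitney_greater(x, y)
        u2, _ = sc.mann_whitney_greater(y, x)
        assert u1 + u2 == pytest.approx(len(x) * len(y))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            sc.mann_whitney_greater([], [1.0])


class TestBHAdjust:
    def test_hand_worked_step_up(self):
        q = sc.bh_adjust([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(q, [0.04, 0.04, 0.05, 0.05])

    def test_single_p_unchanged(self):
        assert sc.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_unchanged(self):
        assert np.allclose(sc.bh_adjust([0.2] * 5), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sc.bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_matches_statsmodels_and_bounds(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = sc.bh_adjust(pvals)
        _, q_ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(q, q_ref)
        assert ((q >= np.asarray(pvals) - 1e-12) & (q <= 1)).all()


class TestCorrect:
    def test_unique_to_swab_retained(self):
        table, meta = two_group_table(
            [[10, 5], [8, 7]], [[0, 9], [0, 11]], ["only_swab", "everywhere"])
        result, corrected = sc.correct(table, meta)
        rec = result.per_feature.loc["only_swab"]
        assert rec["status"] == STATUS_UNIQUE and rec["retained"]
        assert "only_swab" in corrected.feature_ids

    def test_identical_distribution_removed(self):
        table, meta = two_group_table(
            [[5, 5], [5, 5], [5, 5]], [[5, 5], [5, 5], [5, 5]], ["f1", "f2"])
        result, _ = sc.correct(table, meta)
        assert not result.per_feature["retained"].any()

    def test_no_water_samples_instructs_skip(self):
        table = sc.FeatureTable(pd.DataFrame(
            [[1]], index=["s"], columns=["f"]))
        meta = sc.validate_metadata(pd.DataFrame(
            {"sample_type": ["swab"]}, index=["s"]))
        with pytest.raises(ValidationError, match="skip"):
            sc.correct(table, meta)

    def test_corrected_table_scope(self, sim_default):
        result, corrected = sc.correct(sim_default.table,
                                       sim_default.metadata)
        swabs = set(sim_default.metadata.index[
            sim_default.metadata["sample_type"] == "swab"])
        assert set(corrected.sample_ids) == swabs
        assert set(corrected.feature_ids) <= set(sim_default.table.feature_ids)
        assert set(corrected.feature_ids) == set(result.retained_features)

    def test_faith_pd_never_increases_under_correction(self, sim_default):
        _, corrected = sc.correct(sim_default.table, sim_default.metadata)
        raw_pd = sc.faith_pd_table(
            sim_default.table.select_samples(corrected.sample_ids),
            sim_default.tree)
        cor_pd = sc.faith_pd_table(corrected, sim_default.tree)
        assert (cor_pd <= raw_pd + 1e-12).all()

    def test_scale_invariance(self, sim_default):
        table = sim_default.table
        doubled = sc.FeatureTable(table.counts * 2)
        r1, _ = sc.correct(table, sim_default.metadata)
        r2, _ = sc.correct(doubled, sim_default.metadata)
        assert r1.retained_features == r2.retained_features
        pd.testing.assert_series_equal(r1.per_feature["p_value"],
                                       r2.per_feature["p_value"])

    def test_recovery_on_simulated_truth(self, sim_default):
        result, _ = sc.correct(sim_default.table, sim_default.metadata)
        sens, spec = sc.truth_recovery_score(
            result, sim_default.truth, swab_present_features(sim_default))
        assert sens == pytest.approx(1.0)
        assert spec > 0.7

    def test_transformer_interface(self, sim_default):
        from sklearn.base import clone

        est = sc.BackgroundCorrector(alpha=0.01)
        assert clone(est).get_params()["alpha"] == 0.01
        y = sim_default.metadata.loc[sim_default.table.sample_ids,
                                     "sample_type"]
        out = est.fit_transform(sim_default.table.counts, y)
        assert list(out.columns) == est.retained_features_
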