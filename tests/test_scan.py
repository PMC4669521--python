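"""Association scan: masking, imputation, per-site OLS, FDR, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import random_matrix
from epiclock.errors import ValidationError
from epiclock.matrix import MethylationMatrix
from epiclock.scan import (
    ScanConfig,
    bh_fdr,
    island_enrichment,
    knn_impute,
    mask_low_detection,
    scan_associations,
    select_sites,
    site_regression,
)
from helpers import bh_stepup_reference, fisher_two_sided_enumeration


def make_matrix(values, aux=None, sites=None, samples=None, unit_interval=True):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    sites = sites or [f"cg{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=sites, columns=samples)
    aux_frame = None
    if aux is not None:
        aux_frame = pd.DataFrame(np.atleast_2d(np.asarray(aux, float)),
                                 index=sites, columns=samples)
    return MethylationMatrix(frame, aux_frame, unit_interval=unit_interval)


class TestMaskLowDetection:
    def test_all_good_detection_unchanged(self, small_matrix):
        out = mask_low_detection(small_matrix, 0.01)
        assert out.values.equals(small_matrix.values)

    def test_threshold_is_strict(self):
        m = make_matrix([[0.5, 0.5]], aux=[[0.01, 0.0100001]])
        out = mask_low_detection(m, 0.01)
        assert not np.isnan(out.values.iloc[0, 0])  # exactly 0.01 kept
        assert np.isnan(out.values.iloc[0, 1])

    def test_masked_count_matches_counting_oracle(self, rng):
        m = random_matrix(rng, n_sites=50, n_samples=20, missing_rate=0.0, with_aux=True)
        m = MethylationMatrix(m.values, m.aux / 100.0)  # aux in [0, 0.05]
        out = mask_low_detection(m, 0.01)
        expected = int((m.aux.to_numpy() > 0.01).sum())
        assert int(out.values.isna().to_numpy().sum()) == expected

    def test_requires_aux(self):
        m = make_matrix([[0.5]])
        with pytest.raises(ValidationError, match="aux"):
            mask_low_detection(m, 0.01)


class TestKnnImpute:
    def test_no_missing_is_identity(self, rng):
        m = random_matrix(rng, n_sites=10, n_samples=5, missing_rate=0.0)
        assert knn_impute(m, 3).values.equals(m.values)

    def test_identical_neighbours_fill_shared_value(self):
        vals = [[0.2, 0.4, 0.6], [0.2, 0.4, 0.6], [0.2, np.nan, 0.6]]
        out = knn_impute(make_matrix(vals), 2)
        assert out.values.iloc[2, 1] == pytest.approx(0.4)

    def test_k1_equals_nearest_row_by_bruteforce(self, rng):
        vals = rng.random((5, 4))
        vals[1, 2] = np.nan
        vals[4, 0] = np.nan
        m = make_matrix(vals)
        out = knn_impute(m, 1)
        for i, j in [(1, 2), (4, 0)]:
            # exhaustive distance computation over mutually observed columns
            best, best_d = None, np.inf
            for r in range(5):
                if r == i or np.isnan(vals[r, j]):
                    continue
                shared = ~(np.isnan(vals[r]) | np.isnan(vals[i]))
                d = ((vals[r, shared] - vals[i, shared]) ** 2).sum() * 4 / shared.sum()
                if d < best_d:
                    best, best_d = r, d
            assert out.values.iloc[i, j] == pytest.approx(vals[best, j])

    def test_observed_values_never_altered(self, rng):
        m = random_matrix(rng, n_sites=30, n_samples=8, missing_rate=0.2)
        out = knn_impute(m, 5)
        obs = ~m.values.isna()
        assert out.values[obs].equals(m.values[obs])
        assert not out.values.isna().to_numpy().any()

    def test_all_missing_site_is_error(self):
        vals = [[0.1, 0.2], [np.nan, np.nan], [0.3, 0.4]]
        with pytest.raises(ValidationError, match="cg1"):
            knn_impute(make_matrix(vals), 1)


class TestSiteRegression:
    def test_perfect_line_r_one_p_zero(self):
        ages = np.arange(20.0, 28.0)
        beta = 0.001 * ages + 0.1
        rec = site_regression(beta, ages)
        assert rec["R"] == pytest.approx(1.0)
        assert rec["R2"] == pytest.approx(1.0)
        assert rec["p"] == 0.0
        assert rec["slope"] == pytest.approx(0.001)

    def test_constant_beta_zero_variance_convention(self):
        rec = site_regression(np.full(5, 0.3), np.array([20, 30, 40, 50, 60.0]))
        assert rec["R"] == 0.0 and rec["p"] == 1.0 and rec["slope"] == 0.0
        assert rec["degenerate"]

    def test_matches_closed_form_ols_oracle(self):
        ages = np.array([20.0, 30.0, 40.0, 50.0])
        beta = np.array([0.10, 0.30, 0.20, 0.50])
        rec = site_regression(beta, ages)
        # normal equations by hand
        D = np.column_stack([np.ones(4), ages])
        coef = np.linalg.solve(D.T @ D, D.T @ beta)
        r_exp = np.corrcoef(ages, beta)[0, 1]
        t_exp = r_exp * np.sqrt(2 / (1 - r_exp**2))
        p_exp = 2 * stats.t.sf(abs(t_exp), df=2)
        assert rec["slope"] == pytest.approx(coef[1], abs=1e-12)
        assert rec["intercept"] == pytest.approx(coef[0], abs=1e-12)
        assert rec["R"] == pytest.approx(r_exp, abs=1e-12)
        assert rec["p"] == pytest.approx(p_exp, abs=1e-12)

    def test_agrees_with_scipy_linregress_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(4, 30)
            ages = rng.uniform(20, 80, n)
            beta = rng.random(n)
            rec = site_regression(beta, ages)
            ref = stats.linregress(ages, beta)
            assert rec["slope"] == pytest.approx(ref.slope, abs=1e-10)
            assert rec["R"] == pytest.approx(ref.rvalue, abs=1e-10)
            assert rec["p"] == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-12)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError, match="3"):
            site_regression(np.array([0.1, 0.2]), np.array([20.0, 30.0]))


class TestScanAssociations:
    def test_vectorised_path_matches_per_site_path(self, rng, tiny_meta):
        vals = rng.random((20, 3))
        m = make_matrix(vals, samples=["S1", "S2", "S3"],
                        sites=[f"cg{i}" for i in range(20)])
        table = scan_associations(m, tiny_meta)
        ages = np.array([25.0, 40.0, 60.0])
        for i in range(20):
            rec = site_regression(vals[i], ages)
            assert table["R"].iloc[i] == pytest.approx(rec["R"], abs=1e-12)
            assert table["p"].iloc[i] == pytest.approx(rec["p"], abs=1e-12)


class TestBhFdr:
    def test_hand_computed_example(self):
        q = bh_fdr([0.001, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.004, 0.04, 0.04, 0.5])

    def test_all_equal_p_map_to_same_q(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_textbook_reference_and_dominates_p(self, pvals):
        q = bh_fdr(pvals)
        assert np.allclose(q, bh_stepup_reference(pvals), atol=1e-12)
        assert (q >= np.asarray(pvals) - 1e-15).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_ref, atol=1e-12)


class TestSelectSites:
    def _records(self, rows):
        df = pd.DataFrame(rows, columns=["site_id", "p", "R2", "q", "slope"])
        return df

    def test_loose_boundary_strictness(self):
        records = self._records(
            [
                ["a", 0.009, 0.51, 0.5, 0.01],   # in
                ["b", 0.01, 0.51, 0.5, 0.01],    # p exactly at threshold: out
                ["c", 0.009, 0.50, 0.5, 0.01],   # R2 exactly at threshold: out
            ]
        )
        sel = select_sites(records)
        assert sel.loose == ["a"]

    def test_sign_split_counts(self):
        records = self._records(
            [
                ["a", 0.001, 0.9, 0.001, 0.02],
                ["b", 0.001, 0.9, 0.001, -0.02],
                ["c", 0.5, 0.1, 0.9, 0.0],
            ]
        )
        sel = select_sites(records)
        assert (sel.loose_positive, sel.loose_negative) == (1, 1)
        assert (sel.strict_positive, sel.strict_negative) == (1, 1)

    def test_selection_equals_bruteforce_refilter(self, rng):
        records = pd.DataFrame({
            "site_id": [f"cg{i}" for i in range(200)],
            "p": rng.random(200),
            "R2": rng.random(200),
            "q": rng.random(200),
            "slope": rng.normal(size=200),
        })
        sel = select_sites(records)
        expected = sorted(
            records.loc[(records.p < 0.01) & (records.R2 > 0.5), "site_id"]
        )
        assert sel.loose == expected
        assert sel.strict == sorted(records.loc[records.q < 0.01, "site_id"])


class TestIslandEnrichment:
    def test_null_case_p_near_one(self):
        ann = {f"s{i}": i % 2 == 0 for i in range(40)}
        selected = [f"s{i}" for i in range(10)]  # same 50% island rate
        table, p = island_enrichment(selected, ann, list(ann))
        assert p > 0.5

    def test_matches_hypergeometric_enumeration_oracle(self):
        ann = {}
        selected = []
        # build a universe realising the table [[8,2],[2,8]]
        for i in range(10):
            ann[f"sel{i}"] = i < 8
            selected.append(f"sel{i}")
        for i in range(10):
            ann[f"bg{i}"] = i < 2
        table, p = island_enrichment(selected, ann, list(ann))
        assert table.tolist() == [[8, 2], [2, 8]]
        assert p == pytest.approx(fisher_two_sided_enumeration([[8, 2], [2, 8]]), rel=1e-9)

    def test_row_label_swap_leaves_p_unchanged(self):
        ann = {f"s{i}": i % 3 == 0 for i in range(30)}
        sel = [f"s{i}" for i in range(12)]
        _, p1 = island_enrichment(sel, ann, list(ann))
        other = [s for s in ann if s not in sel]
        _, p2 = island_enrichment(other, ann, list(ann))
        assert p1 == pytest.approx(p2, rel=1e-9)
        assert 0 < p1 <= 1

    def test_empty_selection_is_error(self):
        with pytest.raises(ValidationError, match="empty"):
            island_enrichment([], {"a": True}, ["a"])

    def test_unannotated_site_is_error(self):
        with pytest.raises(ValidationError, match="unannotated"):
            island_enrichment(["a"], {"a": True}, ["a", "b"])


class TestScanRecovery:
    def test_planted_sites_recovered_and_background_rejected(self):
        """Strong planted trends pass the loose filter; background rarely does."""
        from epiclock.synthetic import simulate_discovery

        cohort, matrix, truth = simulate_discovery(seed=42, n_sites=2000, n_associated=100)
        masked = mask_low_detection(matrix, 0.01)
        imputed = knn_impute(masked, 10)
        records = scan_associations(imputed, cohort)
        sel = select_sites(records, ScanConfig())
        planted = set(truth.loc[truth["associated"], "site_id"])
        background = set(truth.loc[~truth["associated"], "site_id"])
        loose = set(sel.loose)
        recall = len(planted & loose) / len(planted)
        admitted = len(background & loose) / len(background)
        assert recall >= 0.9
        assert admitted <= 0.01
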