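"""Cluster phenotyping statistics and ROI hypometabolism models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import netstrat as ns
from netstrat.phenotype_profiling import roi_results_table


class TestChiSquare:
    @pytest.mark.parametrize("carriers,sizes,stat,pval", [
        # printed APOE carrier counts for the three dementia groups
        ((5, 3, 0), (11, 29, 2), 6.87, 0.0322),
        ((0, 10, 1), (11, 29, 2), 5.52, 0.0633),
        ((6, 15, 1), (11, 29, 2), 0.03, 0.9850),
        ((0, 1, 0), (11, 29, 2), 0.46, 0.7948),
    ])
    def test_reproduces_printed_contingency_statistics(self, carriers, sizes,
                                                       stat, pval):
        table = np.array([carriers,
                          [n - c for n, c in zip(sizes, carriers)]])
        s, p = ns.chi_square_categorical(table)
        assert round(s, 2) == stat
        assert round(p, 4) == pval

    def test_identical_proportions_zero_statistic(self):
        s, p = ns.chi_square_categorical([[10, 20, 30], [10, 20, 30]])
        assert s == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            ns.chi_square_categorical([[0, 0, 0], [5, 5, 5]])
        with pytest.raises(ValueError):
            ns.chi_square_categorical([[5, 0], [5, 0]])


class TestContinuousComparison:
    def test_identical_groups_zero_F(self):
        F, p, _ = ns.anova_tukey_continuous([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert F == pytest.approx(0.0)

    def test_matches_ssb_ssw_oracle(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0]),
                  np.array([5.0, 6.0, 7.0, 8.0])]
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        expect = (ssb / 2) / (ssw / (9 - 3))
        F, _, pairs = ns.anova_tukey_continuous(groups)
        assert F == pytest.approx(expect)
        assert len(pairs) == 3

    def test_tukey_two_groups_equals_pooled_t_test(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
        _, _, pairs = ns.anova_tukey_continuous([a, b])
        _, p_t = stats.ttest_ind(a, b)
        assert pairs[(0, 1)] == pytest.approx(p_t, abs=1e-7)

    def test_missing_group_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            F, p, _ = ns.anova_tukey_continuous(
                [[1.0, 2.0], [np.nan, np.nan], [3.0, 4.0]])
        assert np.isfinite(F)
        assert "excluded" in caplog.text


class TestSummaryTable:
    def test_stratum_sizes_and_columns(self, small_bundle):
        labels = small_bundle["truth"].labels
        tab = ns.summarize_cluster_phenotypes(
            small_bundle["phenotypes"], labels, "MCI")
        n_row = tab[tab.variable == "Number"].iloc[0]
        mci = small_bundle["phenotypes"]["diagnosis"] == "MCI"
        for c in np.unique(labels):
            assert n_row[f"cluster_{c}"] == int((mci & (labels == c)).sum())
        assert {"statistic", "p_value"} <= set(tab.columns)

    def test_planted_sex_imbalance_detected(self, rng):
        n = 300
        labels = np.repeat([0, 1], n // 2)
        sex = np.where(
            labels == 0,
            rng.choice(["F", "M"], n, p=[0.8, 0.2]),
            rng.choice(["F", "M"], n, p=[0.3, 0.7]),
        )
        pheno = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "diagnosis": "MCI", "sex": sex,
            "age": rng.normal(73, 7, n),
        })
        tab = ns.summarize_cluster_phenotypes(pheno, labels, "MCI")
        p = tab[tab.variable == "sex (F)"].iloc[0]["p_value"]
        assert p < 0.05

    def test_single_cluster_has_no_statistics(self, small_bundle):
        labels = np.zeros(len(small_bundle["phenotypes"]), dtype=int)
        tab = ns.summarize_cluster_phenotypes(
            small_bundle["phenotypes"], labels, "MCI")
        assert "statistic" not in tab.columns


class TestFDR:
    def test_step_up_example(self):
        adj = ns.fdr_adjust([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])

    def test_all_ones_and_singleton(self):
        assert np.allclose(ns.fdr_adjust([1.0, 1.0, 1.0]), 1.0)
        assert ns.fdr_adjust([0.37])[0] == pytest.approx(0.37)
        assert ns.fdr_adjust([]).size == 0

    def test_matches_step_up_definition(self, rng):
        p = rng.random(50)
        adj = ns.fdr_adjust(p)
        # independent step-up oracle
        m = len(p)
        order = np.argsort(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(stepped, 1.0)
        assert np.allclose(adj, expect, atol=1e-12)

    def test_monotone_and_never_below_raw(self, rng):
        p = rng.random(30)
        adj = ns.fdr_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def roi_table(offsets, slopes, n_per_group=60, n_controls=60, visits=(0.0,),
              noise=0.05, subj_sd=0.0, seed=0, roi="Angular_L"):
    """Single-ROI long table with planted cluster offsets and slopes."""
    rng = np.random.default_rng(seed)
    rows = []
    groups = ["control"] * n_controls
    for c in range(len(offsets)):
        groups += [f"cluster_{c + 1}"] * n_per_group
    for i, g in enumerate(groups):
        c = 0 if g == "control" else int(g.split("_")[1])
        off = 0.0 if g == "control" else offsets[c - 1]
        slope = 0.0 if g == "control" else slopes[c - 1]
        u = rng.normal(0, subj_sd)
        age = rng.normal(73, 7)
        sex = rng.choice(["F", "M"])
        for t in visits:
            rows.append((f"P{i:03d}", roi,
                         1.2 + off + slope * t + u + rng.normal(0, noise),
                         t, sex, age, g))
    return pd.DataFrame(rows, columns=["subject_id", "roi", "suvr",
                                       "time_years", "sex", "age", "group"])


class TestBaselineModel:
    def test_planted_offset_recovered_within_two_se(self):
        hits = 0
        for seed in range(20):
            obs = roi_table([-0.05], [0.0], n_per_group=100, n_controls=100,
                            seed=seed)
            res = ns.fit_roi_model_baseline(obs)
            r = next(x for x in res if x.cluster == "cluster_1")
            if abs(r.coefficient - (-0.05)) <= 2 * r.std_error:
                hits += 1
        assert hits >= 17

    def test_null_has_no_fdr_significant_rois(self):
        clean = 0
        for seed in range(20):
            frames = [roi_table([0.0], [0.0], n_per_group=40, n_controls=40,
                                seed=100 + seed, roi=f"ROI_{j}")
                      for j in range(6)]
            res = ns.fit_roi_model_baseline(pd.concat(frames))
            if not any(r.significant for r in res):
                clean += 1
        assert clean >= 18

    def test_constant_suvr_zero_coefficients(self):
        obs = roi_table([0.0], [0.0], noise=0.0, seed=1)
        res = ns.fit_roi_model_baseline(obs)
        assert all(abs(r.coefficient) < 1e-10 for r in res)

    def test_reduces_to_group_means_without_covariate_effects(self):
        obs = roi_table([-0.08], [0.0], noise=0.0, seed=2)
        res = ns.fit_roi_model_baseline(obs)
        r = next(x for x in res if x.cluster == "cluster_1")
        ctrl = obs[obs.group == "control"]["suvr"].mean()
        clus = obs[obs.group == "cluster_1"]["suvr"].mean()
        assert r.coefficient == pytest.approx(clus - ctrl, abs=1e-9)

    def test_sparse_roi_skipped(self, caplog):
        obs = roi_table([0.0], [0.0], n_per_group=3, n_controls=3, seed=3)
        with caplog.at_level("WARNING"):
            assert ns.fit_roi_model_baseline(obs) == []


class TestLongitudinalModel:
    def test_planted_interaction_recovered_within_two_se(self):
        hits = 0
        for seed in range(10):
            obs = roi_table([0.0], [-0.02], visits=(0.0, 1.0, 2.0),
                            n_per_group=75, n_controls=75, subj_sd=0.05,
                            seed=seed)
            res = ns.fit_roi_model_longitudinal(obs)
            r = next(x for x in res if x.cluster == "cluster_1")
            if abs(r.coefficient - (-0.02)) <= 2 * r.std_error:
                hits += 1
        assert hits >= 8

    def test_constant_time_rejected(self):
        obs = roi_table([0.0], [0.0], visits=(0.0,), seed=4)
        with pytest.raises(ValueError, match="constant"):
            ns.fit_roi_model_longitudinal(obs)

    def test_label_permutation_destroys_signal(self, rng):
        obs = roi_table([0.0], [-0.03], visits=(0.0, 1.0, 2.0),
                        n_per_group=50, n_controls=50, subj_sd=0.05, seed=5)
        assert any(r.significant for r in ns.fit_roi_model_longitudinal(obs))
        subjects = obs["subject_id"].unique()
        groups = [obs[obs.subject_id == s]["group"].iloc[0] for s in subjects]
        sig_counts = []
        for _ in range(8):
            perm = dict(zip(subjects, rng.permutation(groups)))
            shuffled = obs.assign(group=obs["subject_id"].map(perm))
            res = ns.fit_roi_model_longitudinal(shuffled)
            sig_counts.append(sum(r.significant for r in res))
        # permuted labels mix the two latent slope populations into both
        # groups, which a random-intercept-only model does not capture; its
        # SEs are mildly anticonservative there, so the count collapses
        # toward zero without vanishing exactly
        assert np.mean(sig_counts) <= 0.5

    def test_results_table_flags(self):
        obs = roi_table([-0.1], [-0.05], visits=(0.0, 1.0, 2.0),
                        n_per_group=60, n_controls=60, subj_sd=0.02, seed=6)
        tab = roi_results_table(ns.fit_roi_model_longitudinal(obs))
        sig = tab[tab.significant]
        assert (sig.fdr_p < 0.05).all()
        assert (tab.fdr_p >= tab.p - 1e-12).all()


def test_aal_vocabulary_has_116_regions():
    labels = ns.aal_labels()
    assert len(labels) == 116
    assert len(set(labels)) == 116
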