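import numpy as np
import pandas as pd
import pytest
from scipy import stats

import peptipanel as pp
from peptipanel.data import DataError


class TestAuc:
    def test_perfect_separation(self):
        assert pp.auc([2, 3], [0, 1]) == 1.0

    def test_pair_counting_example(self):
        # exhaustive pair counting: 0.9>0.85, 0.9>0.1, 0.8>0.1 -> 3/4
        assert pp.auc([0.9, 0.8], [0.85, 0.1]) == 0.75

    def test_all_ties(self):
        assert pp.auc([1, 1, 1], [1, 1]) == 0.5

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            cases = rng.integers(0, 5, size=8).astype(float)  # force ties
            controls = rng.integers(0, 5, size=9).astype(float)
            wins = sum(
                1.0 if c > d else 0.5 if c == d else 0.0
                for c in cases for d in controls
            )
            assert pp.auc(cases, controls) == pytest.approx(
                wins / (len(cases) * len(controls))
            )

    def test_complement_symmetry_tie_free(self):
        rng = np.random.default_rng(3)
        cases = rng.normal(1, 1, 10)
        controls = rng.normal(0, 1, 12)
        assert pp.auc(cases, controls) + pp.auc(controls, cases) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            pp.auc([], [1.0])

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(4)
        pts = pp.roc_points(rng.normal(1, 1, 20), rng.normal(0, 1, 25))
        assert (np.diff(pts["fpr"]) >= 0).all()
        assert (np.diff(pts["tpr"]) >= 0).all()


class TestDelong:
    def test_matches_pair_counting_auc(self):
        rng = np.random.default_rng(5)
        cases = rng.normal(0.8, 1, 15)
        controls = rng.normal(0, 1, 20)
        a, var = pp.evalstats.delong_variance(cases, controls)
        assert a == pytest.approx(pp.auc(cases, controls))
        assert var > 0

    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(6)
        labels = np.array([True] * 12 + [False] * 15)
        s = rng.normal(np.where(labels, 1.0, 0.0), 1.0)
        cmp = pp.delong_ci_and_test(s, s, labels)
        assert cmp.delta == 0.0
        assert cmp.p_difference == 1.0

    def test_ci_shrinks_toward_one_for_perfect_score(self):
        labels = np.array([True] * 200 + [False] * 200)
        s = np.where(labels, 1.0, 0.0) + np.linspace(0, 0.4, 400)
        a, ci = pp.delong_ci(s[labels], s[~labels])
        assert a == 1.0
        assert ci[0] > 0.99 and ci[1] == 1.0

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(7)
        cases = rng.normal(0.7, 1, 25)
        controls = rng.normal(0, 1, 30)
        a, ci = pp.delong_ci(cases, controls)
        assert ci[0] <= a <= ci[1]
        assert 0 <= ci[0] and ci[1] <= 1

    def test_agrees_with_bootstrap_oracle(self):
        # paired difference test vs a 10^4-resample bootstrap on 30 samples
        rng = np.random.default_rng(8)
        labels = np.array([True] * 14 + [False] * 16)
        latent = np.where(labels, 1.2, 0.0) + rng.normal(0, 1, 30)
        score_a = latent + rng.normal(0, 0.6, 30)
        score_b = rng.normal(0, 1, 30) + 0.3 * latent
        cmp = pp.delong_ci_and_test(score_a, score_b, labels)

        deltas = []
        idx_cases = np.flatnonzero(labels)
        idx_controls = np.flatnonzero(~labels)
        for _ in range(10_000):
            bc = rng.choice(idx_cases, size=idx_cases.size, replace=True)
            bn = rng.choice(idx_controls, size=idx_controls.size, replace=True)
            da = pp.auc(score_a[bc], score_a[bn]) - pp.auc(score_b[bc], score_b[bn])
            deltas.append(da)
        deltas = np.asarray(deltas)
        # normal-theory bootstrap p for H0: delta = 0
        z = cmp.delta / deltas.std(ddof=1)
        p_boot = 2 * stats.norm.sf(abs(z))
        assert abs(cmp.p_difference - p_boot) < 0.02

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(DataError):
            pp.delong_ci_and_test([1, 2], [1, 2, 3], [True, False, True])


class TestOperatingPoints:
    def test_paper_count_arithmetic(self):
        assert pp.sensitivity_percent(16, 19) == 84.2
        assert pp.specificity_percent(161, 170) == 94.7
        assert pp.specificity_percent(109, 110) == 99.1

    def test_rounding_is_half_up_compatible(self):
        for n_ok in range(0, 171):
            pct = pp.specificity_percent(n_ok, 170)
            assert pct == round(100 * n_ok / 170, 1)

    def test_operating_point(self):
        sens, spec = pp.operating_point([1.0, 2.0, -1.0], [-2.0, -3.0], 0.0)
        assert sens == pytest.approx(66.7)
        assert spec == 100.0


class TestIndependentSpecificity:
    @pytest.fixture
    def fitted_panel(self, separable_xy):
        X, y = separable_xy
        panel = pp.fit_svm(X, y, ["f1"])
        cutoff, _, _ = pp.youden_cutoff(
            panel.decision_scores(X)[y], panel.decision_scores(X)[~y]
        )
        panel.cutoff = cutoff
        return panel

    def test_low_intensity_controls_all_correct(self, fitted_panel):
        rng = np.random.default_rng(9)
        ds = pp.IntensityDataset(
            sample_ids=[f"n{i}" for i in range(50)],
            peptide_ids=["f1"],
            intensities=rng.lognormal(np.log(5), 0.2, size=(50, 1)),
            group=["NC"] * 50,
        )
        n_ok, n_tot, pct = pp.independent_specificity(fitted_panel, ds)
        assert (n_ok, n_tot, pct) == (50, 50, 100.0)

    def test_case_samples_rejected(self, fitted_panel):
        ds = pp.IntensityDataset(
            sample_ids=["x"],
            peptide_ids=["f1"],
            intensities=np.array([[1.0]]),
            group=["pFSGS"],
        )
        with pytest.raises(DataError):
            pp.independent_specificity(fitted_panel, ds)

    def test_percentage_matches_count_ratio(self, fitted_panel):
        rng = np.random.default_rng(10)
        ds = pp.IntensityDataset(
            sample_ids=[f"c{i}" for i in range(40)],
            peptide_ids=["f1"],
            intensities=rng.lognormal(np.log(60), 1.5, size=(40, 1)),
            group=["CKD_other"] * 40,
        )
        n_ok, n_tot, pct = pp.independent_specificity(fitted_panel, ds)
        assert pct == round(100 * n_ok / n_tot, 1)


class TestCovariableScreen:
    def _frame(self, seed, beta_score=1.5, n=500):
        rng = np.random.default_rng(seed)
        score = rng.normal(0, 1, n)
        sex = rng.choice(["M", "F"], size=n)
        age = rng.normal(50, 10, n)
        proteinuria = rng.lognormal(0.5, 0.7, n)
        egfr = rng.lognormal(4, 0.4, n)
        ifta = rng.uniform(0, 60, n)
        logit = -0.5 + beta_score * score
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        return pd.DataFrame(
            {"outcome": y.astype(float), "score": score, "sex": sex, "age": age,
             "proteinuria": proteinuria, "egfr": egfr, "ifta": ifta}
        )

    def test_parameter_recovery(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            model = pp.covariable_screen(self._frame(seed))
            beta = model.coefficients["score"]
            se = model.std_errors["score"]
            if abs(beta - 1.5) <= 2 * se:
                hits += 1
        assert hits / n_seeds >= 0.90

    def test_null_covariate_flat(self):
        # covariate identical across classes: negligible effect and no
        # significance (a constant column is collinear with the intercept,
        # so its Wald p is undefined rather than exactly 1)
        frame = self._frame(1)
        frame["age"] = 47.0
        model = pp.covariable_screen(frame)
        assert abs(model.coefficients["age"]) < 0.1
        p_age = model.p_values["age"]
        assert np.isnan(p_age) or p_age > 0.05

    def test_term_subset_contract(self):
        frame = self._frame(2)
        model = pp.covariable_screen(
            frame, terms=("score", "age", "proteinuria", "egfr", "ifta")
        )
        assert model.terms == ["score", "age", "proteinuria", "egfr", "ifta"]
        assert len([t for t in model.coefficients if t != "const"]) == 5

    def test_separation_flagged_penalized(self):
        frame = self._frame(3)
        frame["score"] = np.where(frame["outcome"] > 0, 10.0, -10.0)  # separable
        model = pp.covariable_screen(frame)
        assert model.penalized

    def test_too_few_events_rejected(self):
        frame = self._frame(4)
        frame["outcome"] = 0.0
        frame.loc[:4, "outcome"] = 1.0
        with pytest.raises(DataError):
            pp.covariable_screen(frame)


class TestNomogram:
    def test_uninformative_second_term(self):
        rng = np.random.default_rng(11)
        labels = np.array([True] * 100 + [False] * 100)
        score = np.where(labels, 1.0, 0.0) + rng.normal(0, 0.7, 200)
        proteinuria = rng.lognormal(0.5, 0.5, 200)  # identical distributions
        nomo = pp.build_nomogram(score, proteinuria, labels)
        assert abs(nomo.auc_combined - nomo.auc_score_alone) < 0.05

    def test_two_informative_predictors_combine(self):
        rng = np.random.default_rng(12)
        n = 2000
        labels = np.array([True] * (n // 2) + [False] * (n // 2))
        score = np.where(labels, 0.95, 0.0) + rng.normal(0, 1, n)      # AUC ~ .75
        proteinuria = np.where(labels, 0.95, 0.0) + rng.normal(0, 1, n)
        nomo = pp.build_nomogram(score, proteinuria, labels)
        assert nomo.auc_combined > nomo.auc_score_alone
        assert nomo.auc_combined > nomo.auc_proteinuria_alone

    def test_combined_never_much_below_best_single(self):
        rng = np.random.default_rng(13)
        for seed in range(5):
            r = np.random.default_rng(seed)
            labels = np.array([True] * 40 + [False] * 60)
            score = np.where(labels, 1.0, 0.0) + r.normal(0, 1, 100)
            prot = r.lognormal(np.where(labels, 1.2, 0.6), 0.8)
            nomo = pp.build_nomogram(score, prot, labels)
            best_single = max(nomo.auc_score_alone, nomo.auc_proteinuria_alone)
            assert nomo.auc_combined >= best_single - 0.02

    def test_delong_comparison_contract(self):
        rng = np.random.default_rng(14)
        labels = np.array([True] * 30 + [False] * 30)
        score = np.where(labels, 1.0, 0.0) + rng.normal(0, 1, 60)
        prot = rng.lognormal(0.5, 0.5, 60)
        nomo = pp.build_nomogram(score, prot, labels)
        assert 0.0 <= nomo.vs_score.p_difference <= 1.0
        assert 0.0 <= nomo.vs_proteinuria.p_difference <= 1.0

    def test_constant_predictor_rejected(self):
        labels = np.array([True, True, False, False])
        with pytest.raises(DataError):
            pp.build_nomogram([1, 2, 3, 4], [5, 5, 5, 5], labels)


class TestCohortTableStats:
    def test_nephrotic_range_proteinuria_table(self):
        # printed 2x2 counts: 14/19 cases vs 14/44 disease controls
        p = pp.cohort_table_stats("categorical", [[14, 5], [14, 30]])
        assert round(p, 4) == 0.0052

    def test_identical_proportions(self):
        assert pp.cohort_table_stats("categorical", [[10, 10], [10, 10]]) == 1.0

    @staticmethod
    def _exact_enumeration_p(table):
        """Oracle: conditional exact p — enumerate all tables with the
        observed margins, summing hypergeometric probabilities of tables
        whose Yates statistic is at least as extreme."""
        (a, b), (c, d) = table
        r1, r2, c1 = a + b, c + d, a + c
        n = r1 + r2

        def yates_stat(a_):
            t = np.array([[a_, r1 - a_], [c1 - a_, r2 - (c1 - a_)]], float)
            if (t < 0).any():
                return -1.0
            exp = np.outer(t.sum(1), t.sum(0)) / n
            return float(((np.clip(np.abs(t - exp) - 0.5, 0, None) ** 2) / exp).sum())

        obs = yates_stat(a)
        lo, hi = max(0, c1 - r2), min(r1, c1)
        return sum(
            stats.hypergeom.pmf(k, n, r1, c1)
            for k in range(lo, hi + 1)
            if yates_stat(k) >= obs - 1e-9
        )

    def test_yates_tracks_exact_enumeration(self):
        # The continuity-corrected chi-square approximates the conditional
        # exact test: mean absolute deviation small, worst case bounded.
        # (Worst-case agreement within 0.02 is not attainable for arbitrary
        # margins — the correction is conservative by design.)
        rng = np.random.default_rng(15)
        diffs = []
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(40, 120, 4))
            table = [[a, b], [c, d]]
            p_yates = pp.cohort_table_stats("categorical", table)
            diffs.append(abs(p_yates - self._exact_enumeration_p(table)))
        assert np.mean(diffs) < 0.02
        assert max(diffs) < 0.15

    def test_continuous_uses_t_test(self):
        rng = np.random.default_rng(16)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        assert pp.cohort_table_stats("continuous", a, b) == pytest.approx(
            stats.ttest_ind(a, b, equal_var=True).pvalue
        )

    def test_nonnormal_uses_rank_test(self):
        rng = np.random.default_rng(17)
        a, b = rng.lognormal(0, 1, 30), rng.lognormal(0.5, 1, 30)
        assert pp.cohort_table_stats("nonnormal", a, b) == pytest.approx(
            stats.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic").pvalue
        )

    def test_kind_mismatch_rejected(self):
        with pytest.raises(DataError):
            pp.cohort_table_stats("categorical", [[1, 2], [3, 4]], [1.0, 2.0])
        with pytest.raises(DataError):
            pp.cohort_table_stats("continuous", [[1, 2], [3, 4]])
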