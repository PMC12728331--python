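import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from interbrain.scores import PathModel, simulate_scores, simulate_structural
from interbrain.stats import (bh_fdr, cohens_d_from_t, cronbach_alpha,
                              freqwise_tests, levene, mixed_anova_2x2,
                              partial_eta_sq, pearson, serial_mediation,
                              simple_effects, t_test_auto)


def random_scores(rng, n1=20, n2=20, effect=0.0, sd=1.0):
    """Pre/post score table with a group-by-time interaction of ``effect``."""
    n = n1 + n2
    group = np.array(["real"] * n1 + ["sham"] * n2)
    pre = rng.normal(5, sd, n)
    post = pre + rng.normal(0.2, sd, n) + np.where(group == "real", effect, 0)
    return pd.DataFrame({"group": group, "sc_pre": pre, "sc_post": post})


class TestLevene:
    def test_identical_samples_have_equal_variance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        W, p = levene(x, x.copy())
        assert W == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_detects_fivefold_scale_difference(self):
        rng = np.random.default_rng(0)
        hits = sum(levene(rng.normal(0, 1, 50),
                          rng.normal(0, 5, 50))[1] < 0.05
                   for _ in range(200))
        assert hits >= 0.95 * 200

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 2, 40)
        W1, _ = levene(x, y)
        W2, _ = levene(10 * x, 10 * y)
        assert W1 == pytest.approx(W2)


class TestLeveneGatedTTest:
    def test_equal_samples_are_null(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        res = t_test_auto(x, x.copy())
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_cohens_d_from_t_worked_example(self):
        # two-group comparison with t(55) = 4.542, n = 28 and 29
        assert cohens_d_from_t(4.542, 28, 29) == pytest.approx(1.203,
                                                               abs=5e-4)

    def test_welch_selected_when_variances_differ(self):
        rng = np.random.default_rng(2)
        res = t_test_auto(rng.normal(0, 1, 40), rng.normal(0, 6, 40))
        assert res.variant == "welch"
        assert res.levene_p < 0.05
        assert res.df < 78  # Satterthwaite shrinks the df

    def test_student_when_variances_match(self):
        rng = np.random.default_rng(3)
        res = t_test_auto(rng.normal(0, 1, 40), rng.normal(0.5, 1, 40))
        assert res.variant == "student"
        assert res.df == 78

    def test_student_equals_welch_for_balanced_equal_variance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        student = sps.ttest_ind(x, y, equal_var=True)
        welch = sps.ttest_ind(x, y, equal_var=False)
        assert student.statistic == pytest.approx(welch.statistic)
        assert t_test_auto(x, y).t == pytest.approx(student.statistic)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            t_test_auto(np.ones(5), np.ones(5))


class TestFreqwise:
    def test_returns_one_result_per_bin(self):
        rng = np.random.default_rng(5)
        res = freqwise_tests(rng.normal(0, 1, (10, 30)),
                             rng.normal(0, 1, (12, 30)))
        assert len(res) == 30

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(100):
            res = freqwise_tests(rng.normal(0, 1, (15, 30)),
                                 rng.normal(0, 1, (15, 30)))
            pvals.extend(t.p for t in res)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_group_size_validated(self):
        with pytest.raises(ValueError):
            freqwise_tests(np.zeros((1, 30)), np.zeros((5, 30)))


class TestBHFDR:
    @staticmethod
    def brute_force_bh(p, q=0.05):
        """Textbook step-up: largest k with p_(k) <= k q / m."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        reject = np.zeros(m, dtype=bool)
        k_max = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * q / m:
                k_max = k
        reject[order[:k_max]] = True
        adj = np.empty(m)
        prev = 1.0
        for k in range(m, 0, -1):
            prev = min(prev, p[order[k - 1]] * m / k)
            adj[order[k - 1]] = prev
        return reject, adj

    def test_constant_small_pvalues_all_rejected(self):
        reject, _ = bh_fdr([0.01] * 30)
        assert reject.all()

    def test_hand_evaluated_example(self):
        _, adj = bh_fdr([0.001, 0.2, 0.9])
        assert np.allclose(adj, [0.003, 0.3, 0.9])

    def test_single_pvalue_unchanged(self):
        reject, adj = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert reject[0]

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 3)
            reject, adj = bh_fdr(p)
            bf_reject, bf_adj = self.brute_force_bh(p)
            assert np.array_equal(reject, bf_reject)
            assert np.allclose(adj, bf_adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestMixedAnova:
    def test_printed_eta_squared_pairings(self):
        pairs = [(18.992, 0.257), (5.695, 0.094), (29.253, 0.347),
                 (10.598, 0.162), (22.351, 0.289), (9.600, 0.149)]
        for F, expected in pairs:
            assert partial_eta_sq(F, 1, 55) == pytest.approx(expected,
                                                             abs=5e-4)

    def test_interaction_equals_squared_difference_score_t(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            df = random_scores(rng, n1=int(rng.integers(5, 30)),
                               n2=int(rng.integers(5, 30)),
                               effect=rng.normal())
            an = mixed_anova_2x2(df, "sc")
            d = (df["sc_post"] - df["sc_pre"]).to_numpy()
            g = df["group"] == "real"
            t = sps.ttest_ind(d[g], d[~g], equal_var=True).statistic
            assert an.effects["interaction"].F == pytest.approx(t ** 2,
                                                                abs=1e-8)

    def test_group_effect_equals_squared_t_on_dyad_means(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            df = random_scores(rng, n1=int(rng.integers(5, 30)),
                               n2=int(rng.integers(5, 30)),
                               effect=rng.normal())
            an = mixed_anova_2x2(df, "sc")
            m = ((df["sc_post"] + df["sc_pre"]) / 2).to_numpy()
            g = df["group"] == "real"
            t = sps.ttest_ind(m[g], m[~g], equal_var=True).statistic
            assert an.effects["group"].F == pytest.approx(t ** 2, abs=1e-8)

    def test_matches_pingouin_on_balanced_designs(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        df = random_scores(rng, n1=15, n2=15, effect=0.5)
        an = mixed_anova_2x2(df, "sc")
        long = pd.DataFrame({
            "dyad": list(range(30)) * 2,
            "group": df["group"].tolist() * 2,
            "time": ["pre"] * 30 + ["post"] * 30,
            "y": df["sc_pre"].tolist() + df["sc_post"].tolist()})
        ref = pg.mixed_anova(long, dv="y", within="time", subject="dyad",
                             between="group").set_index("Source")
        assert an.effects["group"].F == pytest.approx(
            ref.loc["group", "F"], rel=1e-9)
        assert an.effects["time"].F == pytest.approx(
            ref.loc["time", "F"], rel=1e-9)
        assert an.effects["interaction"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)

    def test_no_change_means_no_within_effects(self):
        rng = np.random.default_rng(11)
        df = random_scores(rng)
        df["sc_post"] = df["sc_pre"]
        an = mixed_anova_2x2(df, "sc")
        assert an.effects["time"].F == pytest.approx(0.0)
        assert an.effects["interaction"].F == pytest.approx(0.0)


class TestSimpleEffects:
    def test_changed_group_beats_flat_group(self):
        rng = np.random.default_rng(12)
        df = random_scores(rng, effect=1.5)
        eff = simple_effects(df, "sc")
        assert eff["real"].p < eff["sham"].p

    def test_pooled_error_degrees_of_freedom(self):
        rng = np.random.default_rng(13)
        df = random_scores(rng, n1=28, n2=29)
        eff = simple_effects(df, "sc")
        assert eff["real"].df2 == 55
        assert eff["sham"].df2 == 55

    def test_group_relabel_swaps_contrasts(self):
        rng = np.random.default_rng(14)
        df = random_scores(rng, effect=1.0)
        eff = simple_effects(df, "sc")
        swapped = df.assign(group=df["group"].map(
            {"real": "sham", "sham": "real"}))
        eff2 = simple_effects(swapped, "sc")
        assert eff["real"].F == pytest.approx(eff2["sham"].F)
        assert eff["sham"].F == pytest.approx(eff2["real"].F)


class TestPearsonAndAlpha:
    def test_perfect_and_affine_correlations(self):
        x = np.arange(10.0)
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -2 * x + 7)[0] == pytest.approx(-1.0)

    def test_sampling_distribution_at_rho_half(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(10_000)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(10_000)
        r, p = pearson(x, y)
        assert r == pytest.approx(0.5, abs=0.02)
        assert p < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(10), np.arange(10.0))

    def test_alpha_of_identical_items_is_one(self):
        x = np.random.default_rng(16).normal(5, 1, 200)
        items = np.column_stack([x, x, x, x])
        assert cronbach_alpha(items) == pytest.approx(1.0)

    def test_alpha_of_independent_items_vanishes(self):
        rng = np.random.default_rng(17)
        items = rng.normal(0, 1, (10_000, 4))
        assert abs(cronbach_alpha(items)) < 0.05

    def test_alpha_matches_spearman_brown_for_parallel_items(self):
        """Three parallel items with loading lambda on one factor and unit
        total variance: alpha = k rbar / (1 + (k-1) rbar), rbar=lambda^2."""
        lam = 0.7
        rng = np.random.default_rng(18)
        f = rng.standard_normal(20_000)
        items = np.column_stack([
            lam * f + np.sqrt(1 - lam ** 2) * rng.standard_normal(20_000)
            for _ in range(3)])
        rbar = lam ** 2
        expected = 3 * rbar / (1 + 2 * rbar)
        assert cronbach_alpha(items) == pytest.approx(expected, abs=0.02)

    def test_alpha_input_validated(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((5, 1)))


class TestSerialMediation:
    @staticmethod
    def unit_variance_model(n, seed):
        """a1=d21=b2=0.5 with residuals chosen so every variable has unit
        variance, making standardized and generating coefficients equal."""
        s = np.sqrt(0.75)
        return PathModel(a1=0.5, d21=0.5, b2=0.5,
                         residual_sds=(s, s, 1.0, s), n_dyads=n, seed=seed)

    def test_ols_decomposition_identity(self):
        rng = np.random.default_rng(19)
        V = rng.standard_normal((40, 5))
        med = serial_mediation(*V.T, n_boot=1000, seed=0)
        resid = med.paths["c"] - med.paths["c_prime"] - med.total_indirect
        assert abs(resid) < 1e-10

    def test_recovers_generating_chain(self):
        sem = simulate_structural(self.unit_variance_model(5000, 20))
        med = serial_mediation(sem.X, sem.M1, sem.M2, sem.M3, sem.Y,
                               n_boot=1000, seed=1)
        est = dict(zip(med.indirect["label"], med.indirect["estimate"]))
        assert est["X -> M1 -> M2 -> Y"] == pytest.approx(0.125, abs=0.02)
        for label, v in est.items():
            if label != "X -> M1 -> M2 -> Y":
                assert v == pytest.approx(0.0, abs=0.02)
        for name, target in (("a1", 0.5), ("d21", 0.5), ("b2", 0.5)):
            assert med.paths[name] == pytest.approx(target, abs=0.05)

    def test_seven_labelled_paths_and_reproducibility(self):
        rng = np.random.default_rng(21)
        V = rng.standard_normal((30, 5))
        med1 = serial_mediation(*V.T, n_boot=1000, seed=5)
        med2 = serial_mediation(*V.T, n_boot=1000, seed=5)
        assert len(med1.indirect) == 7
        assert np.array_equal(med1.indirect["ci_low"],
                              med2.indirect["ci_low"])

    def test_incomplete_dyads_dropped_with_warning(self):
        rng = np.random.default_rng(22)
        V = rng.standard_normal((30, 5))
        V[3, 2] = np.nan
        with pytest.warns(UserWarning, match="incomplete"):
            med = serial_mediation(*V.T, n_boot=1000, seed=2)
        assert med.n == 29

    def test_small_bootstrap_warns(self):
        rng = np.random.default_rng(23)
        V = rng.standard_normal((30, 5))
        with pytest.warns(UserWarning, match="n_boot"):
            serial_mediation(*V.T, n_boot=500, seed=3)

    def test_minimum_sample_enforced(self):
        rng = np.random.default_rng(24)
        V = rng.standard_normal((8, 5))
        with pytest.raises(ValueError, match="10"):
            serial_mediation(*V.T, n_boot=1000, seed=4)
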