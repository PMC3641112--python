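"""Moderated t-test, permutation machinery and selection rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rrtempo as rt
from rrtempo import diffexp as de
from rrtempo.containers import ExpressionMatrix


def _toy_matrix(xa: np.ndarray, xb: np.ndarray) -> ExpressionMatrix:
    """Wrap two unpaired arms as an M-vs-N1 design at T0."""
    na, nb = xa.shape[1], xb.shape[1]
    values = pd.DataFrame(
        np.hstack([xa, xb]),
        index=[f"G{i}" for i in range(len(xa))],
        columns=[f"M_P{j:02d}_T0" for j in range(na)]
        + [f"N1_S{j:02d}_T0" for j in range(nb)])
    meta = pd.DataFrame(
        {"subject": [f"P{j:02d}" for j in range(na)]
         + [f"S{j:02d}" for j in range(nb)],
         "group": ["M"] * na + ["N1"] * nb,
         "timepoint": ["T0"] * (na + nb)},
        index=values.columns)
    return ExpressionMatrix(values, meta)


def _paired_matrix(d_base: np.ndarray) -> ExpressionMatrix:
    """Design whose N1 T1-vs-T0 differences equal ``d_base`` exactly."""
    g, n = d_base.shape
    t0 = np.zeros((g, n))
    cols, vals, subj, tps = [], [], [], []
    for j in range(n):
        cols += [f"N1_S{j:02d}_T0", f"N1_S{j:02d}_T1"]
        subj += [f"S{j:02d}"] * 2
        tps += ["T0", "T1"]
    values = np.empty((g, 2 * n))
    values[:, 0::2] = t0
    values[:, 1::2] = d_base
    df = pd.DataFrame(values, index=[f"G{i}" for i in range(g)], columns=cols)
    meta = pd.DataFrame({"subject": subj, "group": ["N1"] * 2 * n,
                         "timepoint": tps}, index=cols)
    return ExpressionMatrix(df, meta)


def _ordinary_t(xa, xb):
    na, nb = xa.shape[1], xb.shape[1]
    s2 = ((na - 1) * xa.var(axis=1, ddof=1)
          + (nb - 1) * xb.var(axis=1, ddof=1)) / (na + nb - 2)
    return (xa.mean(1) - xb.mean(1)) / np.sqrt(s2 * (1 / na + 1 / nb))


class TestHyperparamFit:
    def test_self_consistency_recovery_within_20pct(self):
        rng = np.random.default_rng(0)
        a, b, nu = 3.0, 0.5, 4
        sigma2 = 1.0 / rng.gamma(a, 1.0 / b, 5000)
        s2 = sigma2 * rng.chisquare(nu, 5000) / nu
        hp = de.fit_rvm_hyperparams(s2, nu)
        assert abs(hp.a - a) / a < 0.20
        assert abs(hp.b - b) / b < 0.20

    def test_equal_variances_push_shape_to_cap(self):
        s2 = np.full(200, 1.7)
        hp = de.fit_rvm_hyperparams(s2, 5)
        assert hp.a == de.A_MAX
        shrunk = hp.shrink(np.array([0.1, 1.7, 40.0]))
        assert np.allclose(shrunk, shrunk[0], rtol=1e-3)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        sigma2 = 1.0 / rng.gamma(3.0, 2.0, 3000)
        s2 = sigma2 * rng.chisquare(6, 3000) / 6
        hp1 = de.fit_rvm_hyperparams(s2, 6)
        hp2 = de.fit_rvm_hyperparams(4.0 * s2, 6)
        assert hp2.a == pytest.approx(hp1.a, rel=0.02)
        assert hp2.b == pytest.approx(4.0 * hp1.b, rel=0.02)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            de.fit_rvm_hyperparams(np.ones(10), 4)

    def test_shrinkage_dominates_sample_variance(self):
        """MSE of the shrunken variance beats the raw sample variance."""
        rng = np.random.default_rng(2)
        a, b, nu = 3.0, 0.5, 4
        sigma2 = 1.0 / rng.gamma(a, 1.0 / b, 5000)
        s2 = sigma2 * rng.chisquare(nu, 5000) / nu
        hp = de.fit_rvm_hyperparams(s2, nu)
        mse_shrunk = np.mean((hp.shrink(s2) - sigma2) ** 2)
        mse_raw = np.mean((s2 - sigma2) ** 2)
        assert mse_shrunk <= mse_raw


class TestModeratedT:
    def test_identical_arms_give_zero_t_unit_p(self):
        x = np.tile([[1.0, 2.0, 3.0]], (4, 1))
        m = _toy_matrix(x, x)
        hp = de.RVMHyperparams(2.0, 1.0, 4)
        res = de.rvm_t_test(m, de.ComparisonSpec.across("M", "N1", "T0"), hp)
        assert np.allclose(res["t"], 0.0)
        assert np.allclose(res["p_param"], 1.0)

    def test_vanishing_prior_recovers_ordinary_t(self):
        """a, b -> 0: shrinkage disappears and t matches the textbook
        pooled two-sample statistic to 1e-9."""
        rng = np.random.default_rng(3)
        xa, xb = rng.normal(0, 1, (5, 3)), rng.normal(0.5, 1, (5, 3))
        m = _toy_matrix(xa, xb)
        hp = de.RVMHyperparams(1e-12, 1e-12, 4)
        res = de.rvm_t_test(m, de.ComparisonSpec.across("M", "N1", "T0"), hp)
        assert np.abs(res["t"].to_numpy() - _ordinary_t(xa, xb)).max() < 1e-9

    def test_zero_variance_paired_differences_still_finite(self):
        d = np.array([[1.0, 1.0]])
        m = _paired_matrix(d)
        hp = de.RVMHyperparams(2.0, 0.5, 1)
        res = de.rvm_t_test(m, de.ComparisonSpec.within("N1", "T1", "T0"), hp)
        assert np.isfinite(res["t"]).all()
        assert res["t"].iloc[0] > 0

    def test_orphan_subjects_dropped_then_error_when_too_few(self):
        d = np.array([[1.0, 2.0, 3.0]])
        m = _paired_matrix(d)
        # drop one subject's T1 sample -> still 2 matched pairs: works
        keep = [c for c in m.values.columns if c != "N1_S02_T1"]
        sub = ExpressionMatrix(m.values[keep], m.samples.loc[keep])
        hp = de.RVMHyperparams(2.0, 0.5, 1)
        res = de.rvm_t_test(sub, de.ComparisonSpec.within("N1", "T1", "T0"), hp)
        assert len(res) == 1
        # only one complete pair left -> error naming orphans
        keep2 = [c for c in keep if c != "N1_S01_T1"]
        sub2 = ExpressionMatrix(m.values[keep2], m.samples.loc[keep2])
        with pytest.raises(de.ContrastError, match="orphans"):
            de.rvm_t_test(sub2, de.ComparisonSpec.within("N1", "T1", "T0"), hp)


class TestPermutations:
    def test_unpaired_exhaustive_matches_brute_force(self):
        """3-vs-3 toy: enumeration over all 20 label splits, compared to a
        hand-rolled oracle that re-derives the moderated t from scratch."""
        rng = np.random.default_rng(4)
        xa, xb = rng.normal(1, 1, (6, 3)), rng.normal(0, 1, (6, 3))
        m = _toy_matrix(xa, xb)
        hp = de.RVMHyperparams(1.5, 0.8, 4)
        res = de.permutation_pvalues(
            m, de.ComparisonSpec.across("M", "N1", "T0"), hp, 100, seed=0)
        assert res.attrs["exact_enumeration"]

        def mod_t(ya, yb):
            s2 = (2 * ya.var(ddof=1) + 2 * yb.var(ddof=1)) / 4
            shrunk = (4 * s2 + 2 * 0.8) / (4 + 2 * 1.5)
            return (ya.mean() - yb.mean()) / np.sqrt(shrunk * (2 / 3))

        pooled = np.hstack([xa, xb])
        for i in range(6):
            obs = abs(mod_t(xa[i], xb[i]))
            cnt = 0
            for combo in itertools.combinations(range(6), 3):
                sel = np.zeros(6, bool)
                sel[list(combo)] = True
                cnt += abs(mod_t(pooled[i, sel], pooled[i, ~sel])) >= obs - 1e-12
            assert res["p_perm"].iloc[i] == pytest.approx(cnt / 20, abs=0)

    def test_paired_exhaustive_matches_sign_flip_brute_force(self):
        """n = 6 subjects: oracle enumerates all 2^6 sign vectors."""
        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 1, (5, 6))
        m = _paired_matrix(d)
        hp = de.RVMHyperparams(1.2, 0.6, 5)
        res = de.permutation_pvalues(
            m, de.ComparisonSpec.within("N1", "T1", "T0"), hp, 64, seed=0)
        assert res.attrs["exact_enumeration"]

        def mod_t(y):
            shrunk = (5 * y.var(ddof=1) + 2 * 0.6) / (5 + 2 * 1.2)
            return y.mean() / np.sqrt(shrunk / 6)

        for i in range(5):
            obs = abs(mod_t(d[i]))
            cnt = 0
            for signs in itertools.product([-1, 1], repeat=6):
                cnt += abs(mod_t(d[i] * np.array(signs))) >= obs - 1e-12
            assert res["p_perm"].iloc[i] == pytest.approx(cnt / 64, abs=0)

    def test_same_seed_identical_p(self, small_study):
        matrix, _, _ = small_study
        spec = de.ComparisonSpec.across("M", "N1", "T1")
        hp = de.fit_rvm_hyperparams(*de.contrast_variances(matrix, spec))
        r1 = de.permutation_pvalues(matrix, spec, hp, 80, seed=13)
        r2 = de.permutation_pvalues(matrix, spec, hp, 80, seed=13)
        assert (r1["p_perm"] == r2["p_perm"]).all()

    def test_monotone_power_in_effect_size(self):
        """Rejection rate on planted genes is nondecreasing in beta."""
        rates = []
        for beta in (0.0, 0.5, 1.5):
            config = rt.SimulationConfig(
                n_genes=150, set_size_range=(15, 20), beta=beta,
                gamma=0.0, seed=21)
            matrix, truth = rt.generate_expression(config)
            spec = de.ComparisonSpec.across("M", "N1", "T1")
            res = de.run_contrast(matrix, spec, 100, seed=3)
            planted = [g for g, p in truth.gene_patterns.items() if p != "Null"]
            rates.append((res.loc[planted, "p_perm"] < 0.05).mean())
        assert rates[0] <= rates[1] + 0.05
        assert rates[1] <= rates[2] + 0.05
        assert rates[2] > rates[0]

    def test_nperm_below_one_rejected(self, small_study):
        matrix, _, _ = small_study
        spec = de.ComparisonSpec.across("M", "N1", "T0")
        hp = de.RVMHyperparams(1.0, 1.0, 4)
        with pytest.raises(ValueError):
            de.permutation_pvalues(matrix, spec, hp, 0, seed=1)


class TestSelection:
    def _result(self, p, t=None):
        genes = [f"G{i}" for i in range(len(p))]
        return pd.DataFrame(
            {"t": t if t is not None else np.ones(len(p)),
             "direction": 1, "p_param": p, "p_perm": p},
            index=pd.Index(genes, name="gene"))

    def test_strict_threshold_at_published_alpha(self):
        res = self._result([0.009, 0.010, 0.012])
        assert de.select_de(res, 0.01) == ["G0"]

    def test_vacuous_threshold_selects_everything(self):
        res = self._result([0.2, 0.5, 0.9])
        assert sorted(de.select_de(res, 1.0)) == ["G0", "G1", "G2"]

    def test_empty_result(self):
        empty = pd.DataFrame(columns=["t", "direction", "p_param", "p_perm"])
        assert de.select_de(empty, 0.01) == []

    def test_sorted_by_abs_t_then_identifier(self):
        res = self._result([0.001] * 3, t=[-5.0, 2.0, 5.0])
        assert de.select_de(res, 0.01) == ["G0", "G2", "G1"]


class TestVenn:
    def test_identical_lists(self):
        counts = de.venn_counts({"A": ["x", "y"], "B": ["x", "y"]})
        assert counts[("A", "B")] == 2
        assert counts[("A",)] == 0 and counts[("B",)] == 0

    def test_disjoint_lists(self):
        counts = de.venn_counts({"A": ["x"], "B": ["y"], "C": ["z"]})
        for combo, n in counts.items():
            assert n == (1 if len(combo) == 1 else 0)

    def test_random_lists_match_set_algebra(self):
        rng = np.random.default_rng(6)
        ids = [f"g{i}" for i in range(20)]
        lists = {name: list(rng.choice(ids, size=rng.integers(1, 15),
                                       replace=False))
                 for name in "ABC"}
        counts = de.venn_counts(lists)
        sets = {k: set(v) for k, v in lists.items()}
        # exclusive-region oracle by explicit membership classification
        oracle = {combo: 0 for combo in counts}
        for g in set().union(*sets.values()):
            member = tuple(sorted(k for k in sets if g in sets[k]))
            oracle[member] += 1
        assert counts == oracle
        assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_more_than_three_lists_rejected(self):
        with pytest.raises(ValueError):
            de.venn_counts({k: [] for k in "ABCD"})
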