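"""Enrichment engine: running-sum oracle, calibration, covariate mode."""

import numpy as np
import pandas as pd
import pytest

import rrtempo as rt
from rrtempo import gsea
from rrtempo.containers import ExpressionMatrix


def _brute_force_es(metric_sorted, hit, p=1.0):
    """Step-by-step enumeration of the weighted running sum."""
    n = len(metric_sorted)
    nh = int(hit.sum())
    total = sum(abs(m) ** p for m, h in zip(metric_sorted, hit) if h)
    running, cur, best = [], 0.0, 0.0
    for m, h in zip(metric_sorted, hit):
        if h:
            cur += (abs(m) ** p / total) if total > 0 else 1.0 / nh
        else:
            cur -= 1.0 / (n - nh)
        running.append(cur)
        if abs(cur) > abs(best):
            best = cur
    return best, np.array(running)


class TestEnrichmentScore:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(200):
            n = int(rng.integers(5, 51))
            k = int(rng.integers(1, min(10, n - 1) + 1))
            metric = np.sort(rng.normal(0, 1, n))[::-1]
            hit = np.zeros(n, bool)
            hit[rng.choice(n, size=k, replace=False)] = True
            es = gsea._es_from_hits(metric, hit)
            es_ref, running_ref = _brute_force_es(metric, hit)
            worst = max(worst, abs(es - es_ref))
            assert abs(running_ref[-1]) < 1e-9  # running sum returns to 0
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        assert worst < 1e-12

    def test_singleton_at_top_scores_one(self):
        ranked = pd.DataFrame({"gene": ["A", "B", "C"],
                               "metric": [3.0, 1.0, 0.5]})
        es, running = gsea.enrichment_score(ranked, ["A"])
        assert es == pytest.approx(1.0)
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_reversal_negates_es(self):
        """Reversing the ranked list (with metric signs negated, so it
        stays descending) negates the enrichment score."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 20
            metric = np.sort(rng.normal(0, 1, n))[::-1]
            hit = np.zeros(n, bool)
            hit[rng.choice(n, 5, replace=False)] = True
            es, running = gsea._es_from_hits(metric, hit,
                                             return_running=True)
            es_rev = gsea._es_from_hits(-metric[::-1], hit[::-1])
            assert abs(es_rev) == pytest.approx(abs(es), abs=1e-12)
            # the sign flips whenever the extremum is unambiguous
            if abs(running.max() + running.min()) > 1e-9:
                assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_whole_universe_set_rejected(self):
        ranked = pd.DataFrame({"gene": ["A", "B"], "metric": [1.0, 0.5]})
        with pytest.raises(gsea.GseaError, match="whole universe"):
            gsea.enrichment_score(ranked, ["A", "B"])

    def test_agrees_with_independent_reference_implementation(self):
        """Cross-check against gseapy's preranked enrichment scores."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(2)
        genes = [f"G{i:03d}" for i in range(60)]
        metric = np.sort(rng.normal(0, 1.5, 60))[::-1]
        sets = {"TOP": genes[3:15], "BOTTOM": genes[40:55],
                "SPREAD": genes[::7]}
        ref = gseapy.prerank(
            rnk=pd.DataFrame({"gene": genes, "score": metric})
            .set_index("gene"),
            gene_sets=sets, permutation_num=10, seed=1, outdir=None,
            min_size=1, max_size=60, weight=1.0, no_plot=True,
        ).res2d.set_index("Term")["ES"].astype(float)
        ranked = pd.DataFrame({"gene": genes, "metric": metric})
        for name, members in sets.items():
            es, _ = gsea.enrichment_score(ranked, members)
            assert es == pytest.approx(ref[name], abs=1e-6)


class TestRanking:
    def test_two_gene_signal_to_noise_toy(self):
        # gene 0: means 3 vs 1, sds 1 and 1 -> metric 1; gene 1: no diff
        xa = np.array([[2.0, 3.0, 4.0], [0.0, 1.0, 2.0]])
        xb = np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0]])
        m = ExpressionMatrix(pd.DataFrame(
            np.hstack([xa, xb]), index=["G0", "G1"],
            columns=[f"s{j}" for j in range(6)]))
        ranked = gsea.rank_genes(m, ["a"] * 3 + ["b"] * 3, classes=("a", "b"))
        assert list(ranked["gene"]) == ["G0", "G1"]
        assert ranked["metric"].iloc[0] == pytest.approx(1.0)
        assert ranked["metric"].iloc[1] == pytest.approx(0.0)

    def test_identical_classes_all_zero_identifier_order(self):
        x = np.tile([[5.0, 6.0, 7.0]], (3, 1))
        m = ExpressionMatrix(pd.DataFrame(
            np.hstack([x, x]), index=["GC", "GA", "GB"],
            columns=[f"s{j}" for j in range(6)]))
        ranked = gsea.rank_genes(m, ["a"] * 3 + ["b"] * 3)
        assert np.allclose(ranked["metric"], 0.0)
        assert list(ranked["gene"]) == ["GA", "GB", "GC"]

    def test_covariate_equal_to_own_profile_ranks_first(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, (10, 8))
        m = ExpressionMatrix(pd.DataFrame(
            values, index=[f"G{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(8)]))
        ranked = gsea.rank_genes(m, values[4])
        assert ranked["gene"].iloc[0] == "G4"
        assert ranked["metric"].iloc[0] == pytest.approx(1.0)

    def test_constant_covariate_rejected(self):
        m = ExpressionMatrix(pd.DataFrame(
            np.random.default_rng(0).normal(size=(3, 5)),
            index=list("ABC"), columns=[f"s{j}" for j in range(5)]))
        with pytest.raises(gsea.GseaError, match="constant covariate"):
            gsea.rank_genes(m, np.ones(5))


class TestPermutationSignificance:
    def test_null_saturation_gives_p_one(self):
        """Identical samples: every relabeling reproduces the observed ES."""
        x = np.tile(np.arange(12, dtype=float)[:, None], (1, 6))
        m = ExpressionMatrix(pd.DataFrame(
            x, index=[f"G{i:02d}" for i in range(12)],
            columns=[f"s{j}" for j in range(6)]))
        coll = rt.GeneSetCollection(
            [rt.GeneSet("S", "", frozenset({"G00", "G03", "G07"}))])
        res = gsea.permutation_significance(
            m, ["a", "a", "a", "b", "b", "b"], coll, 20, seed=0,
            mode="phenotype", classes=("a", "b"))
        assert res.loc["S", "p_nom"] == pytest.approx(1.0)

    def test_planted_set_detected_in_most_seeds(self, small_config):
        """Planted up-module reaches the published NPV/FDR criteria
        (p < 0.05, q < 0.25) in at least 90% of generator seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            config = rt.SimulationConfig(n_genes=300, seed=seed)
            matrix, truth = rt.generate_expression(config)
            coll = rt.generate_gene_sets(config, truth)
            meta = matrix.require_design()
            sel = (matrix.select_samples(group="M", timepoint="T1")
                   + matrix.select_samples(group="N1", timepoint="T1"))
            sub = ExpressionMatrix(matrix.values[sel], meta.loc[sel])
            res = gsea.permutation_significance(
                sub, meta.loc[sel, "group"].to_numpy(), coll, 100,
                seed=seed + 1000, classes=("M", "N1"))
            row = res.loc["SET_PROGRESSIVEI_UP"]
            hits += (row["p_nom"] < 0.05) and (row["fdr_q"] < 0.25) \
                and row["es"] > 0
        assert hits >= 0.9 * n_seeds

    def test_modes_agree_on_rejection_ordering(self, small_study):
        matrix, _, coll = small_study
        meta = matrix.require_design()
        sel = (matrix.select_samples(group="M", timepoint="T1")
               + matrix.select_samples(group="N1", timepoint="T1"))
        sub = ExpressionMatrix(matrix.values[sel], meta.loc[sel])
        labels = meta.loc[sel, "group"].to_numpy()
        kwargs = dict(n_perm=200, classes=("M", "N1"))
        r_ph = gsea.permutation_significance(sub, labels, coll, seed=1,
                                             mode="phenotype", **kwargs)
        r_gs = gsea.permutation_significance(sub, labels, coll, seed=2,
                                             mode="gene_set", **kwargs)
        joint = r_ph["p_nom"].rank().corr(r_gs["p_nom"].rank(),
                                          method="spearman")
        assert joint > 0.8

    def test_auto_mode_falls_back_for_small_classes(self):
        rng = np.random.default_rng(4)
        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(30, 8)), index=[f"G{i:02d}" for i in range(30)],
            columns=[f"s{j}" for j in range(8)]))
        coll = rt.GeneSetCollection(
            [rt.GeneSet("S", "", frozenset({"G00", "G01", "G02"}))])
        res = gsea.permutation_significance(
            m, ["a"] * 4 + ["b"] * 4, coll, 50, seed=0, mode="auto")
        assert res.attrs["mode"] == "gene_set"

    def test_leading_edge_subset_of_set_and_universe(self, small_study):
        matrix, _, coll = small_study
        meta = matrix.require_design()
        sel = (matrix.select_samples(group="M", timepoint="T1")
               + matrix.select_samples(group="N1", timepoint="T1"))
        sub = ExpressionMatrix(matrix.values[sel], meta.loc[sel])
        res = gsea.permutation_significance(
            sub, meta.loc[sel, "group"].to_numpy(), coll, 50, seed=5,
            classes=("M", "N1"))
        for name, row in res.iterrows():
            le = set(row["leading_edge"])
            assert le <= set(coll[name].genes)
            assert np.sign(row["nes"]) == np.sign(row["es"]) or row["es"] == 0
            assert 0.0 <= row["fdr_q"] <= 1.0


class TestCovariateMode:
    def test_planted_pathway_changes_track_covariate(self):
        """Covariate built as 0.9 x standardized planted-pathway delta
        score (plus independent noise): the planted set comes out as a
        significant positively correlated pathway at n = 20 subjects."""
        config = rt.SimulationConfig(
            n_genes=300, n_subjects_per_group=20, covariate_r=0.9,
            covariate_pattern="ProgressiveI_Up", seed=8)
        matrix, truth = rt.generate_expression(config)
        coll = rt.generate_gene_sets(config, truth)
        cov = rt.generate_covariate(matrix, truth, config)
        dvals, _ = gsea.subject_deltas(matrix, "M", "T0", "T2", cov)
        score = dvals.loc[truth.genes_of("ProgressiveI_Up")].mean(axis=0)
        z = (score - score.mean()) / score.std(ddof=0)
        rng = np.random.default_rng(88)
        dcov = pd.Series(0.9 * z + np.sqrt(1 - 0.81)
                         * rng.standard_normal(len(z)),
                         index=dvals.columns)
        res = gsea.covariate_correlation_gsea(dvals, dcov, coll, 100, seed=9)
        row = res.loc["SET_PROGRESSIVEI_UP"]
        assert row["es"] > 0
        assert row["p_nom"] < 0.05

    def test_flipping_covariate_flips_every_es(self):
        config = rt.SimulationConfig(n_genes=250, n_subjects_per_group=8,
                                     seed=10)
        matrix, truth = rt.generate_expression(config)
        coll = rt.generate_gene_sets(config, truth)
        cov = rt.generate_covariate(matrix, truth, config)
        dvals, dcov = gsea.subject_deltas(matrix, "M", "T0", "T1", cov)
        r1 = gsea.covariate_correlation_gsea(dvals, dcov, coll, 50, seed=3)
        r2 = gsea.covariate_correlation_gsea(dvals, -dcov, coll, 50, seed=3)
        assert np.allclose(r1["es"].to_numpy(), -r2["es"].to_numpy())

    def test_too_few_complete_subjects_rejected(self):
        config = rt.SimulationConfig(n_genes=60, set_size_range=(4, 6),
                                     n_subjects_per_group=2, seed=0)
        matrix, truth = rt.generate_expression(config)
        cov = rt.generate_covariate(matrix, truth, config)
        with pytest.raises(gsea.GseaError, match="complete subjects"):
            gsea.subject_deltas(matrix, "M", "T0", "T1", cov)
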