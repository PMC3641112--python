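"""Gene-set enrichment engine (weighted running-sum statistic).

Genes are ranked by a per-gene association metric — signal-to-noise for
two-class phenotypes, Pearson correlation for continuous covariates — and
each gene set is scored by the signed extremum of a weighted running sum
walked down the ranked list: set members ("hits") add |metric|^p
normalized by the in-set total, non-members subtract 1/(N - N_H). The
enrichment score ES lies in [-1, 1]; positive ES means the set is
concentrated at the top of the ranking (up in the first-named class),
negative at the bottom.

Significance comes from permutations, either of the phenotype (sample
relabeling; within-subject timepoint swaps for paired time contrasts;
covariate shuffles in continuous mode) or of the gene set (random
same-size sets against the observed ranking — the fallback when a class
has fewer than 7 samples). The normalized score NES divides ES by the mean
same-sign permuted ES; the FDR q pools the permuted NES across all sets
and compares tail proportions, clipped to [0, 1]. The leading edge is the
set members appearing at or before the running-sum extremum (at or after,
for negative scores).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection

log = logging.getLogger(__name__)

MIN_SAMPLES_PER_CLASS = 7  # below this, gene_set permutation is auto-selected
SD_FRACTION = 0.2


class GseaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ranking metrics


def _global_sd_floor(x: np.ndarray) -> float:
    """Scale floor for the signal-to-noise denominator: the median pooled SD."""
    pooled = x.std(axis=1, ddof=1) if x.shape[1] > 1 else np.zeros(x.shape[0])
    med = float(np.median(pooled))
    return med


def _signal_to_noise(x: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray,
                     sd_floor: float) -> np.ndarray:
    xa, xb = x[:, mask_a], x[:, mask_b]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    sa, sb = xa.std(axis=1, ddof=1), xb.std(axis=1, ddof=1)
    floor_a = np.maximum(SD_FRACTION * np.abs(ma),
                         max(SD_FRACTION * sd_floor, 1e-8))
    floor_b = np.maximum(SD_FRACTION * np.abs(mb),
                         max(SD_FRACTION * sd_floor, 1e-8))
    return (ma - mb) / (np.maximum(sa, floor_a) + np.maximum(sb, floor_b))


def _pearson_metric(x: np.ndarray, cov: np.ndarray) -> np.ndarray:
    cov_c = cov - cov.mean()
    denom_c = np.sqrt((cov_c ** 2).sum())
    if denom_c == 0:
        raise GseaError("constant covariate")
    xc = x - x.mean(axis=1, keepdims=True)
    denom_x = np.sqrt((xc ** 2).sum(axis=1))
    num = xc @ cov_c
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / (denom_x * denom_c)
    return np.where(denom_x == 0, 0.0, r)  # constant genes get metric 0


def _order(metric: np.ndarray, gene_codes: np.ndarray) -> np.ndarray:
    """Descending metric order; ties broken by gene identifier ascending."""
    return np.lexsort((gene_codes, -metric))


def rank_genes(matrix: ExpressionMatrix,
               phenotype: Sequence[str] | np.ndarray,
               classes: tuple[str, str] | None = None) -> pd.DataFrame:
    """Rank all genes by association with a phenotype.

    ``phenotype`` is either a vector of two class labels (one per sample,
    in matrix column order) — metric: signal-to-noise ``(m1 - m2) /
    (sd1 + sd2)`` with floored SDs, positive meaning up in the first
    class of ``classes`` — or a numeric covariate — metric: Pearson
    correlation. Returns a DataFrame (gene, metric) in rank order.
    """
    x = matrix.values.to_numpy(float)
    genes = np.asarray(matrix.genes)
    pheno = np.asarray(phenotype)
    if np.issubdtype(pheno.dtype, np.number):
        if len(pheno) != x.shape[1]:
            raise GseaError("covariate length must match sample count")
        if len(pheno) < 3:
            raise GseaError("continuous ranking needs >= 3 samples")
        metric = _pearson_metric(x, pheno.astype(float))
    else:
        labels = list(dict.fromkeys(pheno))
        if classes is None:
            if len(labels) != 2:
                raise GseaError(f"expected 2 classes, got {labels}")
            classes = (labels[0], labels[1])
        mask_a, mask_b = pheno == classes[0], pheno == classes[1]
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            raise GseaError("each class needs >= 2 samples")
        metric = _signal_to_noise(x, mask_a, mask_b,
                                  _global_sd_floor(x[:, mask_a | mask_b]))
    codes = np.argsort(np.argsort(genes))
    order = _order(metric, codes)
    return pd.DataFrame({"gene": genes[order], "metric": metric[order]})


# ---------------------------------------------------------------------------
# enrichment score


def _es_from_hits(metric_sorted: np.ndarray, hit: np.ndarray, p: float = 1.0,
                  return_running: bool = False):
    n = len(metric_sorted)
    n_hit = int(hit.sum())
    if n_hit == 0:
        running = np.zeros(n)
        return (0.0, running) if return_running else 0.0
    if n_hit == n:
        raise GseaError("gene set covers the whole universe")
    w = np.where(hit, np.abs(metric_sorted) ** p, 0.0)
    total = w.sum()
    if total == 0:  # all in-set metrics zero: fall back to unweighted hits
        w = hit.astype(float)
        total = float(n_hit)
    step = w / total - (~hit) / (n - n_hit)
    running = np.cumsum(step)
    idx = int(np.argmax(np.abs(running)))
    es = float(running[idx])
    if return_running:
        return es, running
    return es


def enrichment_score(ranked: pd.DataFrame, gene_set: Sequence[str],
                     p: float = 1.0) -> tuple[float, np.ndarray]:
    """ES and the full running sum for one set against a ranked list."""
    genes = ranked["gene"].to_numpy()
    hit = np.isin(genes, list(gene_set))
    if hit.sum() == 0:
        raise GseaError("gene set has no overlap with the ranked universe")
    return _es_from_hits(ranked["metric"].to_numpy(float), hit, p,
                         return_running=True)


# ---------------------------------------------------------------------------
# permutation machinery


def _phenotype_perm_masks(pheno: np.ndarray, classes: tuple[str, str],
                          n_perm: int, rng: np.random.Generator,
                          paired_subjects: Sequence[str] | None):
    """Yield (mask_a, mask_b) label assignments for each permutation."""
    n = len(pheno)
    in_ab = (pheno == classes[0]) | (pheno == classes[1])
    if paired_subjects is None:
        base = np.asarray(pheno, object)
        for _ in range(n_perm):
            perm = np.asarray(base, object).copy()
            perm[in_ab] = rng.permutation(perm[in_ab])
            yield perm == classes[0], perm == classes[1]
    else:
        subj = np.asarray(paired_subjects)
        uniq = pd.unique(subj[in_ab])
        for _ in range(n_perm):
            flip = dict(zip(uniq, rng.integers(0, 2, len(uniq)).astype(bool)))
            perm = np.asarray(pheno, object).copy()
            for i in np.nonzero(in_ab)[0]:
                if flip[subj[i]]:
                    perm[i] = classes[1] if pheno[i] == classes[0] else classes[0]
            yield perm == classes[0], perm == classes[1]


def _summarize(es_obs: np.ndarray, es_perm: np.ndarray):
    """NES, nominal p and pooled-NES FDR q from the permutation scores.

    ``es_perm`` has shape (n_sets, n_perm).
    """
    n_sets, n_perm = es_perm.shape
    nes_obs = np.zeros(n_sets)
    nes_perm = np.full_like(es_perm, np.nan, dtype=float)
    p_nom = np.ones(n_sets)
    for i in range(n_sets):
        perms = es_perm[i]
        pos, neg = perms[perms >= 0], perms[perms < 0]
        mean_pos = pos.mean() if len(pos) else np.nan
        mean_neg = np.abs(neg).mean() if len(neg) else np.nan
        # normalize permuted scores by the same same-sign means
        with np.errstate(invalid="ignore", divide="ignore"):
            nes_perm[i] = np.where(perms >= 0, perms / mean_pos,
                                   perms / mean_neg)
        es = es_obs[i]
        if es >= 0:
            nes_obs[i] = es / mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else 0.0
            n_same, hits = len(pos), int((pos >= es).sum())
        else:
            nes_obs[i] = es / mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else 0.0
            n_same, hits = len(neg), int((neg <= es).sum())
        p_nom[i] = (1.0 + hits) / (1.0 + n_same) if n_same else 1.0
    pooled = nes_perm[np.isfinite(nes_perm)]
    fdr = np.ones(n_sets)
    for i in range(n_sets):
        nes = nes_obs[i]
        if nes >= 0:
            denom_pool = (pooled >= 0).sum()
            num = (pooled >= nes).sum() / denom_pool if denom_pool else 1.0
            den = (nes_obs >= nes).sum() / max((nes_obs >= 0).sum(), 1)
        else:
            denom_pool = (pooled < 0).sum()
            num = (pooled <= nes).sum() / denom_pool if denom_pool else 1.0
            den = (nes_obs <= nes).sum() / max((nes_obs < 0).sum(), 1)
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0
    return nes_obs, p_nom, fdr


def _leading_edge(genes_sorted: np.ndarray, metric_sorted: np.ndarray,
                  hit: np.ndarray, es: float) -> list[str]:
    _, running = _es_from_hits(metric_sorted, hit, return_running=True)
    idx = int(np.argmax(np.abs(running)))
    if es >= 0:
        sel = hit & (np.arange(len(hit)) <= idx)
    else:
        sel = hit & (np.arange(len(hit)) >= idx)
    return list(genes_sorted[sel])


def permutation_significance(matrix: ExpressionMatrix,
                             phenotype: Sequence[str] | np.ndarray,
                             collection: GeneSetCollection,
                             n_perm: int, seed: int,
                             mode: str = "auto",
                             classes: tuple[str, str] | None = None,
                             paired_subjects: Sequence[str] | None = None,
                             weight: float = 1.0) -> pd.DataFrame:
    """Full enrichment analysis of a collection against one phenotype.

    Returns one row per set: size (in-universe), es, nes, p_nom, fdr_q,
    direction, leading_edge. ``mode`` is ``"phenotype"``, ``"gene_set"``
    or ``"auto"`` (phenotype permutation when every class has at least
    7 samples, else gene-set permutation with a logged notice).
    """
    if n_perm < 10:
        raise GseaError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    x = matrix.values.to_numpy(float)
    genes = np.asarray(matrix.genes)
    codes = np.argsort(np.argsort(genes))
    pheno = np.asarray(phenotype)
    continuous = np.issubdtype(pheno.dtype, np.number)

    if continuous:
        metric = _pearson_metric(x, pheno.astype(float))
        enough = len(pheno) >= MIN_SAMPLES_PER_CLASS
    else:
        labels = list(dict.fromkeys(pheno))
        if classes is None:
            if len(labels) != 2:
                raise GseaError(f"expected 2 classes, got {labels}")
            classes = (labels[0], labels[1])
        mask_a, mask_b = pheno == classes[0], pheno == classes[1]
        sd_floor = _global_sd_floor(x[:, mask_a | mask_b])
        metric = _signal_to_noise(x, mask_a, mask_b, sd_floor)
        enough = min(mask_a.sum(), mask_b.sum()) >= MIN_SAMPLES_PER_CLASS
    if mode == "auto":
        mode = "phenotype" if enough else "gene_set"
        if mode == "gene_set":
            log.info("fewer than %d samples per class: using gene_set "
                     "permutation", MIN_SAMPLES_PER_CLASS)
    if mode not in ("phenotype", "gene_set"):
        raise GseaError(f"unknown permutation mode {mode!r}")

    order = _order(metric, codes)
    genes_sorted, metric_sorted = genes[order], metric[order]
    universe = set(genes)
    hit_masks, sizes, names = [], [], []
    for s in collection:
        members = s.genes & universe
        hit = np.isin(genes_sorted, list(members))
        names.append(s.name)
        sizes.append(len(members))
        hit_masks.append(hit)
        if len(members) == len(universe):
            raise GseaError(f"set {s.name!r} covers the whole universe")
    es_obs = np.array([
        _es_from_hits(metric_sorted, hit, weight) if size else 0.0
        for hit, size in zip(hit_masks, sizes)
    ])

    n_sets = len(names)
    es_perm = np.zeros((n_sets, n_perm))
    if mode == "gene_set":
        n = len(genes_sorted)
        for j in range(n_perm):
            for i, size in enumerate(sizes):
                if size == 0:
                    continue
                hit = np.zeros(n, bool)
                hit[rng.choice(n, size=size, replace=False)] = True
                es_perm[i, j] = _es_from_hits(metric_sorted, hit, weight)
    elif continuous:
        for j in range(n_perm):
            m = _pearson_metric(x, rng.permutation(pheno.astype(float)))
            o = _order(m, codes)
            ms = m[o]
            reindex = np.argsort(o)
            for i, hit in enumerate(hit_masks):
                if sizes[i] == 0:
                    continue
                # recompute hit positions under the permuted ordering
                hit_p = np.isin(genes[o], genes_sorted[hit])
                es_perm[i, j] = _es_from_hits(ms, hit_p, weight)
    else:
        gen = _phenotype_perm_masks(pheno, classes, n_perm, rng,
                                    paired_subjects)
        for j, (ma, mb) in enumerate(gen):
            m = _signal_to_noise(x, ma, mb, sd_floor)
            o = _order(m, codes)
            ms = m[o]
            for i, hit in enumerate(hit_masks):
                if sizes[i] == 0:
                    continue
                hit_p = np.isin(genes[o], genes_sorted[hit])
                es_perm[i, j] = _es_from_hits(ms, hit_p, weight)

    nes, p_nom, fdr = _summarize(es_obs, es_perm)
    leading = []
    for i, hit in enumerate(hit_masks):
        if sizes[i] == 0:
            leading.append([])
            p_nom[i], fdr[i], nes[i] = 1.0, 1.0, 0.0
        else:
            leading.append(_leading_edge(genes_sorted, metric_sorted, hit,
                                         es_obs[i]))
    out = pd.DataFrame(
        {"size": sizes, "es": es_obs, "nes": nes, "p_nom": p_nom,
         "fdr_q": fdr,
         "direction": np.where(es_obs >= 0, "up", "down"),
         "leading_edge": leading},
        index=pd.Index(names, name="set"),
    )
    out.attrs["mode"] = mode
    out.attrs["n_perm"] = n_perm
    return out


# ---------------------------------------------------------------------------
# continuous-covariate (physiological correlate) mode


def subject_deltas(matrix: ExpressionMatrix, group: str,
                   tp_from: str, tp_to: str,
                   covariate: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subject expression and covariate changes between two timepoints.

    Returns (delta expression genes x subjects, delta covariate per
    subject) for ``tp_to`` minus ``tp_from`` within one group; subjects
    missing either timepoint or either covariate value are dropped.
    """
    meta = matrix.require_design()
    sel_from = matrix.select_samples(group=group, timepoint=tp_from)
    sel_to = matrix.select_samples(group=group, timepoint=tp_to)
    by_subj_from = {meta.loc[s, "subject"]: s for s in sel_from}
    by_subj_to = {meta.loc[s, "subject"]: s for s in sel_to}
    common = sorted(
        s for s in set(by_subj_from) & set(by_subj_to)
        if by_subj_from[s] in covariate.index and by_subj_to[s] in covariate.index
    )
    if len(common) < 3:
        raise GseaError(
            f"need >= 3 complete subjects in {group} {tp_from}->{tp_to}, "
            f"got {len(common)}"
        )
    dx = (matrix.values[[by_subj_to[s] for s in common]].to_numpy()
          - matrix.values[[by_subj_from[s] for s in common]].to_numpy())
    dcov = pd.Series(
        [covariate[by_subj_to[s]] - covariate[by_subj_from[s]] for s in common],
        index=common, name="delta",
    )
    dvals = pd.DataFrame(dx, index=matrix.genes, columns=common)
    return dvals, dcov


def covariate_correlation_gsea(delta_values: pd.DataFrame,
                               delta_covariate: pd.Series,
                               collection: GeneSetCollection,
                               n_perm: int, seed: int,
                               mode: str = "auto") -> pd.DataFrame:
    """Enrichment of sets against per-subject covariate changes.

    Continuous-mode ranking (Pearson correlation of each gene's change
    with the covariate change) with covariate permutation; sets with
    negative ES are reported as negatively correlated pathways.
    """
    if list(delta_values.columns) != list(delta_covariate.index):
        delta_covariate = delta_covariate.loc[delta_values.columns]
    dm = ExpressionMatrix(delta_values)
    return permutation_significance(
        dm, delta_covariate.to_numpy(float), collection, n_perm, seed,
        mode=mode,
    )
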