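"""Individual-gene differential expression.

The workhorse is the random-variance (moderated) t-test: per-gene variances
are assumed drawn from an inverse-gamma prior sigma^2 ~ InvGamma(a, b)
(equivalently 1/sigma^2 ~ Gamma(shape a, rate b), so s^2 * a / b follows an
F(nu, 2a) distribution). Sharing the fitted prior across genes shrinks each
gene's variance estimate

    sigma~^2 = (nu * s^2 + 2 * b) / (nu + 2 * a)

and augments the degrees of freedom to nu + 2a, which stabilizes the t
statistic in small samples without assuming equal variance across genes.
Significance is assessed by permutation: group-label shuffles for unpaired
contrasts, per-subject sign flips for paired ones, with full enumeration
replacing sampling whenever the exhaustive permutation count fits in the
requested budget.

Contrast conventions: N1-vs-N2 and all within-group time contrasts are
paired (same subjects); any contrast involving M versus another group is
unpaired (independent people). A contrast ``(a, b)`` tests arm a minus
arm b, so a positive statistic means higher expression in the first-named
arm.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import ExpressionMatrix, GROUPS, TIMEPOINTS

log = logging.getLogger(__name__)

A_MAX = 1e6


class ContrastError(ValueError):
    """Invalid or unsatisfiable comparison specification."""


@dataclass(frozen=True)
class ComparisonSpec:
    """One across-group or within-group contrast.

    ``kind`` is ``"across"`` (two groups at a fixed timepoint) or
    ``"within"`` (two timepoints inside one group). ``pair`` holds the
    (a, b) arms — groups for across, timepoints for within — and ``fixed``
    the held-constant timepoint or group. Pairing is forced by the design:
    within-group time contrasts and N1-vs-N2 are paired, anything against
    M is unpaired.
    """

    kind: str
    pair: tuple[str, str]
    fixed: str

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ContrastError("contrast arms must differ")
        if self.kind == "across":
            if not {a, b} <= set(GROUPS) or self.fixed not in TIMEPOINTS:
                raise ContrastError(f"bad across-group contrast {self}")
        elif self.kind == "within":
            if not {a, b} <= set(TIMEPOINTS) or self.fixed not in GROUPS:
                raise ContrastError(f"bad within-group contrast {self}")
        else:
            raise ContrastError(f"unknown contrast kind {self.kind!r}")

    @classmethod
    def across(cls, group_a: str, group_b: str, timepoint: str) -> "ComparisonSpec":
        return cls("across", (group_a, group_b), timepoint)

    @classmethod
    def within(cls, group: str, tp_a: str, tp_b: str) -> "ComparisonSpec":
        return cls("within", (tp_a, tp_b), group)

    @property
    def paired(self) -> bool:
        return self.kind == "within" or "M" not in self.pair

    @property
    def label(self) -> str:
        a, b = self.pair
        return f"{a}-vs-{b}@{self.fixed}"


@dataclass(frozen=True)
class RVMHyperparams:
    """Fitted inverse-gamma prior (shape a, scale b) and residual df nu."""

    a: float
    b: float
    nu: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if self.nu < 1:
            raise ValueError("nu must be >= 1")

    def shrink(self, s2: np.ndarray) -> np.ndarray:
        return (self.nu * s2 + 2.0 * self.b) / (self.nu + 2.0 * self.a)

    @property
    def df(self) -> float:
        return self.nu + 2.0 * self.a


# ---------------------------------------------------------------------------
# data extraction


def _paired_differences(matrix: ExpressionMatrix, spec: ComparisonSpec
                        ) -> tuple[np.ndarray, list[str]]:
    """Per-subject difference matrix (genes x subjects), arm a minus arm b."""
    meta = matrix.require_design()
    a, b = spec.pair
    if spec.kind == "across":
        sel_a = matrix.select_samples(group=a, timepoint=spec.fixed)
        sel_b = matrix.select_samples(group=b, timepoint=spec.fixed)
    else:
        sel_a = matrix.select_samples(group=spec.fixed, timepoint=a)
        sel_b = matrix.select_samples(group=spec.fixed, timepoint=b)
    subj_a = {meta.loc[s, "subject"]: s for s in sel_a}
    subj_b = {meta.loc[s, "subject"]: s for s in sel_b}
    common = sorted(set(subj_a) & set(subj_b))
    orphans = sorted(set(subj_a) ^ set(subj_b))
    if orphans:
        log.warning("contrast %s: dropping %d unmatched subjects",
                    spec.label, len(orphans))
    if len(common) < 2:
        raise ContrastError(
            f"contrast {spec.label}: fewer than 2 matched subjects "
            f"(orphans: {orphans})"
        )
    da = matrix.values[[subj_a[s] for s in common]].to_numpy()
    db = matrix.values[[subj_b[s] for s in common]].to_numpy()
    return da - db, common


def _unpaired_arms(matrix: ExpressionMatrix, spec: ComparisonSpec
                   ) -> tuple[np.ndarray, np.ndarray]:
    ga, gb = spec.pair
    sel_a = matrix.select_samples(group=ga, timepoint=spec.fixed)
    sel_b = matrix.select_samples(group=gb, timepoint=spec.fixed)
    if len(sel_a) < 2 or len(sel_b) < 2:
        raise ContrastError(f"contrast {spec.label}: each arm needs >= 2 samples")
    return matrix.values[sel_a].to_numpy(), matrix.values[sel_b].to_numpy()


def contrast_variances(matrix: ExpressionMatrix, spec: ComparisonSpec
                       ) -> tuple[np.ndarray, int]:
    """Per-gene residual variances and their degrees of freedom."""
    if spec.paired:
        d, _ = _paired_differences(matrix, spec)
        return d.var(axis=1, ddof=1), d.shape[1] - 1
    xa, xb = _unpaired_arms(matrix, spec)
    na, nb = xa.shape[1], xb.shape[1]
    s2 = ((na - 1) * xa.var(axis=1, ddof=1)
          + (nb - 1) * xb.var(axis=1, ddof=1)) / (na + nb - 2)
    return s2, na + nb - 2


# ---------------------------------------------------------------------------
# hyperparameter fitting


def _f_logpdf(x: np.ndarray, d1: float, d2: float) -> np.ndarray:
    # explicit F log-density (vectorized, avoids distribution overhead)
    return ((d1 / 2) * np.log(d1 / d2) + (d1 / 2 - 1) * np.log(x)
            - ((d1 + d2) / 2) * np.log1p(d1 * x / d2)
            - special.betaln(d1 / 2, d2 / 2))


def _neg_loglik(theta: np.ndarray, s2: np.ndarray, nu: float) -> float:
    a, b = np.exp(theta)
    scale = b / a  # s2 = scale * F(nu, 2a)
    return -np.sum(_f_logpdf(s2 / scale, nu, 2.0 * a) - np.log(scale))


def fit_rvm_hyperparams(sample_variances: np.ndarray, nu: float,
                        min_genes: int = 50, n_restarts: int = 4
                        ) -> RVMHyperparams:
    """Maximum-likelihood fit of the inverse-gamma variance prior.

    Zero variances are excluded from the fit (they carry no likelihood
    information under the continuous model but are still shrunk when
    testing). If the likelihood pushes the shape parameter beyond
    ``A_MAX`` the prior is effectively degenerate (all genes share one
    variance) and ``a`` is capped there.
    """
    s2 = np.asarray(sample_variances, float)
    s2 = s2[s2 > 0]
    if len(s2) < min_genes:
        raise ValueError(
            f"need >= {min_genes} positive variances to fit the prior, "
            f"got {len(s2)}"
        )
    if nu < 1:
        raise ValueError("nu must be >= 1")
    mean = float(s2.mean())
    starts = [(2.0, mean), (1.0, mean / 2), (5.0, 4 * mean), (0.5, mean / 4),
              (10.0, 9 * mean)]
    best = None
    last = None
    for a0, b0 in starts[: n_restarts + 1]:
        res = optimize.minimize(
            _neg_loglik, np.log([a0, b0]), args=(s2, float(nu)),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 1000},
        )
        last = res
        if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
            best = (res.fun, res.x, res.success)
    if best is None:
        raise RuntimeError(
            f"random-variance prior fit failed to converge; last iterate "
            f"(log a, log b) = {None if last is None else last.x}"
        )
    a, b = np.exp(best[1])
    converged = bool(best[2])
    if a > A_MAX:
        a, converged = A_MAX, True  # degenerate common-variance prior
    return RVMHyperparams(float(a), float(b), float(nu), converged)


# ---------------------------------------------------------------------------
# moderated t statistics


def _t_unpaired(xa: np.ndarray, xb: np.ndarray, hp: RVMHyperparams) -> np.ndarray:
    na, nb = xa.shape[1], xb.shape[1]
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    s2 = ((na - 1) * xa.var(axis=1, ddof=1)
          + (nb - 1) * xb.var(axis=1, ddof=1)) / (na + nb - 2)
    se = np.sqrt(hp.shrink(s2) * (1.0 / na + 1.0 / nb))
    return diff / se


def _t_paired(d: np.ndarray, hp: RVMHyperparams) -> np.ndarray:
    n = d.shape[1]
    se = np.sqrt(hp.shrink(d.var(axis=1, ddof=1)) / n)
    return d.mean(axis=1) / se


def rvm_t_test(matrix: ExpressionMatrix, spec: ComparisonSpec,
               hp: RVMHyperparams) -> pd.DataFrame:
    """Moderated t-test for one contrast; returns the per-gene result table.

    Columns: ``t``, ``direction`` (sign of t), ``p_param`` (two-sided,
    t distribution with nu + 2a df); ``attrs['contrast']`` carries the
    contrast label.
    """
    if spec.paired:
        d, _ = _paired_differences(matrix, spec)
        t = _t_paired(d, hp)
    else:
        xa, xb = _unpaired_arms(matrix, spec)
        t = _t_unpaired(xa, xb, hp)
    p = 2.0 * stats.t.sf(np.abs(t), hp.df)
    out = pd.DataFrame(
        {"t": t, "direction": np.sign(t).astype(int), "p_param": p},
        index=matrix.genes,
    )
    out.attrs["contrast"] = spec.label
    return out


# ---------------------------------------------------------------------------
# permutation p-values


def _perm_unpaired(xa: np.ndarray, xb: np.ndarray, hp: RVMHyperparams,
                   n_perm: int, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray, bool]:
    na = xa.shape[1]
    pooled = np.hstack([xa, xb])
    n = pooled.shape[1]
    t_obs = _t_unpaired(xa, xb, hp)
    n_exact = math.comb(n, na)
    count = np.zeros(len(t_obs))
    tol = 1e-12
    if n_exact <= n_perm:
        for combo in itertools.combinations(range(n), na):
            mask = np.zeros(n, bool)
            mask[list(combo)] = True
            t_p = _t_unpaired(pooled[:, mask], pooled[:, ~mask], hp)
            count += np.abs(t_p) >= np.abs(t_obs) - tol
        return t_obs, count / n_exact, True
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, bool)
        mask[perm[:na]] = True
        t_p = _t_unpaired(pooled[:, mask], pooled[:, ~mask], hp)
        count += np.abs(t_p) >= np.abs(t_obs) - tol
    return t_obs, (1.0 + count) / (1.0 + n_perm), False


def _perm_paired(d: np.ndarray, hp: RVMHyperparams, n_perm: int,
                 rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray, bool]:
    n = d.shape[1]
    t_obs = _t_paired(d, hp)
    count = np.zeros(len(t_obs))
    tol = 1e-12
    # global negation leaves |t| unchanged, so the exhaustive two-sided
    # null has 2^(n-1) distinct classes: fix the first sign at +1
    if n <= 21 and 2 ** (n - 1) <= n_perm:
        for bits in range(2 ** (n - 1)):
            signs = np.ones(n)
            signs[1:] = 1 - 2 * ((bits >> np.arange(n - 1)) & 1)
            t_p = _t_paired(d * signs, hp)
            count += np.abs(t_p) >= np.abs(t_obs) - tol
        return t_obs, count / 2 ** (n - 1), True
    for _ in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_p = _t_paired(d * signs, hp)
        count += np.abs(t_p) >= np.abs(t_obs) - tol
    return t_obs, (1.0 + count) / (1.0 + n_perm), False


def permutation_pvalues(matrix: ExpressionMatrix, spec: ComparisonSpec,
                        hp: RVMHyperparams, n_perm: int, seed: int
                        ) -> pd.DataFrame:
    """Permutation p-values for the moderated t of one contrast.

    Unpaired contrasts shuffle group labels; paired contrasts flip the
    sign of per-subject differences. When the exhaustive permutation count
    is within ``n_perm`` the full enumeration replaces sampling and the
    p-value is exact; otherwise the add-one Monte-Carlo estimator
    ``(1 + hits) / (1 + n_perm)`` is used, so p is never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if spec.paired:
        d, _ = _paired_differences(matrix, spec)
        t_obs, p_perm, exact = _perm_paired(d, hp, n_perm, rng)
    else:
        xa, xb = _unpaired_arms(matrix, spec)
        t_obs, p_perm, exact = _perm_unpaired(xa, xb, hp, n_perm, rng)
    p_param = 2.0 * stats.t.sf(np.abs(t_obs), hp.df)
    out = pd.DataFrame(
        {"t": t_obs, "direction": np.sign(t_obs).astype(int),
         "p_param": p_param, "p_perm": p_perm},
        index=matrix.genes,
    )
    out.attrs["contrast"] = spec.label
    out.attrs["exact_enumeration"] = exact
    return out


def run_contrast(matrix: ExpressionMatrix, spec: ComparisonSpec,
                 n_perm: int, seed: int) -> pd.DataFrame:
    """Fit the variance prior on this contrast's residuals, then test."""
    s2, nu = contrast_variances(matrix, spec)
    hp = fit_rvm_hyperparams(s2, nu)
    return permutation_pvalues(matrix, spec, hp, n_perm, seed)


# ---------------------------------------------------------------------------
# selection and overlap summaries


def select_de(result: pd.DataFrame, alpha: float) -> list[str]:
    """Genes with permutation p strictly below alpha, strongest |t| first."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if result.empty:
        return []
    hits = result[result["p_perm"] < alpha]
    # ties on |t| broken by identifier
    order = (hits.assign(abs_t=hits["t"].abs())
             .rename_axis("gene").reset_index()
             .sort_values(["abs_t", "gene"], ascending=[False, True],
                          kind="stable"))
    return list(order["gene"])


def venn_counts(lists: dict[str, list[str]]) -> dict[tuple[str, ...], int]:
    """Inclusion-exclusion region counts for 2 or 3 named gene lists.

    Keys are sorted tuples of the list names whose exclusive region the
    count describes; region counts sum to the size of the union.
    """
    if not 2 <= len(lists) <= 3:
        raise ValueError("venn_counts takes 2 or 3 named lists")
    sets = {name: set(v) for name, v in lists.items()}
    names = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            counts[combo] = len(inside - outside)
    return counts
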