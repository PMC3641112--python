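"""Temporal pattern discovery on differentially expressed genes.

Each gene is summarized by its 9-condition profile (group x timepoint
means, centered at the gene's grand mean and scaled to max |value| = 1) and
the profiles are clustered on a rectangular self-organizing map (default
3 x 6 = 18 nodes) under the Pearson-correlation distance d = 1 - r. The
map is trained in batch mode with a monotonically shrinking Gaussian
neighborhood, which makes training deterministic given the seed used to
sample the initial prototypes.

Node prototypes are then classified into the temporal pattern categories
(Progressive I/II, Long-term, up/down) by a deterministic rule set applied
to the prototype shape — the automated stand-in for the manual curation of
maps into categories — and genes inherit their node's label. A flat or
ambiguous prototype yields Unclassified.

The module also provides a Fisher-exact over-representation test of a gene
list against a gene-set collection (flat sets, no ontology propagation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CONDITIONS, ExpressionMatrix, GeneSetCollection, GROUPS, TIMEPOINTS

log = logging.getLogger(__name__)

CATEGORIES = (
    "ProgressiveI_Up", "ProgressiveI_Down",
    "ProgressiveII_Up", "ProgressiveII_Down",
    "LongTerm_Up", "LongTerm_Down",
    "Unclassified",
)


def condition_profiles(matrix: ExpressionMatrix,
                       genes: list[str] | None = None) -> pd.DataFrame:
    """Standardized 9-condition mean profiles (genes x conditions).

    Condition means are centered at the gene's grand mean (the mean of
    the 9 condition means, so each design cell counts equally) and scaled
    so the largest |value| is 1; constant genes map to the all-zero
    profile. Raises if any (group, timepoint) cell has no samples.
    """
    meta = matrix.require_design()
    cols = []
    for g, t in CONDITIONS:
        sel = matrix.select_samples(group=g, timepoint=t)
        if not sel:
            raise ValueError(f"design cell ({g}, {t}) has no samples")
        cols.append(matrix.values[sel].mean(axis=1))
    prof = pd.concat(cols, axis=1)
    prof.columns = [f"{g}@{t}" for g, t in CONDITIONS]
    if genes is not None:
        prof = prof.loc[list(genes)]
    arr = prof.to_numpy(float)
    arr = arr - arr.mean(axis=1, keepdims=True)
    scale = np.abs(arr).max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        arr = np.where(scale > 0, arr / scale, 0.0)
    return pd.DataFrame(arr, index=prof.index, columns=prof.columns)


# ---------------------------------------------------------------------------
# Pearson-distance batch SOM


def _pearson_distance(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """d = 1 - Pearson(x_i, w_j) for all profile/prototype pairs.

    A zero-variance vector has undefined correlation; its distance is
    defined as 1 to everything.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    wc = w - w.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc ** 2).sum(axis=1))
    wn = np.sqrt((wc ** 2).sum(axis=1))
    num = xc @ wc.T
    denom = np.outer(xn, wn)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    return 1.0 - r


@dataclass
class SOMGrid:
    """Trained map: prototypes, per-gene node assignment, grid geometry."""

    shape: tuple[int, int]
    prototypes: pd.DataFrame            # nodes x profile columns
    assignments: pd.Series              # gene -> node index
    quantization_errors: pd.Series      # node -> mean distance of members

    @property
    def n_nodes(self) -> int:
        return self.shape[0] * self.shape[1]

    def node_position(self, node: int) -> tuple[int, int]:
        return divmod(node, self.shape[1])

    def members(self, node: int) -> list[str]:
        return list(self.assignments.index[self.assignments == node])


def _grid_distances(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    pos = np.array([(r, c) for r in range(rows) for c in range(cols)], float)
    diff = pos[:, None, :] - pos[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def train_som(profiles: pd.DataFrame, shape: tuple[int, int] = (3, 6),
              seed: int = 0, epochs: int = 30,
              sigma_start: float | None = None,
              sigma_end: float = 0.5) -> SOMGrid:
    """Batch-train a rectangular SOM under Pearson distance.

    Prototypes are initialized by sampling input profiles (seeded);
    each epoch assigns every profile to its nearest prototype and moves
    each prototype to the Gaussian-neighborhood-weighted mean of the
    profiles, with the neighborhood radius decaying geometrically from
    ``sigma_start`` (default: half the larger grid side) to ``sigma_end``.
    """
    n_nodes = shape[0] * shape[1]
    x = profiles.to_numpy(float)
    if len(x) < n_nodes:
        raise ValueError(f"need >= {n_nodes} profiles for a {shape} grid")
    if np.allclose(x, x[0]):
        log.warning("all profiles identical: SOM degenerates to one node")
    rng = np.random.default_rng(seed)
    init_idx = rng.choice(len(x), size=n_nodes, replace=False)
    w = x[init_idx].copy()
    grid_d = _grid_distances(shape)
    if sigma_start is None:
        sigma_start = max(shape) / 2.0
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma_start * (sigma_end / sigma_start) ** frac
        d = _pearson_distance(x, w)
        bmu = d.argmin(axis=1)
        h = np.exp(-grid_d ** 2 / (2.0 * sigma ** 2))  # nodes x nodes
        weights = h[bmu]                                # genes x nodes
        denom = weights.sum(axis=0)
        num = weights.T @ x
        update = denom > 1e-12
        w[update] = num[update] / denom[update, None]
    d = _pearson_distance(x, w)
    bmu = d.argmin(axis=1)
    qerr = pd.Series(
        [d[bmu == j, j].mean() if (bmu == j).any() else np.nan
         for j in range(n_nodes)],
        index=range(n_nodes), name="quantization_error",
    )
    return SOMGrid(
        shape=shape,
        prototypes=pd.DataFrame(w, index=range(n_nodes),
                                columns=profiles.columns),
        assignments=pd.Series(bmu, index=profiles.index, name="node"),
        quantization_errors=qerr,
    )


def quantization_error(profiles: pd.DataFrame, prototypes: np.ndarray) -> float:
    """Mean best-matching-unit distance of the profiles to the prototypes."""
    d = _pearson_distance(profiles.to_numpy(float), np.asarray(prototypes, float))
    return float(d.min(axis=1).mean())


# ---------------------------------------------------------------------------
# prototype -> category rules


def classify_prototype(profile: np.ndarray, eps: float = 0.25) -> str:
    """Temporal category of one 9-condition prototype (or gene profile).

    Rules on the group-level means gN1, gN2, gM (averaged over timepoints,
    profile scaled to max |value| <= 1) with separation threshold ``eps``:

    * flat profile, or no M/N1 separation -> Unclassified;
    * N2 indistinguishable from N1 while M separates from both -> Long-term;
    * N2 between N1 and M in the shared direction -> Progressive
      (subtype I when M additionally separates from N2, else II);
    * anything else (non-monotone) -> Unclassified.
    """
    prof = np.asarray(profile, float).reshape(len(GROUPS), len(TIMEPOINTS))
    if np.abs(prof).max() < eps:
        return "Unclassified"
    g = prof.mean(axis=1)  # N1, N2, M
    d_m = g[2] - g[0]
    if abs(d_m) < eps:
        return "Unclassified"
    sign = 1 if d_m > 0 else -1
    suffix = "Up" if sign > 0 else "Down"
    d_n2 = g[1] - g[0]
    d_m_n2 = g[2] - g[1]
    if abs(d_n2) < eps / 2 and sign * d_m_n2 >= eps / 2:
        return f"LongTerm_{suffix}"
    if sign * d_n2 >= eps / 2:
        if sign * d_m_n2 >= eps / 2:
            return f"ProgressiveI_{suffix}"
        return f"ProgressiveII_{suffix}"
    return "Unclassified"


def merge_to_categories(grid: SOMGrid,
                        de_genes: list[str] | None = None,
                        eps: float = 0.25) -> pd.Series:
    """Assign every mapped gene its node prototype's pattern category.

    ``de_genes`` optionally restricts the output to a gene subset (the
    differentially expressed universe). Genes whose profile was all-zero
    sit on whichever node won the d=1 tie; their own flat profile keeps
    them meaningful only at node level, and flat *prototypes* are
    Unclassified, which is where such genes land in practice.
    """
    node_cat = {
        node: classify_prototype(grid.prototypes.loc[node].to_numpy(), eps)
        for node in grid.prototypes.index
    }
    cats = grid.assignments.map(node_cat)
    cats.name = "category"
    if de_genes is not None:
        cats = cats.loc[[g for g in de_genes if g in cats.index]]
    return cats


# ---------------------------------------------------------------------------
# Fisher-exact over-representation


def ora_fisher(query: list[str], collection: GeneSetCollection,
               background: list[str], alpha: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher-exact over-representation of a query gene list.

    Each set is intersected with the background before testing; the 2x2
    table is (query ∩ set, query \\ set, set \\ query, neither). Returns
    per set: overlap, set size (in background), odds ratio, p, and a
    significance flag at ``alpha`` (strict inequality).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    q = set(query)
    if not q <= bg:
        raise ValueError("query must be a subset of the background")
    rows = []
    for s in collection:
        members = s.genes & bg
        k = len(q & members)
        table = [[k, len(q) - k],
                 [len(members) - k, len(bg) - len(q) - len(members) + k]]
        if k == 0:
            odds, p = 0.0, 1.0
        else:
            odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append((s.name, k, len(members), odds, p, p < alpha))
    return pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "odds_ratio", "p",
                       "significant"],
    ).set_index("set")
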