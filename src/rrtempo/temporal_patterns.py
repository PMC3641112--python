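"""Dot-matrix assembly, temporal pattern calls and enrichment-map merging.

Every gene set is summarized over the full contrast grid: a solid "dot"
for each across-group comparison (N1vsN2, N1vsM, N2vsM) x timepoint where
the enrichment FDR q fell below 0.25, and a star tier for each within-group
time contrast (T0vsT1, T0vsT2, T1vsT2) x group where the nominal p fell
below 0.09 / 0.05 / 0.01 (1/2/3 stars). Dots and stars carry the
enrichment direction: positive means enrichment in the more-practiced
group (across) or the later timepoint (within).

Pattern calls follow an ordered rule table on the across-group dots:

1. Long-term — M separates from both N1 and N2 at >= 2 timepoints and N1
   never differs from N2;
2. Progressive I — all three comparisons fire at >= 1 timepoint (N2 and M
   both differ from N1, and M additionally from N2);
3. Progressive II — N2 and M differ from N1 but M never differs from N2
   at T0 or T1;
4. otherwise Unclassified. Rows mixing up- and down-dots are Unclassified.

Enriched sets are merged into functional modules when their overlap
coefficient |A ∩ B| / min(|A|, |B|) reaches 0.70; modules are the
connected components of the resulting overlap graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GROUPS, TIMEPOINTS

log = logging.getLogger(__name__)

ACROSS_COMPARISONS = ("N1vsN2", "N1vsM", "N2vsM")
WITHIN_CONTRASTS = ("T0vsT1", "T0vsT2", "T1vsT2")

DEFAULT_FDR = 0.25
DEFAULT_STARS = (0.09, 0.05, 0.01)


@dataclass
class DotMatrix:
    """Per-set significance grid.

    ``across``: sets x 9 cells (comparison@timepoint), values +1 / -1 for
    a directed dot, 0 for tested-but-not-significant, NaN for untested.
    ``within``: sets x 9 cells (contrast@group), signed star count
    (+-1..3), 0 none, NaN untested.
    """

    across: pd.DataFrame
    within: pd.DataFrame
    fdr_threshold: float = DEFAULT_FDR
    star_levels: tuple[float, ...] = DEFAULT_STARS

    @property
    def sets(self) -> list[str]:
        return list(self.across.index)


@dataclass(frozen=True)
class PatternCall:
    set_name: str
    category: str
    citations: tuple[str, ...] = ()


def _cell_name(comparison: str, fixed: str) -> str:
    return f"{comparison}@{fixed}"


def build_dot_matrix(
    across_results: Mapping[tuple[str, str], pd.DataFrame]
    | Sequence[tuple[str, str, pd.DataFrame]],
    within_results: Mapping[tuple[str, str], pd.DataFrame]
    | Sequence[tuple[str, str, pd.DataFrame]],
    fdr_threshold: float = DEFAULT_FDR,
    star_levels: tuple[float, ...] = DEFAULT_STARS,
) -> DotMatrix:
    """Assemble the dot matrix from per-cell enrichment result tables.

    ``across_results`` maps (comparison, timepoint) — comparison in
    ``N1vsN2 / N1vsM / N2vsM`` — to an enrichment table with ``fdr_q``
    and ``es`` columns; ``within_results`` maps (time contrast, group) to
    a table with ``p_nom`` and ``es``. Missing cells are recorded as
    untested (NaN); duplicate cells with conflicting tables are an error.
    """
    across = _normalize_cells(across_results, ACROSS_COMPARISONS, TIMEPOINTS)
    within = _normalize_cells(within_results, WITHIN_CONTRASTS, GROUPS)
    set_names = sorted(
        set().union(*(set(df.index) for df in across.values()),
                    *(set(df.index) for df in within.values()))
    )
    across_cols = [_cell_name(c, t) for c in ACROSS_COMPARISONS for t in TIMEPOINTS]
    within_cols = [_cell_name(c, g) for c in WITHIN_CONTRASTS for g in GROUPS]
    amat = pd.DataFrame(np.nan, index=set_names, columns=across_cols)
    wmat = pd.DataFrame(np.nan, index=set_names, columns=within_cols)
    for (comp, tp), df in across.items():
        col = _cell_name(comp, tp)
        flag = (df["fdr_q"] < fdr_threshold).astype(int)
        amat.loc[df.index, col] = flag * np.sign(df["es"]).astype(int)
    for (con, grp), df in within.items():
        col = _cell_name(con, grp)
        stars = np.zeros(len(df), int)
        for level in sorted(star_levels, reverse=True):  # 0.09 -> 1 star etc
            stars += (df["p_nom"].to_numpy() < level).astype(int)
        wmat.loc[df.index, col] = stars * np.sign(df["es"]).astype(int)
    return DotMatrix(amat, wmat, fdr_threshold, tuple(star_levels))


def _normalize_cells(results, first_axis, second_axis):
    if isinstance(results, Mapping):
        items = list(results.items())
        items = [((a, b), df) for (a, b), df in items]
    else:
        items = [((a, b), df) for a, b, df in results]
    seen: dict[tuple[str, str], pd.DataFrame] = {}
    for key, df in items:
        a, b = key
        if a not in first_axis or b not in second_axis:
            raise ValueError(f"unknown dot-matrix cell {key}")
        if key in seen:
            if not seen[key].equals(df):
                raise ValueError(f"conflicting duplicate results for cell {key}")
            continue
        seen[key] = df
    return seen


# ---------------------------------------------------------------------------
# pattern rules


def classify_pattern(across_row: pd.Series,
                     set_name: str = "") -> PatternCall:
    """Apply the ordered pattern rule table to one set's across-group row.

    ``across_row`` is indexed by ``comparison@timepoint`` with values
    +-1 (directed dot), 0 or NaN. Mixed dot directions yield Unclassified.
    """
    dots: dict[tuple[str, str], int] = {}
    for cell, val in across_row.items():
        if pd.isna(val) or val == 0:
            continue
        comp, tp = cell.split("@")
        dots[(comp, tp)] = int(np.sign(val))
    if not dots:
        return PatternCall(set_name, "Unclassified")
    signs = set(dots.values())
    if len(signs) > 1:
        log.info("set %s: mixed dot directions -> Unclassified", set_name)
        return PatternCall(set_name, "Unclassified")
    suffix = "Up" if signs.pop() > 0 else "Down"
    cites = tuple(sorted(_cell_name(c, t) for c, t in dots))
    n12 = sum(1 for (c, _t) in dots if c == "N1vsN2")
    n1m = sum(1 for (c, _t) in dots if c == "N1vsM")
    n2m = sum(1 for (c, _t) in dots if c == "N2vsM")
    early_n2m = any((("N2vsM", tp) in dots) for tp in ("T0", "T1"))
    if n1m >= 2 and n2m >= 2 and n12 == 0:
        return PatternCall(set_name, f"LongTerm_{suffix}", cites)
    if n12 >= 1 and n1m >= 1 and n2m >= 1:
        return PatternCall(set_name, f"ProgressiveI_{suffix}", cites)
    if n12 >= 1 and n1m >= 1 and not early_n2m:
        return PatternCall(set_name, f"ProgressiveII_{suffix}", cites)
    return PatternCall(set_name, "Unclassified")


def classify_all(matrix: DotMatrix) -> pd.DataFrame:
    """Pattern call for every set in a dot matrix."""
    calls = [classify_pattern(matrix.across.loc[name], name)
             for name in matrix.sets]
    return pd.DataFrame(
        {"category": [c.category for c in calls],
         "citations": [";".join(c.citations) for c in calls]},
        index=pd.Index(matrix.sets, name="set"),
    )


# ---------------------------------------------------------------------------
# enrichment-map module merging


def merge_gene_sets(members: Mapping[str, Iterable[str]],
                    overlap_threshold: float = 0.70) -> pd.Series:
    """Merge sets into modules by overlap coefficient >= threshold.

    ``members`` maps set name to its (enriched) member genes. Sets whose
    overlap coefficient |A ∩ B| / min(|A|, |B|) reaches the threshold are
    neighbors; modules are connected components of the neighbor graph and
    each is labelled by its largest member set (ties by name). Returns a
    Series: set name -> module label. The result is a partition of the
    input sets.
    """
    if not members:
        raise ValueError("need at least one gene set")
    sets = {name: set(genes) for name, genes in members.items()}
    graph = nx.Graph()
    graph.add_nodes_from(sets)
    names = sorted(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            smaller = min(len(sets[a]), len(sets[b]))
            if smaller == 0:
                continue
            coeff = len(sets[a] & sets[b]) / smaller
            if coeff >= overlap_threshold:
                graph.add_edge(a, b)
    module_of: dict[str, str] = {}
    for component in nx.connected_components(graph):
        label = max(sorted(component), key=lambda n: len(sets[n]))
        for name in component:
            module_of[name] = label
    return pd.Series(module_of, name="module").loc[list(members)]
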