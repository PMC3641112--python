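"""Synthetic study generator with planted temporal structure.

Emulates the design of the relaxation-response session study: three groups
(N1 novices, N2 the same subjects after short-term training, M independent
long-term practitioners) sampled at three timepoints T0/T1/T2, with gene
modules planted to follow the temporal pattern categories the downstream
analysis is meant to recover:

``ProgressiveI``
    group offsets 0 / beta/2 / beta for N1 / N2 / M, session time slope
    gamma in M only — expression lowest in N1, intermediate in N2,
    highest and still rising within the session in M.
``ProgressiveII``
    group offsets 0 / beta / beta, time slope gamma in both N2 and M —
    short- and long-term practice look alike, both differ from novices,
    and M never separates from N2.
``LongTerm``
    group offsets 0 / 0 / beta, a configurable within-M slope
    (default -gamma/2, i.e. the M elevation relaxes within the session) —
    only long-term practice separates from both other groups.

``_Up`` / ``_Down`` suffixes flip the sign of the whole planted effect.
Null genes carry no group or time effect. The generative model per gene g
and sample (subject s, group G, timepoint t in {0,1,2}) is

    y = b_g + u_{g,s} + sign * (delta_pattern(G)*beta
                                + slope_pattern(G)*gamma*t) + eps

with eps ~ N(0, sigma^2) and per-(gene, subject) intercepts
u ~ N(0, tau^2) shared across timepoints, and — because N1 and N2 are the
same people before and after training — shared between a subject's N1 and
N2 samples. Intercepts are independent across genes, so genes are
statistically independent and permutation-calibration checks on gene
ensembles are valid.

All generators are pure functions of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet, GeneSetCollection, GROUPS, TIMEPOINTS

PATTERNS = (
    "ProgressiveI_Up",
    "ProgressiveI_Down",
    "ProgressiveII_Up",
    "ProgressiveII_Down",
    "LongTerm_Up",
    "LongTerm_Down",
)
NULL = "Null"

#: per-pattern family: group -> multiplier of beta (delta) and of gamma (slope)
_FAMILY_DELTA: Mapping[str, Mapping[str, float]] = {
    "ProgressiveI": {"N1": 0.0, "N2": 0.5, "M": 1.0},
    "ProgressiveII": {"N1": 0.0, "N2": 1.0, "M": 1.0},
    "LongTerm": {"N1": 0.0, "N2": 0.0, "M": 1.0},
}
_FAMILY_SLOPE: Mapping[str, Mapping[str, float]] = {
    "ProgressiveI": {"N1": 0.0, "N2": 0.0, "M": 1.0},
    "ProgressiveII": {"N1": 0.0, "N2": 1.0, "M": 1.0},
    "LongTerm": {"N1": 0.0, "N2": 0.0, "M": None},  # filled from config
}


def split_pattern(pattern: str) -> tuple[str, int]:
    """Return (family, sign) for a planted pattern name."""
    family, _, direction = pattern.rpartition("_")
    return family, (1 if direction == "Up" else -1)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults describe a desk-scale version of the design: 8 subjects per
    group (the study enrolled 26), 500 genes, all six planted pattern
    modules plus 6 decoy sets, moderate effects (beta twice the residual
    SD) and a within-session slope half the group effect.
    """

    n_subjects_per_group: int = 8
    n_genes: int = 500
    planted_patterns: tuple[str, ...] = PATTERNS
    n_decoys: int = 6
    set_size_range: tuple[int, int] = (10, 30)
    beta: float = 1.0        # group effect, log-expression units
    gamma: float = 0.5       # within-session slope per timepoint step (M)
    tau: float = 0.5         # subject-intercept SD
    sigma: float = 0.5       # residual SD
    longterm_slope_mult: float = -0.5   # within-M slope of LongTerm, in gamma units
    covariate_r: float = 0.8            # target covariate/pathway correlation
    covariate_pattern: str = "ProgressiveI_Down"
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not abs(self.covariate_r) < 1:
            raise ValueError("|covariate_r| must be < 1")
        lo, hi = self.set_size_range
        if lo < 2 or hi < lo or hi > self.n_genes:
            raise ValueError("set sizes must satisfy 2 <= lo <= hi <= n_genes")
        unknown = set(self.planted_patterns) - set(PATTERNS)
        if unknown:
            raise ValueError(f"unknown planted patterns: {sorted(unknown)}")
        if len(set(self.planted_patterns)) != len(self.planted_patterns):
            raise ValueError("planted patterns must be distinct")
        if self.covariate_pattern not in PATTERNS:
            raise ValueError(f"unknown covariate pattern {self.covariate_pattern!r}")


@dataclass
class PlantedTruth:
    """Ground truth needed by recovery tests."""

    gene_patterns: dict[str, str]        # gene -> pattern (or "Null")
    set_patterns: dict[str, str]         # set name -> pattern ("Null" = decoy)
    set_members: dict[str, tuple[str, ...]]
    hub_nodes: tuple[str, ...] = ()

    def genes_of(self, pattern: str) -> list[str]:
        return [g for g, p in self.gene_patterns.items() if p == pattern]

    @property
    def null_genes(self) -> list[str]:
        return self.genes_of(NULL)


def _effect(pattern: str, group: str, t: int, config: SimulationConfig) -> float:
    family, sign = split_pattern(pattern)
    slope = _FAMILY_SLOPE[family][group]
    if slope is None:  # LongTerm within-M slope comes from the config
        slope = config.longterm_slope_mult
    return sign * (_FAMILY_DELTA[family][group] * config.beta
                   + slope * config.gamma * t)


def planted_set_name(pattern: str) -> str:
    return "SET_" + pattern.upper()


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Simulate the full genes x samples log-expression matrix.

    Planted modules occupy disjoint leading blocks of the gene list (a gene
    belongs to at most one pattern); remaining genes are Null. Raises if
    the requested module sizes cannot fit disjointly into ``n_genes``
    while leaving enough Null genes for decoy sets.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.set_size_range
    sizes = rng.integers(lo, hi + 1, size=len(config.planted_patterns))
    if int(sizes.sum()) + max(hi, 1) > config.n_genes:
        raise ValueError(
            "planted sets would overlap: "
            f"{int(sizes.sum())} planted genes (+decoy room) exceed "
            f"n_genes={config.n_genes}"
        )

    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(config.n_genes)]
    gene_patterns = {g: NULL for g in genes}
    set_patterns: dict[str, str] = {}
    set_members: dict[str, tuple[str, ...]] = {}
    cursor = 0
    for pattern, size in zip(config.planted_patterns, sizes):
        members = tuple(genes[cursor:cursor + int(size)])
        cursor += int(size)
        for g in members:
            gene_patterns[g] = pattern
        name = planted_set_name(pattern)
        set_patterns[name] = pattern
        set_members[name] = members

    # design: N1/N2 share subjects (pre/post training), M is independent
    n = config.n_subjects_per_group
    swidth = max(2, len(str(n)))
    shared = [f"S{i:0{swidth}d}" for i in range(n)]
    m_subj = [f"P{i:0{swidth}d}" for i in range(n)]
    rows = []
    for group in GROUPS:
        subjects = m_subj if group == "M" else shared
        for subj in subjects:
            for tp in TIMEPOINTS:
                rows.append((f"{group}_{subj}_{tp}", subj, group, tp))
    design = pd.DataFrame(rows, columns=["sample_id", "subject", "group",
                                         "timepoint"]).set_index("sample_id")

    n_samples = len(design)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    # per-(gene, subject) intercepts: the 2n distinct people
    people = shared + m_subj
    intercepts = rng.normal(0.0, config.tau, (config.n_genes, len(people)))
    person_of_sample = np.array([people.index(s) for s in design["subject"]])

    effects = np.zeros((config.n_genes, n_samples))
    tidx = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    gene_row = {g: i for i, g in enumerate(genes)}
    for j, (_, meta) in enumerate(design.iterrows()):
        g_lab, t = meta["group"], tidx[meta["timepoint"]]
        for name, members in set_members.items():
            eff = _effect(set_patterns[name], g_lab, t, config)
            if eff != 0.0:
                effects[[gene_row[m] for m in members], j] += eff

    noise = rng.normal(0.0, config.sigma, (config.n_genes, n_samples))
    values = (baseline[:, None] + intercepts[:, person_of_sample]
              + effects + noise)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                     columns=design.index),
        design,
    )
    truth = PlantedTruth(gene_patterns, set_patterns, set_members)
    truth.hub_nodes = tuple(members[0] for members in set_members.values())
    return matrix, truth


def generate_gene_sets(config: SimulationConfig, truth: PlantedTruth) -> GeneSetCollection:
    """One set per planted pattern plus decoy sets of random Null genes."""
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.set_size_range
    sets = [GeneSet(name, f"planted {truth.set_patterns[name]}",
                    frozenset(members))
            for name, members in truth.set_members.items()]
    null_genes = np.array(truth.null_genes)
    for i in range(config.n_decoys):
        size = int(rng.integers(lo, min(hi, len(null_genes)) + 1))
        members = rng.choice(null_genes, size=size, replace=False)
        name = f"DECOY{i + 1}"
        truth.set_patterns[name] = NULL
        sets.append(GeneSet(name, "decoy (null genes)", frozenset(members)))
    return GeneSetCollection(sets)


def generate_network(truth: PlantedTruth, n_background_nodes: int,
                     seed: int) -> nx.Graph:
    """Reference interaction network with one planted hub per component.

    Each planted hub is the centre of a star over its module's remaining
    genes, bridged by a single edge into a private random background
    component of Null genes. The background is capped so the hub's spokes
    are more than a quarter of the component: removing the hub always
    disconnects at least that fraction.
    """
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    null_pool = list(truth.null_genes)
    rng.shuffle(null_pool)
    n_hubs = max(1, len(truth.hub_nodes))
    per_hub_bg = n_background_nodes // n_hubs
    for hub, (name, members) in zip(truth.hub_nodes, truth.set_members.items()):
        spokes = [m for m in members if m != hub]
        for s in spokes:
            graph.add_edge(hub, s, relation="pp")
        # cap the background so spokes exceed a quarter of the component
        bg_size = min(per_hub_bg, max(0, 3 * len(spokes) - 1), len(null_pool))
        bg_nodes = [null_pool.pop() for _ in range(bg_size)]
        if bg_nodes:
            # random connected background: a random tree plus a few chords
            order = list(range(len(bg_nodes)))
            for i in range(1, len(bg_nodes)):
                j = int(rng.integers(0, i))
                graph.add_edge(bg_nodes[order[i]], bg_nodes[order[j]],
                               relation="pp")
            n_extra = max(0, len(bg_nodes) // 4)
            for _ in range(n_extra):
                i, j = rng.integers(0, len(bg_nodes), 2)
                if i != j:
                    graph.add_edge(bg_nodes[int(i)], bg_nodes[int(j)],
                                   relation="pp")
            graph.add_edge(hub, bg_nodes[0], relation="pp")
    return graph


def generate_covariate(matrix: ExpressionMatrix, truth: PlantedTruth,
                       config: SimulationConfig) -> pd.Series:
    """Per-sample physiological covariate tracking a planted pathway.

    The covariate is ``r * z + sqrt(1 - r^2) * noise`` where ``z`` is the
    standardized per-sample mean expression of the planted pathway named
    in ``config.covariate_pattern``, so its population correlation with
    the pathway score equals ``covariate_r`` exactly.
    """
    if not abs(config.covariate_r) < 1:
        raise ValueError("|covariate_r| must be < 1")
    genes = truth.genes_of(config.covariate_pattern)
    if not genes:
        raise ValueError(
            f"no genes planted with pattern {config.covariate_pattern!r}"
        )
    rng = np.random.default_rng(config.seed + 2)
    score = matrix.values.loc[genes].mean(axis=0).to_numpy()
    z = (score - score.mean()) / score.std(ddof=0)
    r = config.covariate_r
    noise = rng.standard_normal(len(z))
    cov = r * z + np.sqrt(1.0 - r * r) * noise
    return pd.Series(cov, index=matrix.sample_ids, name="value")
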