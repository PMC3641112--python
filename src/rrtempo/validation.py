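"""Statistical self-checks of the pipeline on synthetic data.

These routines re-derive, at runtime, the operating characteristics the
method is supposed to have: permutation-test calibration under the null,
recovery of planted temporal pattern categories, and recovery of planted
network hubs. They are used by the test suite and by the reproduction
script; none of them is needed for analysing real data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import diffexp, gsea, network_hubs, temporal_patterns
from .containers import ExpressionMatrix, TIMEPOINTS
from .diffexp import ComparisonSpec
from .pipeline import ACROSS_CLASS_ORDER
from .synthetic_data import (
    NULL,
    SimulationConfig,
    generate_expression,
    generate_gene_sets,
    generate_network,
)


def de_null_calibration(n_genes: int = 2000, n_subjects: int = 8,
                        n_perm: int = 200, seed: int = 0,
                        paired: bool = False) -> np.ndarray:
    """Permutation p-values of every gene under the null generator.

    The generator runs with beta = gamma = 0 so no gene carries any group
    or time effect; the returned p-vector should be (sub)uniform.
    Unpaired mode tests M vs N1 at T1; paired mode tests T1 vs T0 within
    N1 (per-subject sign flips).
    """
    config = SimulationConfig(
        n_genes=n_genes, n_subjects_per_group=n_subjects,
        beta=0.0, gamma=0.0, seed=seed,
    )
    matrix, _ = generate_expression(config)
    if paired:
        spec = ComparisonSpec.within("N1", "T1", "T0")
    else:
        spec = ComparisonSpec.across("M", "N1", "T1")
    res = diffexp.run_contrast(matrix, spec, n_perm, seed + 1)
    return res["p_perm"].to_numpy()


def across_enrichment_grid(matrix: ExpressionMatrix, collection,
                           n_perm: int, seed: int,
                           mode: str = "auto") -> dict:
    """The 9 across-group enrichment tables keyed by (comparison, timepoint)."""
    meta = matrix.require_design()
    out = {}
    counter = 0
    for comp, (pos, neg) in ACROSS_CLASS_ORDER.items():
        for tp in TIMEPOINTS:
            sel = (matrix.select_samples(group=pos, timepoint=tp)
                   + matrix.select_samples(group=neg, timepoint=tp))
            sub = ExpressionMatrix(matrix.values[sel], meta.loc[sel])
            labels = meta.loc[sel, "group"].to_numpy()
            paired = meta.loc[sel, "subject"].to_numpy() \
                if "M" not in (pos, neg) else None
            out[(comp, tp)] = gsea.permutation_significance(
                sub, labels, collection, n_perm, seed + counter,
                mode=mode, classes=(pos, neg), paired_subjects=paired)
            counter += 1
    return out


def pattern_recovery(seed: int, n_subjects: int = 20, n_perm: int = 100,
                     n_genes: int = 500) -> pd.DataFrame:
    """Planted-category recovery of the GSEA dot-matrix classifier.

    Simulates the standard planted design (six pattern modules plus
    decoys, beta = 2 sigma), runs the nine across-group enrichment cells,
    classifies every set, and returns a table with the planted and called
    category per set.
    """
    config = SimulationConfig(n_genes=n_genes,
                              n_subjects_per_group=n_subjects, seed=seed)
    matrix, truth = generate_expression(config)
    collection = generate_gene_sets(config, truth)
    grid = across_enrichment_grid(matrix, collection, n_perm, seed * 100 + 1)
    dots = temporal_patterns.build_dot_matrix(grid, {})
    calls = temporal_patterns.classify_all(dots)
    calls["planted"] = [truth.set_patterns[s] for s in calls.index]
    return calls


def recovery_rates(calls: pd.DataFrame) -> tuple[float, float]:
    """(planted sets called correctly, decoys left Unclassified) rates."""
    planted = calls[calls["planted"] != NULL]
    decoys = calls[calls["planted"] == NULL]
    planted_rate = float((planted["category"] == planted["planted"]).mean()) \
        if len(planted) else float("nan")
    decoy_rate = float((decoys["category"] == "Unclassified").mean()) \
        if len(decoys) else float("nan")
    return planted_rate, decoy_rate


def hub_recovery_rate(n_seeds: int = 40, seed0: int = 0,
                      n_background: int = 120) -> float:
    """Fraction of generator seeds whose planted hubs top their component.

    For each seed a planted network is generated and the bottleneck
    ranking computed; a seed counts as recovered when every planted hub
    attains the highest BN score within its connected component.
    """
    import networkx as nx

    hits = 0
    for s in range(seed0, seed0 + n_seeds):
        config = SimulationConfig(seed=s)
        _, truth = _truth_only(config)
        net = generate_network(truth, n_background, seed=s + 7)
        scores = network_hubs.bottleneck_scores(net)
        ok = True
        for comp in nx.connected_components(net):
            comp_hubs = [h for h in truth.hub_nodes if h in comp]
            if not comp_hubs:
                continue
            top = scores.loc[sorted(comp)].idxmax()
            best = scores.loc[sorted(comp)].max()
            if not any(scores[h] == best for h in comp_hubs):
                ok = False
        hits += ok
    return hits / n_seeds


def _truth_only(config: SimulationConfig):
    """Planted truth without paying for the full expression simulation."""
    small = dataclasses.replace(config, n_subjects_per_group=2)
    return generate_expression(small)
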