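"""End-to-end orchestration: simulate -> diffexp -> som -> gsea -> patterns -> hubs.

Every stage reads files written by earlier stages (never in-memory state),
so any stage can be re-run in isolation from the manifest. One global seed
is expanded into per-stage, per-contrast seeds by a fixed counter scheme;
adding a stage never perturbs earlier stages' randomness. All thresholds
default to the published criteria (DE alpha 0.01; enrichment NPV 0.05 and
FDR 0.25; within-group star tiers 0.09/0.05/0.01; 70% overlap merging;
top-20 hubs) and every override is stamped into the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, gsea, io_formats, network_hubs, som_patterns, temporal_patterns
from .containers import ExpressionMatrix, GeneSetCollection, GROUPS, TIMEPOINTS
from .diffexp import ComparisonSpec
from .synthetic_data import (
    SimulationConfig,
    generate_covariate,
    generate_expression,
    generate_gene_sets,
    generate_network,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

#: (comparison name, (positive class, negative class)) — positive class is
#: the more-practiced group, so positive statistics mean "up with practice"
ACROSS_CLASS_ORDER = {
    "N1vsN2": ("N2", "N1"),
    "N1vsM": ("M", "N1"),
    "N2vsM": ("M", "N2"),
}
#: within contrasts: positive class is the later timepoint
WITHIN_CLASS_ORDER = {
    "T0vsT1": ("T1", "T0"),
    "T0vsT2": ("T2", "T0"),
    "T1vsT2": ("T2", "T1"),
}

_STAGE_OFFSET = {"simulate": 0, "diffexp": 1_000, "som": 2_000,
                 "gsea": 3_000, "patterns": 4_000, "hubs": 5_000}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def stage_seed(base_seed: int, stage: str, counter: int = 0) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (base_seed * 9_973 + _STAGE_OFFSET[stage] + counter) % (2 ** 31)


@dataclass(frozen=True)
class AnalysisConfig:
    """Single configuration object for a full run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    inputs: dict | None = None        # optional paths: gct, design, gmt, sif, covariate
    alpha: float = 0.01               # DE permutation-p threshold (strict <)
    fdr: float = 0.25                 # enrichment FDR dot threshold
    npv: float = 0.05                 # enrichment nominal-p threshold
    star_levels: tuple[float, ...] = (0.09, 0.05, 0.01)
    overlap: float = 0.70             # enrichment-map overlap coefficient
    k_hubs: int = 20
    n_perm_de: int = 1000
    n_perm_gsea: int = 500
    gsea_mode: str = "auto"
    som_shape: tuple[int, int] = (3, 6)
    som_epochs: int = 30
    expand_neighbors: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr", "npv", "overlap"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for lvl in self.star_levels:
            if not 0 < lvl < 1:
                raise ValueError("star levels must be in (0, 1)")
        if min(self.n_perm_de, self.n_perm_gsea) < 10:
            raise ValueError("permutation counts must be >= 10")
        if self.inputs is not None:
            required = {"gct", "design", "gmt"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"inputs missing entries: {sorted(missing)}")
            for key, path in self.inputs.items():
                if not Path(path).is_file():
                    raise ValueError(f"input {key} does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**{
            **raw.pop("simulation", {}),
        }) if "simulation" in raw or "inputs" not in raw else SimulationConfig()
        if "star_levels" in raw:
            raw["star_levels"] = tuple(raw["star_levels"])
        if "som_shape" in raw:
            raw["som_shape"] = tuple(raw["som_shape"])
        return cls(simulation=sim, **raw)

    def canonical_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=default)


def contrast_roster() -> tuple[list[ComparisonSpec], list[ComparisonSpec]]:
    """All 9 across-group and 9 within-group contrasts of the design."""
    across, within = [], []
    for comp, (pos, neg) in ACROSS_CLASS_ORDER.items():
        for tp in TIMEPOINTS:
            across.append(ComparisonSpec.across(pos, neg, tp))
    for con, (later, earlier) in WITHIN_CLASS_ORDER.items():
        for grp in GROUPS:
            within.append(ComparisonSpec.within(grp, later, earlier))
    return across, within


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def _load_inputs(config: AnalysisConfig):
    paths = config.inputs
    with open(paths["gct"]) as fh:
        matrix = io_formats.parse_gct(fh)
    with open(paths["design"]) as fh:
        matrix = matrix.attach_design(io_formats.parse_design_tsv(fh))
    with open(paths["gmt"]) as fh:
        collection = io_formats.parse_gmt(fh)
    network = None
    if "sif" in paths:
        with open(paths["sif"]) as fh:
            network = io_formats.parse_sif(fh)
    covariate = None
    if "covariate" in paths:
        with open(paths["covariate"]) as fh:
            covariate = io_formats.parse_covariate_tsv(fh)
    return matrix, None, collection, network, covariate


def run_pipeline(config: AnalysisConfig, out_dir: str | Path) -> Path:
    """Execute every stage; returns the run directory.

    On stage failure a ``failed`` marker naming the stage and a
    machine-readable code is left in the run directory, partial outputs
    are retained, and :class:`PipelineError` is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()).hexdigest(),
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha, "fdr": config.fdr, "npv": config.npv,
            "star_levels": list(config.star_levels),
            "overlap": config.overlap, "k_hubs": config.k_hubs,
        },
        "permutations": {"de": config.n_perm_de, "gsea": config.n_perm_gsea},
        "stages": {},
    }
    stage = "simulate"
    try:
        # -- stage 1: simulate (or load) --------------------------------
        if config.inputs is None:
            sim = dataclasses.replace(config.simulation,
                                      seed=stage_seed(config.seed, "simulate"))
            matrix, truth = generate_expression(sim)
            collection = generate_gene_sets(sim, truth)
            network = generate_network(truth, sim.n_genes // 4,
                                       stage_seed(config.seed, "simulate", 1))
            covariate = generate_covariate(matrix, truth, sim)
            with open(out / "expression.gct", "w") as fh:
                io_formats.write_gct(matrix, fh)
            with open(out / "design.tsv", "w") as fh:
                io_formats.write_design_tsv(matrix.samples, fh)
            with open(out / "sets.gmt", "w") as fh:
                io_formats.write_gmt(collection, fh)
            with open(out / "network.sif", "w") as fh:
                io_formats.write_sif(network, fh)
            with open(out / "covariate.tsv", "w") as fh:
                io_formats.write_covariate_tsv(covariate, fh)
            for tp in TIMEPOINTS:  # group labels per timepoint slice
                sel = matrix.select_samples(timepoint=tp)
                with open(out / f"groups_{tp}.cls", "w") as fh:
                    io_formats.write_cls(
                        matrix.samples.loc[sel, "group"], fh)
            pd.Series(truth.gene_patterns, name="pattern").rename_axis(
                "gene").to_frame().to_csv(out / "truth_genes.tsv", sep="\t")
            pd.Series(truth.set_patterns, name="pattern").rename_axis(
                "set").to_frame().to_csv(out / "truth_sets.tsv", sep="\t")
        else:
            matrix, truth, collection, network, covariate = _load_inputs(config)
        manifest["stages"]["simulate"] = {
            "n_genes": int(matrix.values.shape[0]),
            "n_samples": int(matrix.values.shape[1]),
            "n_sets": len(collection),
        }

        # -- stage 2: differential expression ---------------------------
        stage = "diffexp"
        across_specs, within_specs = contrast_roster()
        de_results: dict[str, pd.DataFrame] = {}
        de_genes: dict[str, list[str]] = {}
        for i, spec in enumerate(across_specs + within_specs):
            res = diffexp.run_contrast(
                matrix, spec, config.n_perm_de,
                stage_seed(config.seed, "diffexp", i))
            de_results[spec.label] = res
            de_genes[spec.label] = diffexp.select_de(res, config.alpha)
            _write_tsv(res.round(12), out / f"de_{spec.label}.tsv")
        venn_rows = []
        for tp in TIMEPOINTS:
            lists = {s.label: de_genes[s.label]
                     for s in across_specs if s.fixed == tp}
            for region, count in diffexp.venn_counts(lists).items():
                venn_rows.append(("across", tp, "&".join(region), count))
        for grp in GROUPS:
            lists = {s.label: de_genes[s.label]
                     for s in within_specs if s.fixed == grp}
            for region, count in diffexp.venn_counts(lists).items():
                venn_rows.append(("within", grp, "&".join(region), count))
        venn = pd.DataFrame(venn_rows,
                            columns=["kind", "cell", "region", "count"])
        venn.to_csv(out / "venn.tsv", sep="\t", index=False)
        manifest["stages"]["diffexp"] = {
            "contrasts": len(de_results),
            "de_genes_union": len(set().union(*de_genes.values())),
        }

        # -- stage 3: SOM temporal maps ----------------------------------
        stage = "som"
        universe = list(set().union(*de_genes.values()))
        n_nodes = config.som_shape[0] * config.som_shape[1]
        if len(universe) < 2 * n_nodes:
            # too few DE genes to populate the map: widen with the
            # strongest remaining genes (by best permutation p, then |t|)
            best = pd.concat(
                [r[["t", "p_perm"]].assign(abs_t=r["t"].abs())
                 for r in de_results.values()]
            ).groupby(level=0).agg({"p_perm": "min", "abs_t": "max"})
            extra = (best.drop(index=universe, errors="ignore")
                     .sort_values(["p_perm", "abs_t"],
                                  ascending=[True, False])
                     .head(2 * n_nodes - len(universe)))
            log.info("SOM: widening %d DE genes with %d top-ranked genes",
                     len(universe), len(extra))
            universe = universe + list(extra.index)
        universe = sorted(universe)
        profiles = som_patterns.condition_profiles(matrix, universe)
        grid = som_patterns.train_som(
            profiles, config.som_shape,
            seed=stage_seed(config.seed, "som"), epochs=config.som_epochs)
        categories = som_patterns.merge_to_categories(grid)
        _write_tsv(grid.prototypes, out / "som_prototypes.tsv")
        grid.assignments.rename_axis("gene").to_frame().join(
            categories.rename("category")).to_csv(
                out / "som_assignments.tsv", sep="\t")
        ora_reports = []
        background = list(matrix.genes)
        for cat in sorted(set(categories)):
            if cat == "Unclassified":
                continue
            ora = som_patterns.ora_fisher(
                sorted(categories.index[categories == cat]), collection,
                background)
            ora_reports.append(ora.assign(category=cat))
        if ora_reports:
            _write_tsv(pd.concat(ora_reports), out / "som_ora.tsv")
        manifest["stages"]["som"] = {
            "genes_mapped": len(profiles),
            "occupied_nodes": int(grid.assignments.nunique()),
        }

        # -- stage 4: GSEA over the full contrast grid --------------------
        stage = "gsea"
        meta = matrix.require_design()
        across_enrich: dict[tuple[str, str], pd.DataFrame] = {}
        within_enrich: dict[tuple[str, str], pd.DataFrame] = {}
        counter = 0
        for comp, (pos, neg) in ACROSS_CLASS_ORDER.items():
            for tp in TIMEPOINTS:
                sel = (matrix.select_samples(group=pos, timepoint=tp)
                       + matrix.select_samples(group=neg, timepoint=tp))
                sub = ExpressionMatrix(matrix.values[sel], meta.loc[sel])
                labels = meta.loc[sel, "group"].to_numpy()
                paired = meta.loc[sel, "subject"].to_numpy() \
                    if "M" not in (pos, neg) else None
                res = gsea.permutation_significance(
                    sub, labels, collection, config.n_perm_gsea,
                    stage_seed(config.seed, "gsea", counter),
                    mode=config.gsea_mode, classes=(pos, neg),
                    paired_subjects=paired)
                across_enrich[(comp, tp)] = res
                _write_tsv(_enrichment_tsv(res), out / f"gsea_{comp}@{tp}.tsv")
                counter += 1
        for con, (later, earlier) in WITHIN_CLASS_ORDER.items():
            for grp in GROUPS:
                sel = (matrix.select_samples(group=grp, timepoint=later)
                       + matrix.select_samples(group=grp, timepoint=earlier))
                sub = ExpressionMatrix(matrix.values[sel], meta.loc[sel])
                labels = meta.loc[sel, "timepoint"].to_numpy()
                res = gsea.permutation_significance(
                    sub, labels, collection, config.n_perm_gsea,
                    stage_seed(config.seed, "gsea", counter),
                    mode=config.gsea_mode, classes=(later, earlier),
                    paired_subjects=meta.loc[sel, "subject"].to_numpy())
                within_enrich[(con, grp)] = res
                _write_tsv(_enrichment_tsv(res), out / f"gsea_{con}@{grp}.tsv")
                counter += 1
        manifest["stages"]["gsea"] = {"cells": counter}

        # -- stage 5: dot matrix, pattern calls, modules ------------------
        stage = "patterns"
        dots = temporal_patterns.build_dot_matrix(
            across_enrich, within_enrich,
            fdr_threshold=config.fdr, star_levels=config.star_levels)
        calls = temporal_patterns.classify_all(dots)
        _write_tsv(dots.across.join(dots.within), out / "dot_matrix.tsv")
        _write_tsv(calls, out / "pattern_calls.tsv")
        enriched_members: dict[str, set] = {}
        for res in across_enrich.values():
            sig = res[(res["p_nom"] < config.npv) & (res["fdr_q"] < config.fdr)]
            for name, row in sig.iterrows():
                enriched_members.setdefault(name, set()).update(
                    row["leading_edge"])
        if enriched_members:
            modules = temporal_patterns.merge_gene_sets(
                {k: sorted(v) for k, v in sorted(enriched_members.items())},
                config.overlap)
            modules.rename_axis("set").to_frame().to_csv(
                out / "modules.tsv", sep="\t")
        manifest["stages"]["patterns"] = {
            "sets": len(calls),
            "classified": int((calls["category"] != "Unclassified").sum()),
            "enriched_sets": len(enriched_members),
        }

        # -- stage 6: pattern networks and focus hubs ---------------------
        stage = "hubs"
        hub_tables = {}
        pattern_networks = {}
        if network is not None and network.number_of_nodes():
            for cat in sorted(set(calls["category"]) - {"Unclassified"}):
                sets_in = calls.index[calls["category"] == cat]
                genes_in = sorted(set().union(
                    *(enriched_members.get(s, set()) for s in sets_in)))
                if not genes_in:
                    continue
                try:
                    net = network_hubs.build_pattern_network(
                        genes_in, network, config.expand_neighbors)
                except network_hubs.NetworkError:
                    log.info("pattern %s: no overlap with reference network", cat)
                    continue
                pattern_networks[cat] = net
                ranking = network_hubs.hub_ranking(net, config.k_hubs)
                hub_tables[cat] = ranking
                _write_tsv(ranking, out / f"hubs_{cat}.tsv")
            if len(pattern_networks) >= 2:
                merged = network_hubs.merge_networks(
                    list(pattern_networks.values()))
                _write_tsv(network_hubs.hub_ranking(merged, config.k_hubs),
                           out / "hubs_merged.tsv")
        manifest["stages"]["hubs"] = {
            "pattern_networks": len(pattern_networks),
            "ranked": sum(len(t) for t in hub_tables.values()),
        }

    except Exception as exc:
        code = type(exc).__name__
        (out / "failed").write_text(f"{stage}\t{code}\n")
        raise PipelineError(stage, code, str(exc)) from exc

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out


def _enrichment_tsv(res: pd.DataFrame) -> pd.DataFrame:
    out = res.copy()
    out["leading_edge"] = [",".join(le) for le in out["leading_edge"]]
    return out
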