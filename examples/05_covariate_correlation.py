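"""Correlate within-session expression changes with a physiological covariate.

Emulates the exhaled-nitric-oxide analysis: per-subject changes in
expression between two timepoints are ranked by correlation with the
matching covariate changes, and gene sets are tested for concordant
positive or negative correlation.
"""

import numpy as np
import pandas as pd

import rrtempo as rt
from rrtempo import gsea

config = rt.SimulationConfig(n_genes=300, n_subjects_per_group=20,
                             covariate_r=0.9,
                             covariate_pattern="ProgressiveI_Up", seed=8)
matrix, truth = rt.generate_expression(config)
collection = rt.generate_gene_sets(config, truth)
covariate = rt.generate_covariate(matrix, truth, config)

dvals, dcov = gsea.subject_deltas(matrix, group="M", tp_from="T0",
                                  tp_to="T2", covariate=covariate)
# covariate change built to track the planted pathway's delta score
score = dvals.loc[truth.genes_of("ProgressiveI_Up")].mean(axis=0)
z = (score - score.mean()) / score.std(ddof=0)
rng = np.random.default_rng(88)
dcov = pd.Series(0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(len(z)),
                 index=dvals.columns)

res = gsea.covariate_correlation_gsea(dvals, dcov, collection,
                                      n_perm=200, seed=9)
print("covariate-correlation enrichment (M, T0 -> T2):")
print(res[["size", "es", "p_nom", "fdr_q", "direction"]].round(3)
      .to_string())
# The pathway driving the covariate comes out as a significantly
# positively correlated set; decoys hover near p = 0.5.
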