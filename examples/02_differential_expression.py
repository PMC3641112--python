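"""Random-variance permutation t-test on one contrast.

Fits the inverse-gamma variance prior on the contrast's residuals,
computes moderated t statistics with permutation p-values for the
unpaired M-vs-N1 comparison right after the session (T1), and summarizes
the overlap with the M-vs-N2 comparison — the package's analogue of the
overlapping-transcript Venn analysis.
"""

import rrtempo as rt
from rrtempo.diffexp import ComparisonSpec, run_contrast, select_de, venn_counts

config = rt.SimulationConfig(n_genes=300, seed=1)
matrix, truth = rt.generate_expression(config)

results = {}
for spec in (ComparisonSpec.across("M", "N1", "T1"),
             ComparisonSpec.across("M", "N2", "T1"),
             ComparisonSpec.across("N2", "N1", "T1")):
    res = run_contrast(matrix, spec, n_perm=200, seed=7)
    genes = select_de(res, alpha=0.01)
    results[spec.label] = genes
    print(f"{spec.label}: {len(genes)} genes at permutation p < 0.01 "
          f"({'paired' if spec.paired else 'unpaired'} test)")

counts = venn_counts(results)
overlap = counts[tuple(sorted(results))]
print(f"genes shared by all three comparisons at T1: {overlap}")
# Planted Progressive/Long-term genes differ between M and N1, so the
# M-vs-N1 list is the largest and overlaps strongly with M-vs-N2.
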