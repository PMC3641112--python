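# Methods

This note documents the models, rules and numerical choices behind
`rrtempo`, what the synthetic-data generator does and does not emulate,
and the open design decisions we fixed.

## Study design and containers

The design is fixed: groups N1 (novices), N2 (the same people after
short-term training; N1 and N2 share subject identifiers) and M
(independent long-term practitioners), each sampled at T0, T1 and T2
within one session. Timepoints are treated ordinally as t ∈ {0, 1, 2};
the unequal real-time spacing is not modelled because every analysis uses
only ordinal contrasts. Expression lives in an `ExpressionMatrix`
(genes × samples DataFrame plus per-sample subject/group/timepoint
metadata); gene sets in a `GeneSetCollection`; interaction networks are
plain undirected simple `networkx.Graph` objects. File formats are GCT
1.2, categorical CLS, GMT, SIF and TSV, all parsed and written through
streams with strict validation (structural errors raise, naming the
line; writers emit files their own parsers accept). Gene identifiers
match exactly and case-sensitively; an `--uppercase-ids` flag normalizes
inputs when collections come from mixed sources. Duplicate probes for
one identifier are collapsed by keeping the probe with the largest
maximum absolute deviation from its own mean — a fixed convention chosen
because it keeps the most informative probe and is order-independent.

## Synthetic data generator

Per gene g, subject s (group G), timepoint t:

    y = b_g + u_{g,s} + sign · (δ_pat(G)·β + slope_pat(G)·γ·t) + ε,
    ε ~ N(0, σ²),  u_{g,s} ~ N(0, τ²)

with baselines b_g ~ N(7, 1) log-units. Subject intercepts are shared
across timepoints and across a subject's N1/N2 samples (same person),
which is what gives the paired tests their power; they are independent
across genes so that genes are statistically independent and ensemble
calibration checks (binomial intervals, KS uniformity) are valid.

Pattern families (sign = ±1 for the Up/Down variants):

| family        | δ(N1, N2, M) | session slope |
|---------------|--------------|----------------|
| Progressive I | 0, ½, 1      | γ in M only |
| Progressive II| 0, 1, 1      | γ in N2 **and** M |
| Long-term     | 0, 0, 1      | `longterm_slope_mult`·γ in M (default −½) |

Progressive II applies the slope in both practice groups so that M and
N2 stay indistinguishable — the defining property of the category (both
practice groups respond, without a duration gradient). A slope in M only
would manufacture M-vs-N2 differences mid-session and contradict the
category's own definition. The Long-term default slope is negative
(the M-group elevation relaxes within the session); the magnitude is a
free parameter of the config.

Defaults are a desk-scale version of the study: 8 subjects/group
(vs 26 enrolled), 500 genes (vs ~22k array transcripts), six planted
modules of 10–30 genes plus six decoy sets drawn from Null genes,
β = 1.0, γ = 0.5, τ = σ = 0.5 log-units, i.e. a standardized group
effect of β = 2σ. Planted modules occupy disjoint gene blocks (a gene
carries at most one pattern); configurations that cannot fit disjointly
are rejected.

The generator does **not** emulate probe-level artifacts, array
normalization residuals, heavy-tailed noise, gene–gene correlation
beyond the planted modules, batch structure, or missing samples. Passing
recovery tests therefore demonstrates that the pipeline's logic is
correct under its own model assumptions, not that real microarray data
would behave as cleanly.

The reference interaction network embeds one planted hub per pattern
module: the hub is the star centre of its module's genes, bridged by a
single edge into a private random connected background of Null genes.
The background is capped at 3·(spokes)−1 nodes so the spokes always
exceed a quarter of the component — removing the hub provably
disconnects at least that fraction. The covariate is
r·z + √(1−r²)·noise where z is the standardized per-sample mean
expression of one planted pathway, so its population correlation with
the pathway score is exactly `covariate_r`.

## Random-variance t-test

We parametrize the variance prior as σ² ~ Inv-Gamma(shape a, scale b),
equivalently 1/σ² ~ Gamma(a, rate b), under which s²·a/b ~ F(ν, 2a).
(a, b) are fitted by maximizing the exact marginal likelihood of the
per-gene sample variances (Nelder–Mead on (log a, log b), five spread
starting points, explicit F log-density); zero variances are excluded
from the fit but still tested (the prior keeps their t finite). A fit
needs at least 50 positive variances. If the likelihood pushes a beyond
10⁶ the prior is degenerate (common variance) and a is capped there.
Under this parametrization rescaling the data by c multiplies b by c²
and leaves a unchanged. Hyperparameters are fitted once per contrast on
that contrast's own residual variances (pooled two-sample variances with
ν = n₁+n₂−2, or per-subject difference variances with ν = n−1), which
matches the model's assumption that one prior governs the variances
being shrunk.

The moderated statistic uses σ̃² = (ν s² + 2b)/(ν + 2a) and df ν + 2a;
two-sided parametric p-values are reported alongside permutation
p-values. Permutation schemes: unpaired contrasts shuffle group labels;
paired contrasts flip the signs of per-subject differences. Because a
global sign flip leaves |t| unchanged, the exhaustive two-sided paired
null has 2^(n−1) distinct classes; enumeration replaces sampling
whenever that count (or C(n, n₁) for unpaired) fits in the permutation
budget, making small-sample p-values exact. Sampled p-values use the
add-one estimator (1 + hits)/(1 + B), so p is never zero. DE selection
is strict: permutation p < 0.01 by default.

## SOM temporal maps

Genes are summarized by their nine condition means, centred at the mean
of the nine cells (each design cell counts equally regardless of group
sizes) and scaled to max |value| = 1; constant genes map to the zero
profile, whose Pearson correlation is undefined — its distance is
defined as 1 to every prototype. The map is a rectangular grid (default
3×6 = 18 nodes) trained in batch mode: prototypes are initialized by
sampling input profiles (seeded), each epoch assigns genes to the
nearest prototype under d = 1 − r and moves prototypes to the Gaussian
neighborhood-weighted mean, with the radius decaying geometrically from
max(grid)/2 to 0.5 over the epochs. Batch training makes the result a
pure function of (profiles, shape, seed, epochs).

Node prototypes are classified by shape rules on the per-group means
(threshold ε = 0.25 on the unit-scaled profile): no M-vs-N1 separation →
Unclassified; N2 within ε/2 of N1 while M separates from both →
Long-term; N2 strictly between → Progressive (subtype I when M also
separates from N2, else II); sign of M−N1 gives Up/Down. Genes inherit
their node's label. This deterministic rule application replaces the
original workflow's manual curation of maps into categories — a
reproducibility substitution, recorded in the outputs, not a claim of
reproducing any particular manual selection.

Over-representation of a gene list against a collection uses the
one-sided Fisher exact test on the 2×2 table after intersecting each set
with the background; sets with zero overlap report p = 1, and p < 0.05
(strict) flags significance.

## Gene-set enrichment

Two-class ranking uses the signal-to-noise metric (m₁−m₂)/(s₁+s₂) with
each class SD floored at max(0.2·|class mean|, 0.2·g, 10⁻⁸) where g is
the median pooled per-gene SD — the global floor keeps the metric finite
and zero-valued for degenerate genes. Continuous ranking uses the
Pearson correlation with the covariate (constant genes score 0; a
constant covariate is an error). Ties in the ranking are broken by
identifier so results are reproducible. The weighting exponent is p = 1,
the canonical choice for the weighted running-sum statistic.

Permutation modes: *phenotype* (shuffle class labels among the two
classes; swap timepoint labels within subject for paired time contrasts;
permute the covariate in continuous mode) when every class has ≥7
samples, else *gene_set* (random same-size sets against the observed
ranking) with a logged notice; `mode=auto` applies that rule. NES
divides ES by the mean same-sign permuted ES; nominal p is the same-sign
tail proportion with the add-one correction; FDR q pools the
per-set-normalized permuted NES across sets and takes the ratio of tail
proportions (pooled vs observed), clipped to [0, 1]. The leading edge is
the set members at or before the running-sum extremum (at or after, for
negative ES). Whether the original analyses permuted phenotypes or gene
sets is not stated anywhere authoritative; the ≥7-samples auto rule is
this package's defined behavior.

The covariate-correlation mode forms per-subject expression and
covariate changes between two named timepoints within one group
(subjects missing either end are dropped; fewer than three complete
subjects is an error) and runs continuous-mode enrichment on the deltas,
reporting negative-ES sets as negatively correlated pathways.

## Dot matrix, pattern calls, modules

Across-group cells get a directed dot when FDR q < 0.25 (strict);
within-group cells get 1/2/3 stars for nominal p < 0.09/0.05/0.01 with
the ES sign as direction; untested cells are recorded as such. The
0.09 first star tier is intentionally honored verbatim. Pattern calls
use only the across-group dots, in fixed rule order: (1) Long-term —
M-vs-N1 and M-vs-N2 dots at ≥2 timepoints each and no N1-vs-N2 dot;
(2) Progressive I — all three comparisons dotted at ≥1 timepoint;
(3) Progressive II — N1-vs-N2 and N1-vs-M dotted, no M-vs-N2 dot at T0
or T1; (4) otherwise Unclassified. Long-term precedes Progressive so
sets without any N1-vs-N2 signal are never called Progressive. Rows
mixing up- and down-dots are Unclassified rather than majority-voted:
the pattern categories are unidirectional by construction. "Greater
enrichment in M" is operationalized as a significant M-vs-N2 dot — a
quantity the matrix already contains — rather than a new magnitude test.

Modules merge enriched sets (nominal p < 0.05 and FDR < 0.25 in at least
one across cell) on their leading-edge gene unions when the overlap
coefficient |A∩B|/min(|A|,|B|) ≥ 0.70; the coefficient (not Jaccard) is
used because a "70% common genes" notion is asymmetric-friendly. Modules
are connected components, labelled by the largest member set (ties by
name); the output is always a partition of the input sets.

## Bottleneck hubs

Networks are unweighted and undirected (directed interaction semantics
are flattened to edge presence). For each root, the BFS shortest-path
tree is made unique by the smallest-identifier parent rule; a non-root
node is a bottleneck when its subtree (itself included) holds strictly
more than a quarter of the component. BN(v) counts the rooted trees in
which v is a bottleneck; ranks 1..k are assigned by descending BN with
identifier tie-break. The deterministic parent rule exists because the
bottleneck count otherwise depends on an arbitrary tree choice; the test
oracles use the identical rule. Pattern networks are induced subgraphs
of the reference network on a pattern's enriched genes; the optional
neighbor expansion adds reference nodes adjacent to ≥2 input genes and
is off by default because the right expansion policy is genuinely
unclear — it is a flag, not a guess.

## Pipeline

`run_pipeline` executes simulate (or load) → differential expression
(all 9 across + 9 within contrasts) → SOM → the 18-cell enrichment grid
→ dot matrix/calls/modules → pattern networks and hubs, reading and
writing files at every boundary so any stage can be re-run from the
manifest. One global seed expands into per-stage, per-contrast seeds via
a fixed counter scheme (stage offsets of 1000), so adding a stage never
perturbs earlier stages' randomness. Thresholds default to the published
criteria (DE α = 0.01, enrichment NPV 0.05 / FDR 0.25, stars
0.09/0.05/0.01, overlap 0.70, top-20 hubs) and permutation defaults to
1000 (DE) / 500 (enrichment); every override is stamped into the
manifest next to the config hash. TSVs are written with a fixed float
format, so identical configs produce byte-identical outputs.

## Problem sizes

Tests and the reproduction script run the generator at 150–2000 genes
and 4–20 subjects per group with 40–200 permutations. The bundled
end-to-end fixture uses 500 genes, 8 subjects/group, six planted plus
six decoy sets, 200 DE / 100 enrichment permutations; calibration checks
use 2000 genes under the null; pattern-recovery checks use 20
subjects/group with 100 permutations over 5 seeds; bottleneck oracles
enumerate all rooted trees on graphs of ≤12 nodes. These sizes were
chosen to make every statistical property measurable with tight Monte
Carlo error while keeping any single check to seconds.

## Known limitations

* The generator's planted shapes are step/linear idealizations of the
  category definitions; real temporal responses are unlikely to be
  piecewise linear in ordinal time.
* FDR q from pooled permuted NES is noisy at ≤100 permutations and a
  dozen sets; dot-matrix cells near q = 0.25 flicker across seeds at the
  bundled fixture's size (visible as occasional Progressive I/II
  confusions at 8 subjects/group; at 20/group recovery exceeds 90%).
* The SOM category labels depend on the ε = 0.25 shape threshold; very
  weak planted effects (β < ε after scaling) drift into Unclassified by
  design.
* Fisher over-representation treats sets as flat gene lists; no
  ontology-graph propagation is performed.
* The bottleneck score follows the rooted-tree definition with the n/4
  subtree threshold; other hub centralities (degree, closeness, MCC) are
  out of scope.
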