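# Methods

## Scope and model

`crossdx` implements a cross-disease transcriptomics meta-analysis as a
library of six stages: per-cohort differential expression, within- and
cross-disease intersection, fold-change association, PPI hub ranking,
gene-set enrichment / methylation summaries, and docking-score drug
prioritization with rule-based screening. Everything operates on plain-text
interchange formats (TSV expression matrices and sample sheets, TSV/SIF
edge lists, GMT gene sets, CSV affinity matrices), and every stage can be
exercised on synthetic data with planted ground truth.

## Differential expression

Expression is modelled on the log2 scale. Intensities must be strictly
positive; values ≤ 0 raise an error rather than receiving a silent
pseudocount (an explicit `pseudocount` option exists at the I/O layer),
because silently patched zeros corrupt fold changes. The average log2 fold
change has two algebraically equivalent branches (difference of group means
of logs; index-paired mean log-ratio when group sizes are equal); both are
implemented and their equality is a test invariant.

The moderated t-statistic shrinks the pooled per-gene variance `s_g^2`
(equal group variances assumed, `d_g = n1 + n2 − 2` df) toward a prior
`s0^2` with `d0` prior df. The hierarchical model is
`s_g^2 | σ_g^2 ~ σ_g^2 χ²_{d_g}/d_g` with `σ_g^2 ~ d0·s0²/χ²_{d0}`
(scaled inverse chi-square). `(d0, s0²)` are estimated by moment matching
on `log s_g^2`: with `e_g = log s_g² − ψ(d_g/2) + log(d_g/2)`,
`Var(e) − ψ'(d_g/2) = ψ'(d0/2)` is solved with a Newton trigamma-inverse
(tolerance 1e−8, ≤ 50 iterations), and `s0²` follows from the mean of `e`.
Excess dispersion ≤ 0 gives `d0 = ∞` (posterior variance pinned at `s0²`,
normal reference distribution) with a logged warning; a single-gene input
falls back to `d0 = 0` (classical t). The implementation agrees with
Bioconductor limma's `lmFit`/`eBayes` to ~1e−8 relative on shared inputs;
limma serves only as an independent oracle in the test suite.

Multiple-testing adjustment is Benjamini–Hochberg by default (selectable:
`bh | bonferroni | none`), delegated to statsmodels. The DEG rule is
`adjusted p < p_cut` **and** `aLog2FC > fc_cut` (up) or `< −fc_cut` (down),
defaults 0.05 and 1.0, strict inequalities. DEG calling uses each cohort's
own fold change; cross-cohort aggregation happens later — an aggregated
fold change near zero can therefore coexist with per-cohort DEG calls only
when directions conflict, which the strict intersection rejects anyway.

## Intersection, aggregation, association

Within a disease, `strict` mode (default) keeps a gene iff it is a DEG
with the same direction in every cohort; `majority` requires more than half
of the cohorts. Strict output is a subset of majority output. Genes absent
from some cohorts are tolerated — they must be DEGs wherever measured —
because real multi-platform designs never share full gene coverage.
Cross-disease sharing requires presence in both diseases' common-DEG sets
and, by default, concordant direction; discordant genes can be retained
with an explicit flag. Per-disease fold changes are aggregated as the
unweighted mean of per-cohort aLog2FC over cohorts measuring the gene (the
simplest estimator consistent with "average fold change"; no random-effects
weighting). The association is the plain Pearson correlation over
gene-matched aggregated fold changes, with a two-sided label-permutation
p-value using the add-one estimator `(1 + #{|r_perm| ≥ |r_obs|})/(n_perm+1)`
to avoid zero p-values.

## Network centrality

Graphs are undirected, simple, unweighted; edge confidence scores are
ignored. Conventions (all well defined on disconnected graphs):

- betweenness and stress sum over unordered pairs `s < t`, both ≠ v,
  unnormalized (betweenness via networkx; stress from all-pairs BFS
  distance/count matrices);
- closeness is the harmonic variant Σ 1/d (unreachable contributes 0),
  as hub-selection tools use on sparse PPI graphs;
- radiality is computed per component, Σ (Δ_C + 1 − d(v,w))/(n_C − 1) with
  Δ_C the component diameter; isolated nodes score 0;
- MNC is the size of the largest connected component of the subgraph
  induced by the node's neighbors;
- BottleNeck builds one shortest-path tree per root; the tree is not unique,
  so it is made deterministic by BFS with the lexicographically smallest
  parent; a non-root node scores a point per tree in which its subtree
  (itself included) holds strictly more than a quarter of the component.

All seven measures are verified against a brute-force oracle that
enumerates every shortest path on 200 random graphs of ≤ 8 nodes.

Hub aggregation is mean-of-ranks over the seven measures by default (ties
share average ranks), with `topk_count` (membership count in per-measure
top-k lists) as the logged alternative; how seven top-lists become one
top-10 is genuinely underdetermined in this kind of analysis, so both are
provided. All orderings are made total by breaking ties with higher degree,
then lexicographic node id. The printed neighbor-overlap formula is a Dice
similarity (1 for identical neighborhoods), so it is exposed as
`neighborhood_similarity`, with `1 − similarity` available as the distance.

## Enrichment and methylation

Over-representation uses the one-sided upper hypergeometric tail
P(X ≥ k) — enrichment semantics, not the two-sided Fisher test. The
universe defaults to the union of the collection's sets; a user-supplied
background is accepted, since annotation-database size is what actually
fixes N. Query genes outside the universe are dropped with a logged count.
β-values are exactly M/(M+U+100), bounded below 1 by the +100 stabilizer;
no hypo/hyper threshold is hard-coded — group mean comparison with a
configurable margin is provided instead, because no universal margin
exists.

## Drug prioritization and screening

Ligand and receptor orderings use means over available (non-missing)
entries, most negative (strongest) first; missing cells are never imputed,
and ligands under a coverage floor (default 80% of receptors) are excluded
and reported. Candidate selection takes ligands with mean BAS < −7.7
kcal/mol and reports, per candidate, receptors with individual scores
≥ −7.0 kcal/mol (weak bindings that the average hides). Rule-of-five
screening uses the canonical bounds (MW ≤ 500 Da, LogP ≤ 5, HBD ≤ 5,
HBA ≤ 10). ADMET values are consumed as inputs, never predicted; the
implemented verdicts are HIA ≥ 30% = high absorption (the threshold is
configurable, as a 50% convention also circulates) and the LogBB tri-level
(≥ 0.3 permeant, < −1 poor, otherwise intermediate). Under these printed
bounds a LogBB of −0.71 is *intermediate*, not poor, and the classifier
says so.

## Synthetic data

The generator emulates the eight-cohort two-disease microarray design:
four cohorts per disease with default group sizes (6,7), (12,12), (12,12),
(12,12) and (14,14), (27,27), (12,12), (13,13). Log2 intensities are
baseline `N(7, 1.5²)` per gene plus the disease effect for case samples
plus `N(0, σ_g²)` noise, exponentiated to guarantee positivity; the noise
model is log-normal by choice (microarray noise models vary; this one makes
every downstream log2 defined). Per-gene variances follow the scaled
inverse chi-square prior (defaults d0 = 4, s0² = 0.05, typical of
small-sample microarray moderation). Planted classes: shared-up /
shared-down genes get bivariate-normal effect pairs with means ±1.5 log2,
spread `effect_sd = 0.25` and cross-disease correlation ρ = 0.8;
disease-specific genes get the same marginal effect distribution in one
disease only (exercising the intersection's rejection path); null genes
have zero effect. `effect_sd = 0.25` (≈17% CV) was chosen once as a
realistic between-gene heterogeneity: small enough that nearly all planted
genes clear the |FC| > 1 rule in every cohort, large enough that the
planted effect correlation is a meaningful target.

What the generator does **not** emulate: probe-level structure,
normalization artifacts, batch effects, cross-platform coverage gaps, and
correlated genes. Passing recovery tests therefore shows the pipeline's
statistics behave as designed under the assumed model — not that the
defaults are robust to real-world array artifacts.

One caveat the validation studies surface explicitly: the *observed*
fold-change correlation over recovered shared genes is attenuated below the
planted ρ — estimation noise multiplies r by s²/(s² + E[σ²]/24) and
conditioning on recovery truncates the effect distribution — so with these
study conditions the replicate mean is ≈ 0.71 against a planted 0.8. The
attenuation is a property of the estimand, not an implementation defect;
no parameter choice removes it without sacrificing recovery sensitivity.
Pooled over up- and down-regulated genes together the correlation is
instead dominated by the ±effect separation (r ≈ 0.99); within-class
plantings are used whenever ρ itself is the target.

## Determinism and numerics

Every generator and every stochastic procedure takes an explicit seed;
per-dataset substreams derive from one `SeedSequence`, so identical
(config, seed) gives byte-identical outputs. Tie-breaks (hub ordering,
regulator ranking) are total and documented. Validation studies use 100
replicates at 2000 genes — sizes at which the moment estimator's recovery
tolerances (d0 within ±50%, s0² within ±25%) hold comfortably and a full
study runs in seconds.

## Known limitations

No multi-factor or paired designs, covariates, or normalization; no
meta-analytic effect-size models (random effects, Stouffer); no network
inference or edge-confidence thresholding; no GO/KEGG database access or
gene-ID mapping; no survival analysis of CpG sites; no docking or ADMET
prediction — printed decision rules only.
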