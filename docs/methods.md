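# Methods

This note documents the models and procedures implemented in `herbnet`, the
choices made where the method description left the design open, and what the
synthetic data do and do not establish.

## Data model

A prescription (one patient visit's formula) is a *set* of herb IDs with a
cohort label (`case` / `control`). Duplicate herb mentions within one
prescription collapse to one: every downstream statistic — supports,
co-occurrence weights, relative-risk numerators — is presence-based, so set
semantics are the only consistent reading. Herb-use counts are therefore
"number of prescriptions containing the herb", and the total use count N is
the number of (prescription, herb) pairs.

## Co-prescription network and shell extraction

The herb network weights each unordered pair by its joint prescription
frequency. Shell extraction sorts edges by weight (ties broken
lexicographically on the sorted pair, for cross-platform determinism) and
retains the largest prefix k satisfying

    S_k * N >= k**alpha * S_N

with N the herb count of the originating data, S_N the current total pair
weight and S_k the cumulative weight of the top-k pairs. Layers are peeled
iteratively from the residual; N is held fixed across iterations (it is
defined on the data, not the residual graph) while S_N shrinks with each
peel. When no k satisfies the criterion, the single heaviest edge is peeled
and flagged, so the iteration always terminates and, run to exhaustion, the
layers partition the edge set.

The criterion's arithmetic has a regime consequence worth knowing: with
alpha = 2.4 the k-th pair can only be retained if the top-k pairs hold a
k^2.4/N share of all pair weight. In dense prescribing (tens of herbs per
prescription over hundreds of herbs) weight is spread over thousands of
pairs, no k qualifies, and layer 1 degenerates to the flagged single-edge
fallback. Layer-1 recovery of a planted core is therefore demonstrated in a
sparse regime (≈5 herbs per prescription, near-flat background popularity,
3 core herbs at inclusion 0.8), where the criterion concentrates on the core
block; the planted-core acceptance check and `scripts/acceptance.py` use
exactly these conditions.

## Specificity screen

Relative risk contrasts an herb's share of herb uses in case versus control
prescriptions: RR = (n_ij/n_i) / ((n_j−n_ij)/(N−n_i)). An herb used in cases
but absent from controls gets RR = +inf with a warning rather than an
arbitrary cap. Screening uses the Pearson chi-square on the 2×2 table
(df = 1) without continuity correction — counts at cohort scale are large —
with Yates' correction available as an option. The screen is intentionally
uncorrected for multiple testing (raw p < 0.05), matching common practice
for this step; Benjamini–Hochberg screening is available behind a flag.
Herbs whose table has a zero margin are excluded with a warning.

## Association rules

Apriori is implemented level-wise with prefix-join candidate generation and
downward-closure pruning; it is exact (verified against exhaustive subset
enumeration). Rule metrics: support = count/n, coverage = support(LHS),
confidence = support/coverage, lift = confidence/support(RHS). Thresholds
are strict inequalities (support > 0.2, confidence > 0.5) by default, with
`strict=False` switching to inclusive. Consequents are single items by
default (`max_rhs`), and output is ordered by lift, then support, then
itemset labels. Rule grouping embeds each rule as a 0/1 vector over the
union of its LHS∪RHS items and runs seeded k-means; mirrored rules share a
vector and always co-cluster.

## Molecular network, MCODE and the random walk

The heterogeneous graph unions the confidence-filtered protein interaction
edges (confidence as weight) with compound→target edges of weight 1;
disease genes missing from the graph are kept as isolated, flagged nodes so
they can still seed the walk.

MCODE follows the published three-stage procedure: vertex weight = highest
k-core number of the closed neighbourhood × that k-core's density; greedy
expansion from the heaviest unused seed admitting unvisited neighbours with
weight > (1 − node_score_cutoff)·seed weight (defaults: degree cutoff 2,
cutoff 0.2, haircut on, fluff off); complexes lacking a 2-core are dropped
and haircut trims each complex to its 2-core. Note that under uniform vertex
weights the greedy expansion legitimately crosses bridges — two equal
cliques joined by an edge form one complex, not two.

The random walk with restart iterates p ← (1−c)·W·p + c·s to a 1e-9 L1
tolerance, W column-normalized (symmetric normalization available), s
uniform over the seeds, c = 0.75. Isolated nodes receive a self-loop in W so
the score vector remains a probability distribution; scores match the closed
form c(I−(1−c)W)⁻¹s to 1e-8 on every fixture tested. Compound retention
takes the linearly interpolated (type-7) upper quartile of compound scores
and keeps compounds *strictly* above it; with all-equal scores nothing
qualifies (warned), and with fewer than four compounds the quartile is
meaningless so all are retained (warned).

## Enrichment and core pathways

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k) with the collection's universe (all annotated genes) as M;
terms with zero overlap are excluded before Benjamini–Hochberg correction so
q-values are comparable across queries. Significance is q < 0.05; the
screen's "Q" and "adjusted P" are treated as the same BH quantity. Being
discrete, the test is slightly conservative: random queries reach p < 0.05
for ≈3.5–4.5% of terms rather than exactly 5% (measured in the calibration
tests with set sizes 30–150 against a 2000-gene universe).

The core-pathway rule takes the disease-significant terms as candidates and,
per herb, keeps those whose enriched-gene count strictly exceeds the herb's
own upper quartile over the candidates. With a single candidate term, or
with all counts tied, the strict inequality leaves the core set empty — the
rule needs several candidate pathways to be informative.

## Profiles and Ward clustering

Symptom and target profiles are binary incidence matrices; pathway-level
profiles use enriched-gene *counts* over the core terms, since grouping "by
the number of enriched genes" is the count reading. Distances are Euclidean
(for binary rows, squared distance equals the Hamming distance). Ward
clustering merges, at each step, the pair of clusters minimising the
increase in total ESS = Σx² − (Σx)²/n (per coordinate, summed), computed via
the exact closed form n_A n_B/(n_A+n_B)·‖c_A−c_B‖²; merge costs are
non-negative, so cumulative heights never decrease. Ties are broken on the
lexicographically smallest pair of cluster labels (a label is the sorted
tuple of member names), making the tree deterministic and row-order
invariant. This is the direct ESS formulation rather than the Lance–Williams
"ward.D2" recurrence; the implementation matches an exhaustive
ESS-recomputation oracle exactly on small instances. Cut counts per level
are configuration (defaults 4 symptom / 3 target / 4 GO / 4 KEGG), never
inferred from the data.

## Synthetic data: what it emulates and what it does not

`CohortSpec` defaults mirror the reference cohort's summary statistics:
prescriptions of 23.84 ± 3.88 herbs (truncated normal, rounded) over a
425-herb universe, with a 9-herb core block (inclusion probability 0.8),
5 specific herbs implementing a prescription-level relative risk
(p_case = rr_target × p_bg, defaults rr 3 and p_bg 0.05), and Zipf-weighted
background sampling without replacement (Gumbel-top-k), exponent 1 by
default. `MolecularSpec` provides an Erdős–Rényi (or preferential-
attachment) PPI with Uniform(0.4, 1) confidences, Poisson-sized
compound→target maps, disease genes with a configurable overlap into the
herb-target pool, and gene sets with one planted term whose disease-gene
density is a chosen fold (deterministically rounded count; fold 1 draws the
term uniformly, giving an exact null).

The generators capture the *statistical* structure the pipeline assumes —
heavy-tailed herb popularity, a dense core block, a cohort contrast at fixed
RR, one enriched term — but not longitudinal structure, dosages, herb–herb
correlations beyond the core block, PPI modularity, or realistic pathway
overlap. Passing the recovery tests therefore shows the algorithms detect
what they are defined to detect at the stated effect sizes and sample sizes
(e.g. RR 3 at base prevalence 0.05 with 1000 + 1000 prescriptions); it does
not certify performance on real records, where confounding and correlated
prescribing can dominate.

Null calibration of the planted-term generator is tested through the
randomized probability integral transform (u = F(k−1) + U·f(k)), which is
exactly uniform for a discrete statistic; a raw Kolmogorov–Smirnov test of
the discrete p-values against U(0,1) would reject even for a perfectly
calibrated test.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed yields byte-identical output files, and the pipeline manifest records
  the config hash (SHA-256 of the canonical JSON), seed and input checksums.
* Interaction scores are auto-detected as 0–1 or 0–1000 (any score > 1
  switches the file to the 0–1000 reading) so raw and normalized exports
  both load.
* RWR tolerance 1e-9 (L1), max 10,000 iterations, convergence flagged;
  quantiles are NumPy type-7 throughout.
* Problem sizes in the test-suite and acceptance-script simulations (50–100
  replicates; 1000 + 1000 prescriptions for the cohort contrast; 500
  prescriptions for core recovery; 1000-protein universe for enrichment)
  were chosen as the smallest sizes at which the planted effects are
  comfortably identifiable, keeping the default runs fast.

## Known limitations

* The shell criterion is unproductive (single-edge fallback) in dense
  prescribing regimes, as described above; alternative criterion readings
  are deliberately not guessed at, and the fallback is always flagged.
* The specificity screen's chi-square treats herb uses as independent
  counts; within-prescription competition induces slight conservatism
  (measured type-I ≈ 0.03–0.04 at nominal 0.05 in the synthetic null).
* RWR scores depend on the normalization convention; column normalization is
  the default and symmetric normalization is provided, but no claim is made
  that either reproduces scores computed on other, unpublished networks.
* MCODE parameters are the plug-in's published defaults; no parameter search
  is performed.
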