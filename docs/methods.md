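# Methods

## Screening model

A compound is retained when it simultaneously satisfies OB ≥ ob_min
(percent oral bioavailability, default 15), BBB ≥ bbb_min (blood–brain
barrier penetration score, default −0.3) and DL ≥ dl_min (Tanimoto-based
drug-likeness, default 0.1). All bounds are inclusive. The package does
not predict any of these properties from structure; it consumes the
precomputed values the upstream phytochemical databases publish.

BBB categories use a closed middle interval: scores of exactly −0.3 or
+0.3 are "moderate" penetration, while the filter condition BBB ≥ −0.3
is applied independently of the category, so a score of −0.3 is both
moderate-penetrating and retained.

Whitelisted compounds bypass all three thresholds at once. This mirrors
how screening studies re-admit constituents with strong experimental
literature despite poor computed drug-likeness; the re-admission is
recorded per compound in the audit and in the output table's
`whitelisted` flag. Whitelist ids absent from the input warn rather than
error, since whitelists are curated independently of any one table.

## Networks

Compound–target networks are strictly bipartite with no isolated nodes:
a compound enters the node set only through at least one retained edge,
so degree sums on both sides always equal the edge count. Disease
restriction keeps target nodes in the disease set, drops orphaned
edges, and then prunes compounds left edgeless; the operation is
idempotent.

Summary means are reported at the precision this literature prints:
edges/compound half-up to 2 decimals, targets/compound half-up to
1 decimal (e.g. 509/32 = 15.90625 → 15.91; 181/32 = 5.65625 → 5.7).
Round-half-up rather than banker's rounding is deliberate — it is what
reproduces the printed values. Edges/target is reported the same way;
no other per-target average is defined. Degree-table ties break
lexicographically by node id so hub rankings are deterministic.

## Tissue localization

Two rules coexist because both appear in practice: above-mean
membership (a gene locates in every tissue strictly above its own
arithmetic mean — a constant gene locates nowhere) for location
networks, and argmax positioning (single highest-expression tissue,
first-tissue-wins on ties, tie logged) for unique assignment. The rule
is a user-facing switch; above-mean is the default. Both rules are
invariant to positive rescaling of a gene's row, and for a non-constant
gene the argmax tissue is always a member of the above-mean set.
Multiple probe rows per gene are collapsed by arithmetic mean before
either rule is applied. Genes absent from the matrix are reported as
unprofiled, never imputed.

## Over-representation statistic

The raw P value is the hypergeometric upper tail P(X ≥ m) for
X ~ Hypergeometric(N, M, n). Terms are evaluated in log space through
lgamma-based log-binomials and accumulated with compensated summation
(`math.fsum`); direct factorials are never formed. When m exceeds the
distribution mean nM/N the (small) upper tail is summed directly
instead of complementing the lower CDF, which preserves full relative
precision on the tiny P values that drive significance calls; below the
mean the complement form is used. The result is clamped to [0, 1] and
m = 0 returns exactly 1. Exhaustive comparison against exact rational
enumeration over all valid (N ≤ 25, M, n, m) bounds the absolute error
near 1e-14 (see `scripts/acceptance.py`).

Multiplicity is controlled by Benjamini–Hochberg step-up (the procedure
behind both "FDR" and "Benjamini" columns of the common annotation
servers), delegated to `statsmodels.stats.multitest`. Sets with zero
query overlap are excluded from the output but included in the BH
family size — the convention of DAVID-style tools — so hiding empty
sets never makes the survivors look better. Significance requires
p_raw < 0.01 strictly and p_adj ≤ 0.05 inclusively; one convention is
used for every collection rather than per-ontology variants. The
background is an explicit background set when supplied, else the union
of all annotated genes; query genes outside the background are dropped
with a logged count, and an empty effective query is an error. Fold
enrichment (m/n)/(M/N) is reported as a standard companion statistic.

## Synthetic benchmark generator

The generator emulates the shape of a single-herb screening study:
105 candidate compounds of which 30 are engineered to pass the default
thresholds, 181 target proteins hit 5.7 times per active compound on
average, a disease set covering 97/181 targets, 84 organ tissues, and
property ranges spanning the printed reference table (OB 16.73–81.61,
BBB −0.16–2.17, DL 0.04–0.78). Within those ranges only the DL axis can
dip below its threshold, so generated failures fail on drug-likeness —
exactly the failure mode of the reference table. Violating values stay
one printed digit (0.01) clear of each cutoff so rounding to two
decimals cannot flip a record across a threshold.

Interaction degrees are drawn from a discrete power law truncated to
[1, n_targets] (exponent 2.0 by default — hub-dominated networks with a
top degree far above the mean need strong skew), then rescaled and
repaired one unit at a time so the realized edge total equals
round(mean_degree × active compounds) exactly; every target symbol is
guaranteed at least one edge by degree-preserving swaps. A configurable
fraction of compounds receives no rows at all, emulating compounds with
no target information.

Expression baselines are log-normal with meanlog 3.0 and a deliberately
tight sdlog of 0.25; each profiled gene has one planted tissue whose
value is multiplied by an elevation factor (default 5, values ≤ 2
rejected). The tight baseline makes the elevated tissue the argmax for
≥ 99 % of genes, which is the planted-recovery contract the benchmark
tests against; real microarray atlases are far more dispersed, so
passing recovery tests here demonstrates correctness of the rules, not
expected accuracy on real tissue panels. A fraction of genes (default
6/181) is omitted from the matrix to exercise unprofiled-gene
reporting.

Annotation collections draw sets uniformly from a supplied background
(≥ 50 genes required); planted sets contribute a fixed overlap to the
emitted query, the remainder of which is uniform background. All
generators are pure functions of the single mandatory seed, each
drawing from its own derived stream, so any dataset can be regenerated
independently and emitted ground truth always re-validates against the
emitted files.

What the generator does **not** emulate: chemical structure or
property correlations, correlated expression across tissues or genes,
overlapping/nested pathway structure, and annotation bias. Green tests
therefore certify the algorithms and their bookkeeping, not biological
performance on live database extracts.

## Pipeline

One YAML config runs screen → network → disease restriction → tissue
location → enrichment; the optional stages (disease set, expression
matrix, annotation GMT) skip with a logged notice when their input is
absent. Every stage failure aborts with a stage-named error, keeping
the outputs already written. The run summary records the attrition
count at every step (inputs, passed, whitelisted, targetless-removed,
nodes/edges, profiled/unprofiled, tested/significant) because those
counts are precisely what a screening study reports. Reruns on
identical inputs are byte-identical apart from the two timestamps in
`summary.json`.

## Problem sizes in tests

The packaged test and acceptance runs use the study-scale defaults
(105/32 compounds, 181 targets, 84 tissues, 20 annotation sets over a
500-gene background), 1000 null replicates for type-I calibration, 20
seeds for planted-enrichment recovery and 5 × 175 genes for
planted-tissue recovery; all complete in seconds.

## Known limitations

- Target symbols are normalized only by trimming and upper-casing; no
  alias resolution against a gene-symbol authority is attempted.
- The screen treats the three thresholds as independent axes; no
  interaction or weighting between them is modelled.
- Only degree centrality is computed; betweenness/closeness are out of
  scope.
- ORA assumes a well-defined flat background; GO-DAG-aware methods and
  EASE-style modified scores are deliberately not implemented.
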