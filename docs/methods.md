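# Methods

This note records the models, numerical choices and deliberate design
decisions behind oakniche, and what the synthetic data generators do and do
not emulate.

## Dated trees

A `DatedTree` stores parent links, edge lengths (Ma) and node ages (Ma
before present). Ages are derived at construction: the root age equals the
longest root-to-tip path, so ultrametric chronograms place every extant tip
at age 0 and grafted fossil tips sit at positive ages. After age derivation,
edge lengths are canonicalized to exact age differences. This makes tree
surgery exactly invertible in floating point — splitting a branch at a
fossil's age and later merging it back restores the identical edge length —
at the cost of up to one ulp of drift from the textual input lengths
(round-trips are guaranteed to 1e-9, which the tests assert). Polytomies
are accepted everywhere; clade anchors must be monophyletic sets of tip
labels, and duplicate tip labels are a hard error. Newick/NEXUS parsing and
writing go through dendropy.

## Köppen profiling and the five-category cascade

Cells are half-open rectangles `[west, east) × [south, north)`; a record on
the global east/north edge joins the last cell so snapping is total and
deterministic. "Grid-weighted" means unique-cell counting: a cell with 500
herbarium records counts exactly once, which removes collecting-intensity
bias. All threshold comparisons are inclusive (`≥ 0.10` both for
representative types and for the cascade's summer-dry fraction), and both
thresholds are exposed in `NicheRules`.

The cascade itself is an operationalization of verbal category
descriptions, evaluated strictly in order with category 4 as the residual:

0. biome set within {TSMBF, TBMF} with TSMBF present, summer-dry fraction
   (total weight on Cs\*/Ds\* classes) below threshold, dominant class in
   {Cfa, Cwa};
1. TSMBF and TBMF both present, summer-dry below threshold;
2. biomes within {TBMF, TCF, TSMBF}, summer-dry below threshold;
3. summer-dry at/above threshold, at least one of {TBMF, TGSS, TCF}
   present, and (dominant class ≠ Csa **or** winter-cold summer-dry classes
   Ds\*/BSk at/above threshold);
4. otherwise.

The disjunction in rule 3 is the only reading under which a Csa-dominant
species that extends into snowy summer-dry climates (the Hyrcanian relict
case) lands in Meridional while a purely Mediterranean Csa specialist falls
through to category 4. Classification is stable under perturbations of the
fractions smaller than 1e-9 away from the thresholds (asserted by test).

The packaged per-species "signature" configurations follow each species'
listed climate classes and biomes. One species is deliberately coded against
its listed dominant class: the sub-Mediterranean member of the western pair
is kept below the summer-dry threshold (Cfb-dominant) because its summary
category (Nemoral) is incompatible with a Csa-dominated profile under any
ordering of the cascade; its minor Cs classes remain in the signature below
the representativeness threshold. Two East Asian species with TSMBF
membership and a Cfa-dominant profile fall into category 0 under the cascade
even though the field summary treats only one East Asian endemic as truly
Moist-Subtropical; these two are logged, not asserted, and their scored
niche states in the preset character follow the field summary (category 1).

## Mk1 likelihood and ancestral states

The equal-rates k-state model has the closed-form transition matrix
`P(t) = 1/k · J + exp(−kqt)(I − J/k)`; `mk_transition` implements it
directly and the tests pin it to the numerical matrix exponential at 1e-10.
Pruning rescales partials by their per-character maximum at every internal
node, accumulating log factors, so 70+-tip grafted trees at small rates do
not underflow. Missing tip states (including trait characters unscorable on
fossils) contribute all-ones partials.

Marginal reconstruction uses the standard up–down decomposition: downward
messages carry the root prior (uniform 1/k, the Mk stationary distribution,
matching the usual Mk1 default; configurable) and each node's marginal is
the normalized product of its upward partial and downward message. A
"conditional" mode that renormalizes the upward partials alone is provided
because pie-chart "proportional likelihoods" in legacy software are
ambiguous between the two; marginal is the default.

The single rate is estimated by bounded Brent search on log10(q) over
[1e-8, 100] (relative tolerance 1e-8). The log parameterization matters:
the likelihood surface flattens into a saturation plateau at large q, and a
linear search wastes most of its bracket there. Hits within a millidecade
of either bound are flagged `q_at_boundary`: invariant characters drive the
estimate to the lower bound, and extremely homoplastic single characters
can have *no* finite optimum because the saturation likelihood `(1/k)^n`
dominates — the estimate then runs to the upper bound and every marginal is
uniform. This is a real property of single-character ML, not a failure
mode; the demo preset's extant-only niche character is exactly such a case
(the "ambiguous" extant-only reconstruction), while the fossil-informed
tree, whose fossil states are temporally coherent, has an interior optimum
(q ≈ 0.03/Ma) and decisive marginals.

When one character is reconstructed on two trees (`asr_two_trees`), the
rate is estimated separately on each tree unless a fixed `q` is supplied.
Node tables are matched across trees by the fingerprint of descendant
*extant* tips; shadow MRCAs inherit their child's extant fingerprint, so
the lowest (smallest-clade) grafted node is taken as the counterpart and
shadow rows additionally appear only in the grafted table.

## Fossil grafting

Grafting breaks the anchor clade's stem at `oldest_age` and hangs the tip
with pendant length `oldest − youngest`. The oldest age must fall strictly
inside the stem's open age interval; violations are an error naming the
interval rather than a silent re-anchor, because a fossil incompatible with
its branch signals bad input. Multiple fossils on one branch nest
oldest-first into a pectinate backbone — the only supported policy, applied
identically whatever the input order (ties in age break by label). Grafting
above the root creates a new root at the fossil's oldest age. De-grafting
(prune tips, suppress degree-2 shadow nodes) is the exact inverse, bit-level,
thanks to the age-difference canonicalization of edge lengths.

## D-statistics

Site patterns are polarized strictly by the outgroup: only sites where O
carries the ancestral state are informative, and sites with missing entries
are dropped and counted. The bootstrap resamples whole loci with
replacement (the locus, not the site, is the unit of linkage in
reduced-representation data); `Z = |D|/sd(D_boot)` and the significance
convention is `|Z| ≥ 3`, both configurable. Degenerate data with zero
bootstrap spread are flagged rather than given an arbitrary Z. A frequency
mode (products of derived-allele frequencies) exists alongside the default
single-haplotype count mode.

## Neighbour-net and Hamming distances

Hamming distances normalize by *jointly scored* characters (not total
characters), so missing data shrinks the denominator; a pair sharing no
scored character is an error naming the pair. Mismatches count 1 whatever
the state pair, including the ternary character.

Stage 1 follows the agglomerative scheme of the neighbour-net algorithm:
clusters (singletons or linked pairs) are chosen by the neighbour-joining
criterion on cluster-averaged distances; within the chosen pair, member
nodes are chosen by the same criterion on the mixed unit set (remaining
clusters as units plus the members of the two clusters individually); the
linked chain is reduced 3-at-a-time with the standard (2/3, 1/3) distance
reduction, and reductions unwind at the end into the circular ordering.
Selection ties break by lexicographic taxon label and the final cycle is
reported in a canonical rotation/orientation, so orderings are reproducible.
Stage 2 solves non-negative least squares over all n(n−1)/2 circular splits
(active-set NNLS) and drops weights ≤ 1e-8 (configurable). For additive
tree metrics the positive splits provably include all tree splits, and for
metrics generated from a circular split system the recovered weights match
the generator — both verified at 1e-6 across randomized cases. Sparse
circular systems can admit several compatible cycles; recovered weights are
compared as bipartitions, which is invariant to that freedom. Network
drawing is out of scope; the output is the split system.

## Synthetic data

Every generator is a pure function of its parameters and a seed, with a
root seed fanned out through `SeedSequence` substreams so one stage's
settings never perturb another's draws.

- **Trees**: forward birth–death simulation from the crown, stopped at the
  first event after the lineage count reaches `n_tips`; extinct lineages
  are pruned and unary nodes suppressed. For pure birth the root age is a
  sum of Exp(i·λ) intervals, i = 2..n — the tests compare the generator
  against an independent minimal sampler of that same process. With
  extinction, replicates whose extant count falls below target are simply
  redrawn (no GSA correction); this mild conditioning bias is irrelevant to
  the consumers, which need valid dated trees, not unbiased BD samples.
- **Characters**: forward Mk simulation down the tree using the closed-form
  transition matrix.
- **Occurrence worlds**: mosaic grids painted from rectangular patches;
  species ranges as Gaussian clouds (rejection-sampled into the grid), or,
  in the demo preset, stratified class-first placement so computed profiles
  converge on the configured signatures. Real-world features deliberately
  not emulated: coastline/elevation masks, spatially autocorrelated
  collection effort, georeferencing error, and outlier records (the real
  workflow cleans those before profiling). Passing tests therefore show the
  counting and classification machinery is correct, not that it is robust
  to dirty occurrence data.
- **Loci**: per-locus multinomial draws over {ABBA, BABA, uninformative}.
  The admixture mode plants `p_ABBA = p0 + γ·(2/15)`, `p_BABA = p0` with
  `p0 = 0.02`, so γ = 0.3 gives E[D] = 0.5 over a 4 % informative-site
  background — chosen to match reduced-representation scale (50 000 sites,
  200 loci per test). No coalescent process is simulated: the generator
  reproduces the pattern-count statistics the D-test consumes, nothing
  deeper.
- **Fossils**: anchor branch uniform over non-root branches, oldest age
  uniform on the branch's open age interval, youngest uniform on
  [0, oldest], states from a configurable distribution; every spec is
  graftable by construction. The demo preset instead scores fossils
  coherently in time and lineage (Palaeogene → humid categories, Miocene →
  intermediate, younger → the anchor clade's modal extant state), because
  independent uniform states make the combined character saturate the rate
  estimate (see above).

The demo preset is shaped like the motivating study — 15 ingroup species,
root age 36.7 Ma, western crown 24.3 Ma, subsection crowns through the
Miocene, Pleistocene sister pairs, a 5-state niche character, a 12-trait
leaf matrix (11 binary, 1 ternary) and 47 fossils of which ~7/8 are
assignable — but its occurrence counts (600 records/species) and locus
numbers are desk-scale choices, not measurements.

## Pipeline determinism

Stages communicate only through plain-text artifacts with fixed float
formatting (`%.10g`), and the manifest records SHA-256 digests, config hash
and seed but no timestamps, so a rerun under the same config is
byte-identical end to end (asserted in the acceptance suite by comparing
every digest across two fresh runs).

## Known limitations

- Single shared rate per character set; no asymmetric or ordered models,
  rate heterogeneity, stochastic mapping or Bayesian reconstruction.
- Single-character rate estimates can be boundary cases by nature;
  downstream interpretation should check the `q_at_boundary` flag.
- The niche cascade's thresholds are choices, not estimates; sensitivity is
  exposed via `NicheRules` but not explored automatically.
- The D-test assumes polarizable biallelic sites and resamples loci only;
  no f-statistics, windowed scans or VCF ingestion.
- Neighbour-net weight uniqueness holds only up to bipartition identity
  when the input metric is compatible with several circular orderings.
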