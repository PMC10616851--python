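# Methods

This note records the models implemented in `germbank`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
test-bench does and does not demonstrate about real data.

## Genotype model and filtering

Genotypes are unphased biallelic dosages: 0 (hom-ref), 1 (het), 2 (hom-alt),
−1 (missing). `0/1` and `1/0` (phased or unphased) both map to 1 — GBS calls
carry no usable phase. Allele frequencies are allele-count based over
non-missing calls: a het contributes one alt allele, so
`alt_freq = (2·n_homalt + n_het) / (2·n_called)`.

Site filtering keeps a locus iff `maf > 0.01`, `missing < 0.30` and
`het < 0.10`, with *strict* comparisons — boundary values are excluded.
This matters in practice: a MAF of exactly 0.01 is removed. Loci with no
calls at all are always removed (their MAF is undefined). Accession
filtering (drop iff missing fraction > 0.80) runs *before* site filtering,
on the full marker set; running it afterwards would let low-quality
accessions influence which sites survive. Filtering is idempotent.

The duplicate-matching prefilter is deliberately laxer (MAF > 0.01,
missing < 0.50, het < 0.20): identity-by-state comparison tolerates missing
data, and over-filtering before matching discards exactly the informative
rare variants that distinguish near-identical material.

## Duplicate detection (identity by state)

For accessions *a*, *b*, only sites homozygous and non-missing in both are
compared; `IBS = n_matching / n_compared` is kept as an exact rational.
Heterozygous sites are excluded because residual heterozygosity in inbred
material is mostly genotyping noise. Pairs need at least `min_overlap = 100`
compared sites — a 99% threshold over a handful of sites is meaningless.
The threshold is `IBS > 0.99`.

Because ">99% identical" is not transitive, duplicate *sets* are defined as
connected components of the above-threshold graph (size ≥ 2). Within a
component, pairs that individually fall below the threshold are reported as
annotations rather than used to split the set. Matching runs within each
recorded species: cross-species matches are a misclassification problem,
not a redundancy one. The tool only reports; it never renames records — the
curatorial decision (phenotype, provenance) stays with a human.

## Misclassification flagging

The classical procedure — color a phylogeny by recorded species and look
for leaves of the wrong color — is made algorithmic as a k-nearest-neighbor
majority vote on the genetic distance matrix (`k = 5`). An accession is
flagged when a *single other* species holds a strict majority (> 0.5) among
its k nearest non-self neighbors; the vote fraction is reported as support.
Ties produce no flag and are logged. With fewer than k other accessions,
all are used. Flags are advisory: downstream per-species analyses use
recorded labels unless `--apply-flags` regroups by the suggested ones.

k = 5 balances two failure modes: small k is noisy for outliers sitting
between clusters; large k dilutes small species (several species in a real
collection have under ten members).

## Diversity and differentiation

Per-locus gene diversity is `h = 2p(1−p)`; the group's Nei index averages
`h` over **all** loci with a defined frequency, monomorphic loci included
as zeros. Averaging over segregating loci only would change the scale and
make groups genotyped on different marker sets incomparable. Estimators are
plug-in by default; the `2n/(2n−1)` small-sample correction is available
(`unbiased=True`) but off, keeping reported indices on the conventional
scale.

`G_ST = (H_T − H_S)/H_T` is computed as a multi-locus ratio of sums
`Σ(H_T,l − H_S,l) / Σ H_T,l` over loci with defined frequencies in every
group; `H_S` is the unweighted mean of within-group diversities and `H_T`
the diversity at the unweighted mean frequency. Unweighted means keep the
statistic invariant to group size imbalance, which is severe in gene banks.

A property worth knowing: for **two** populations independently diverged
from a common ancestor with divergence `F` (the Balding–Nichols parameter),
pairwise G_ST converges to `F/(2−F)`, not `F` — with k populations the
limit is `F(1−1/k)/(1−F/k)`, approaching `F` only as k grows. The test
suite asserts both facts: the two-population bias explicitly, and
consistency for `F` using ten populations. This is a property of Nei's
estimator itself (Hudson-style estimators behave differently) and is the
reason the estimator-recovery simulations use ten populations.

## Distances, neighbor joining, Newick

Genetic distance is Euclidean on dosages over pairwise-complete loci,
rescaled by `sqrt(L/L_ab)` so that pairs with more missing data are not
artificially closer. Genotypes are not standardized first — distances stay
on the dosage scale. An accession with no calls, or a pair with no shared
calls, is an error naming the offender.

Neighbor joining is the canonical O(n³) agglomeration with
`Q(i,j) = (m−2)d(i,j) − r_i − r_j`; no relaxed/heuristic variants, because
the implementation is required to be *exact* on additive matrices (the
returned tree reproduces every input distance; verified to 1e−9 over
random trees of 5–40 leaves). Ties in the Q-matrix argmin break at the
lowest (row, column) pair of the current matrix — determinism matters more
than which of several equally optimal joins is taken. Negative branch
lengths (possible on non-additive input) are retained in the data
structure; on Newick serialization they are clamped to zero with the
deficit transferred to the child's outgoing edges (path lengths through the
parent are preserved where possible), and `clamp_negative=False` disables
this for exactness work. Newick is written with 6 significant digits by
default and parsed back with full quoting support; round-trips preserve
topology exactly and lengths to the printed precision.

## Relationship matrix and PCA

Missing calls are imputed to the locus mean call (keeps the matrix PSD and
is the convention of standard A-matrix routines), markers centered at
`2p_l`, and `A = WW'/(2Σp_l(1−p_l))`. Because centering uses the sample
frequencies, `A·1 = 0` exactly, and the mean off-diagonal entry equals
`−trace(A)/(n(n−1))` ≈ −1/n — "unrelated individuals have A ≈ 0" holds only
up to that O(1/n) term.

PCA is the eigendecomposition of A; components are ordered by descending
eigenvalue, each eigenvector's sign fixed so its largest-magnitude loading
is positive (signs are otherwise arbitrary and would break reproducibility),
and coordinates scaled by the square root of the (clipped non-negative)
eigenvalue. Variance explained is relative to the sum of **all** clipped
eigenvalues, not the retained top-k — the alternative silently inflates
percentages. Near-degenerate spectra set a `degenerate` flag because
coordinates are then defined only up to rotation.

## Subgenome inference

Each (accession, candidate genome) pair carries two statistics: the
fraction of reads aligning to the candidate's reference, and the fraction
of the candidate's diploid-panel segregating loci that received a call.
A genome is *present* when both clear their presence thresholds, *absent*
when both fall below their absence thresholds, otherwise *ambiguous* — the
two statistics must agree because either alone can be confounded
(read rates by genome similarity, locus rates by coverage). Raising either
statistic can never demote a verdict (monotonicity is property-tested).

Default thresholds (reads: present ≥ 0.30 / absent ≤ 0.27; loci: present
≥ 0.35 / absent ≤ 0.30) sit in the gap between the empirical regimes
observed for U/M tetraploids: present ≈ 0.38 read fraction and 0.46–0.50
locus fraction; absent ≈ 0.21 and 0.10–0.24. They are fully configurable,
and `calibrate_thresholds` sets all four at the mid-gap between known
carrier and non-carrier controls (yielding degenerate bands, every call
decided). Note the geometry: with read rates spread sd ≈ 0.03 around the
present mean, the default presence threshold sits ~2.7 sd away, so roughly
0.4% of truly present genomes land in the ambiguous band; across hundreds
of accessions a handful of ambiguous calls is the expected behavior of the
rule, not a defect. The inferred formula concatenates present symbols
(alphabetically; composition, not donor order) and pads with `X` per
unexplained ploidy slot when ploidy is known. Ambiguous genomes never enter
a formula. Read-rate denominators are whatever the upstream aligner used;
the ingest contract leaves that to the caller's metadata.

## The synthetic generator

What it emulates: several inbred diploid species per genome diverged under
Balding–Nichols (`p_s ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F)` around ancestral
`p0 ~ Beta(0.5, 0.5)`); allopolyploids carrying the union of calls over
their component genomes' disjoint locus blocks; a genus-wide *core* locus
class conserved across all species (callable everywhere at
`1 − missing_rate`), which is what survives whole-collection site filtering
— without it a multi-genome panel has no loci under 30% global missingness,
which contradicts how real collection-wide GBS matrices behave (conserved
restriction sites are exactly the loci that get called genus-wide).
Diploids are cross-called at foreign genome blocks at rate 0.15, and
polyploids are called at carried/foreign blocks at 0.48/0.17 — matching the
observed tetraploid locus-recovery regimes. Duplicates are copies with
per-call error 0.001 and 30% extra missingness; label errors (5% by
default) permute the recorded species (and its formula/ploidy — a wrong
database record is wrong wholesale) while truth retains reality; duplicates
and their sources are never mislabeled, keeping the two planted structures
orthogonal. Defaults: 2,000 loci per genome plus 2,000 core loci, 20
accessions per diploid species, F = 0.3, residual het 0.02, missingness
0.10. Everything is reproducible from the config seed, byte for byte.

What it does **not** emulate — and therefore what passing tests do not
show about real data: linkage disequilibrium (no statistic here uses LD);
homoeologous cross-calling within polyploids beyond a uniform rate;
reference bias, coverage variation and genotyping-error structure of real
GBS; outcrossing species (everything is inbred plus uniform residual het);
geographic population structure within species. Recovery rates measured on
this generator are upper bounds for messy real panels.

## Pipeline conventions

The `all` subcommand chains accession filter → site filter →
misclassification flags → duplicate sets → per-species diversity and G_ST →
NJ tree → PCA → subgenome calls, writing one JSON report and flat TSVs.
Reports round floats to 6 decimals and sort keys, so identical inputs and
seed give byte-identical outputs (the run log carries timestamps and is
excluded from that guarantee). Simulation sizes in the test-bench (134
accessions × 12,000 loci for the standard panel; 200 accessions × 2,000
loci per divergence level for estimator recovery; 200 tetraploids for
subgenome recovery) were chosen to put Monte-Carlo noise well inside the
asserted tolerances while keeping the whole suite fast on a laptop.

## Known limitations

* Misclassification flagging assumes species form coherent genetic
  clusters; recently diverged or admixed species pairs (the kind with
  pairwise G_ST near zero) cannot be distinguished by any label-vs-cluster
  method, this one included.
* Pairwise Nei G_ST between two groups is a biased estimator of the
  divergence parameter (see above); values are comparable across pairs but
  should not be read as absolute F.
* The subgenome AND-rule trades recall for precision near the thresholds;
  with evidence distributions overlapping a threshold, ambiguous calls are
  expected and should be resolved with controls (`calibrate_thresholds`)
  rather than by widening bands ad hoc.
* VCF support is the biallelic-SNP/GT subset only; multiallelic records are
  skipped with a warning, not decomposed.
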