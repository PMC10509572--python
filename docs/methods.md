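# Methods

This note records the models, defaults and numerical choices behind
`ypopgen`, and what the synthetic tests do and do not demonstrate.

## Data model

A sample is one male: a population/ethnicity label, one representative
coordinate (decimal degrees WGS84; populations, not individuals, are
mapped), a terminal haplogroup call, and a 27-STR haplotype. An allele is a
repeat count; intermediate alleles (e.g. 17.2) are valid with fractional
part in {.0, .1, .2, .3} and range [5, 60]. DYS385 and DYF387S1 are stored
as unordered two-allele combinations, so "11-14" and "14-11" are the same
call; haplotype identity for counting distinct haplotypes uses all 27 loci
with combinations as single units. DYS389b is derived as DYS389II −
DYS389I at read time and cross-checked when all three columns are present;
a non-positive difference is a hard row error. Missing alleles are allowed:
each statistic excludes missing-bearing samples for itself only and records
the exclusion count.

The default panel carries per-locus per-generation mutation rates. These
are YHRD-style defaults shipped with the package (artifact defaults, not
measured data) and are overridable via a panel TSV. Two derived subsets
matter: the 23 single-copy loci (FST, networks, prediction) and the 14
slowly-mutating loci (DYS389I, DYS389b, DYS390, DYS391, DYS392, DYS393,
DYS437, DYS438, DYS439, DYS448, DYS456, DYS458, DYS635, YGATAH4) used for
dating.

## Haplogroup nomenclature

Names parse as trunk capital + alternating digit/letter refinements, with
optional `*` (paraphyletic residue) and `-SNP` suffix. Because ISOGG
nomenclature encodes topology, a tree is reconstructed from a flat
(name, defining SNP) list: each node's parent is its longest proper prefix
present in the list. Assignment from SNP states returns the deepest node
whose defining SNP is derived and whose typed ancestors are all derived;
untyped SNPs are unknown, never ancestral (panels differ across source
studies). A derived SNP off the root-to-result path is a conflict error,
not a silent best guess. `X*` is emitted when all typed daughter SNPs are
ancestral; a plain parent name when daughters are untyped.

## Diversity statistics

All spectra are direct counts. Diversity is the unbiased
`n(1 − Σpᵢ²)/(n − 1)` (undefined for n < 2), MP is `Σpᵢ²`, DC the number of
observed haplotypes over n. Gene diversity of the multi-copy loci uses the
allele *combination* as the category — pooling single alleles would
understate the marker's resolution and is not what combination reporting
means. Values are kept at full precision internally; rounding happens only
at presentation.

## AMOVA FST

For a pair of populations the squared-distance matrix between individuals
is partitioned into within/among sums of squares; with mean squares
`MS_a`, `MS_w` and `n' = (N − Σn_k²/N)/(P−1)`, the variance components are
`σ²_a = (MS_a − MS_w)/n'`, `σ²_w = MS_w` and ΦST = σ²_a/(σ²_a + σ²_w).
Two distances are provided because the upstream convention (Arlequin's
setting) is ambiguous: 0/1 haplotype identity (default) and stepwise
Σ|Δrepeats|² (RST-like). The mode is recorded in output metadata.
Intermediate alleles enter the stepwise distance by their numeric
difference. Negative estimates are reported as computed (the estimator's
usual small-sample behaviour; identical populations give slightly negative
values, not exactly zero) and clipped to 0 only for display. Significance
is by permutation of individuals across the pair with the (b+1)/(m+1)
estimator; default 10,000 permutations, seeded. Note that with near-unique
haplotypes everywhere (the forensic regime) identity-mode ΦST approaches
zero by construction; the stepwise mode is the informative one there.

## PCA and frequency surfaces

PCA is covariance PCA (SVD of the column-centred frequency matrix) —
whether the upstream analysis used correlation scaling is unstated, and
covariance is the default here, flagged in output. Signs are fixed by
making each component's largest-magnitude loading positive. Surfaces use
inverse-distance weighting (`wᵢ = dᵢ^−p`, default p = 2) on one station per
population, over the stations' bounding box padded by 2° at 0.5° cells; a
cell within half a cell of a station takes the station value exactly. IDW
was chosen for determinism; no interpolation method is named upstream.
Only gridded values are produced, not cartography.

## Median-joining networks

Characters are the 23 single-copy STRs (weights 1–5, slowest mutation-rate
quintile → 5) plus optional binary SNPs at weight 99. Distance is
Σ w·|Δrepeats| + Σ w·[states differ]. Construction: (1) ε-relaxed minimum
spanning network — an edge belongs iff its weight is within ε of the
bottleneck (minimax-path) weight between its endpoints; (2) quasi-medians
of mutually connected triplets, component-wise median for STRs and majority
for SNPs; (3) greedy addition of the candidate that most reduces the
minimum-spanning cost, repeated to a fixed point (cost strictly decreases,
so termination is guaranteed); (4) removal of medians that no longer
shorten the network. ε defaults to 0 (strict MJ). All ties (equal-cost
edges, equal-gain medians) break lexicographically on node vectors, so the
result is independent of input order. The optional pre-processing step is
star contraction: leaf classes within δ of a more frequent hub are folded
into it, accumulating multiplicity; off by default. Exports (GraphML, DOT,
edge TSV) carry multiplicities, per-population composition strings and
per-edge changed characters. No maximum-parsimony post-processing.

## TMRCA estimation

Three estimators, all on the slow-locus set and reported in generations
and in years at 25 years/generation (configurable):

- **ASD**: per locus, the mean squared deviation from a founder haplotype;
  under single-step mutation `E[ASD_l] = μ_l t`, so `T̂ = mean_l ASD_l/μ_l`.
  The founder defaults to the modal haplotype (component-wise most frequent
  allele, ties to the smaller allele). Intervals by bootstrap over samples
  (1,000 resamples, seeded). Unbiased on star genealogies; on coalescent
  genealogies it dates the founder of the sampled cluster.
- **rho**: multiplicity-weighted mean number of mutational steps from a
  chosen root node along the network (shortest path in unweighted step
  counts), `T̂ = ρ/Σμ`, with the conventional `σ_ρ = sqrt(ρ/n)` interval.
  Because multi-step STR changes partially hide back-mutations, rho is
  mildly downward-biased at depths where per-locus θ is no longer small.
- **Bayesian coalescent MCMC**: a single-population model with effective
  size N (lognormal prior, median 1000, σ = 1 on log N) and exponential
  growth parameterised by scaled growth β = αN (Exp(1) prior); both can be
  fixed. The genealogy prior uses backwards intensity e^{αt}/N per pair.
  The STR likelihood is Felsenstein pruning over an integer allele lattice
  bounded to the observed range ± 10 repeats, with the branch transition
  kernel in closed form: P(Δ = k; θ = μt) = e^{−θ} I_k(θ), computed by
  Miller's downward Bessel recurrence. Moves: node-time slides (uniform
  between the bracketing events; multiplicative for the root gap), narrow
  exchange (node↔uncle) for topology, whole-tree scaling, and log-random
  walks on N and β; partial likelihoods are updated incrementally along
  the path to the root. The chain starts from a UPGMA tree on L1 allele
  distances with heights scaled by 1/(2Σμ). Reported: posterior median
  height and central 95% interval, with the thinned trace. A split-half
  discrepancy of the sampled heights beyond 25% raises a convergence
  warning (never silent). Production defaults mirror the two-million-sample
  protocol with 3,000 burn-in; the `scaled_down` preset (10,000 samples,
  500 burn-in) is used in tests and in the acceptance script to stay within
  ordinary desk runtimes. This sampler is deliberately scoped to a single
  population with growth: multi-population splitting models are out of
  scope, so published multi-group BATWING dates are plausibility context,
  not targets.

## Haplogroup prediction

The claim under test is that Y-STR haplotypes carry enough haplogroup
signal to predict membership. The association table gives the descriptive
evidence (per-haplogroup, per-locus gene diversity and allele spectra,
with a permutation baseline available through label shuffling). The
predictor is the minimal model matching that evidence: a per-locus
conditional-independence categorical Bayes classifier with additive
smoothing (pseudocount 0.5 per allele category; a pseudocount of 0
reintroduces the zero-likelihood hazard for unseen alleles and is allowed
but documented). Priors are training proportions; prediction works in log
space over the covered single-copy loci; multi-copy loci are excluded.
Default prediction level is 1 (major clades, e.g. O1 vs O2). Validation is
stratified k-fold with classes smaller than k excluded and reported.

## Synthetic data generator

The generator is first-class code and defines the study conditions used in
tests: five populations with sizes 1266/654/680/427/314 — the reciprocals
of the published per-population minimum haplotype frequencies — and
major-clade mixtures reconstructed from the published frequency table
(Han O 0.800, Yi O 0.583, Hui O 0.474, Mongolia O 0.365, Kyrgyz R 0.455,
Kyrgyz without O). Within each trunk clade, samples are spread uniformly
over the terminal clades of the bundled nomenclature tree. For every
population × terminal-clade cluster one coalescent genealogy is simulated
(default N = 1000, growth 0 — a scale chosen to put cluster ages in the
plausible few-tens-of-kya range while keeping most haplotypes distinct),
and stepwise mutations are dropped per branch (Poisson(μt), ±1 with equal
probability). Haplogroup founder haplotypes are the base modal haplotype
plus per-locus rounded Normal(0, 2.5) offsets — a stand-in for deep
between-haplogroup divergence that makes haplogroups separable the way
real ones are. Multi-copy loci are simulated as two independent lineages
reported as a combination. SNP states are set derived exactly on the
root-to-clade path. All randomness flows from one seed through named
SeedSequence substreams (founders; population draws; one per
population × clade), so datasets are byte-identical per seed.

What the generator does **not** emulate: migration and admixture between
populations (differentiation comes only from mixture differences and
independent genealogies), population growth history, locus-specific
mutation asymmetries or range constraints beyond clipping at [5, 60], and
genotyping error. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to real-data
artefacts.

## Numerical and design notes

- Problem sizes in tests are chosen for desk-scale runs: the MCMC
  calibration experiment uses 100 replicates of n = 30 with 10,000-sample
  chains; the prior-only check uses 200,000 prior samples against 4,000
  directly simulated genealogies.
- The rho/ASD comparison uses shallow stars (depth 25 generations) where
  per-locus θ ≤ 0.1 so rho's multi-step bias stays inside the comparison
  tolerance; this is a property of the estimator, documented above.
- The Bessel kernel's unbounded-lattice form equals the bounded-lattice
  transition to well below 1e−6 at the ± 10-repeat padding used, so the
  closed form is used throughout.
- Permutation p-values can never be 0 by construction ((b+1)/(m+1)).
- Equal-cost choices everywhere (modal ties, MST ties, median ties) break
  deterministically toward smaller alleles / lexicographically smaller
  vectors.

## Known limitations

- Identity-mode ΦST is uninformative when every haplotype is unique; use
  stepwise mode for high-resolution panels.
- The MCMC models a single panmictic population with exponential growth;
  structured or admixed samples violate the model and the estimate should
  be read as a within-cluster age.
- The predictor assumes conditional independence of loci given the
  haplogroup; linked loci on the non-recombining Y violate this, which
  inflates posterior confidence (winner probabilities) more than accuracy.
- The haplogroup tree is an input; no phylogenetic inference from SNPs is
  attempted.
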