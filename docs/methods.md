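# Methods

This note documents the models, estimators and numerical choices behind
`poolstruct`, and what the synthetic test conditions do and do not show
about real data.

## Pooled frequency calling

Each landrace is a pool of n = 15 diploid plants, so the true pool
frequency of the B allele at a locus is a multiple of 1/(2n) = 1/30. The
array reports two channel intensities per SNP; the caller works entirely on
the fluorescence intensity ratio FIR = I_B / (I_A + I_B) ∈ [0, 1].

**Monomorphism test.** Controlled pools fixed for allele A (known frequency
0) or B (frequency 1) define homozygous clusters (μ_A, σ_A) and (μ_B, σ_B)
with μ_A < μ_B. For an observed FIR the nearer cluster c is chosen by
|FIR − μ_c|, and the entry is declared polymorphic iff the FIR deviates
from μ_c *toward the interior* by more than z_{1−α}·σ_c. The test is
one-sided because a deviation away from the interior cannot be evidence of
polymorphism; under a truly fixed pool with Gaussian cluster noise the
rejection probability is exactly α (default 0.05, i.e. 5% of fixed pools
are expected to be declared polymorphic). No multiple-testing correction is
applied: the test's stated error rate is per landrace × SNP entry. Entries
kept monomorphic are set to exactly 0 or 1, so the caller has zero error on
fixed loci it does not reject — conservative behaviour near fixation, at
the price of α false rejections.

**Frequency prediction.** For polymorphic entries the frequency is
f̂ = invlogit(a + b·logit(FIR)), with (a, b) estimated by a binomial GLM
(logit link, weights 2n gametes) of the known frequencies of the
controlled pools on logit(FIR). Series 1 of the controlled pools trains
the GLM; series 2 is held out and its mean absolute prediction error is
stored on the model (`validation_mae`). The fit is a single global
calibration across SNPs; per-SNP calibrations are deliberately out of
scope. FIR values are clipped to [1e-6, 1 − 1e-6] before the logit so
boundary observations remain finite; f̂ is monotone in FIR whenever b > 0.

## Diversity statistics

All statistics take a landrace × locus matrix of frequencies in [0, 1] with
missing values allowed (available-case per locus, pairwise-complete for
distances; unweighted means everywhere).

* Within landrace: A (1 if the pool is fixed at the locus, else 2), MAF
  = min(p, 1−p), and Nei gene diversity H = 2p(1−p), each averaged ± SD
  across loci.
* Group/panel level: the locus mean frequency p̄_l over member landraces
  gives H_t(l) = 2p̄_l(1−p̄_l) and the group-level A and MAF. A locus
  counts as monomorphic for a group only when **every** member is fixed for
  the same allele (stricter than p̄ ∈ {0,1} under missing data).
* G_st = (H_t − H̄_s)/H_t with H_t and H̄_s averaged across loci, loci with
  H_t(l) = 0 excluded from both averages. H̄_s ≤ H_t always (Nei
  decomposition), so G_st ∈ [0, 1].
* No small-sample correction is applied to H. The unbiased estimator would
  multiply by 2n/(2n−1); at n = 15 that is 30/29, a 3.4% inflation — small
  enough to ignore, and `unbiased_correction_factor` quantifies exactly
  what is being omitted.
* Modified Roger's distance: MRD(i,j) = sqrt(Σ_l Σ_alleles (p_ila −
  p_jla)² / (2L)) = sqrt(Σ_l (p_il − p_jl)² / L) for biallelic loci, a
  scaled Euclidean metric (hence PCoA on an MRD matrix is exact and the
  triangle inequality holds). L counts loci observed in both landraces.
* Pairwise F_ST between two frequency vectors: per locus H_t from the
  midpoint frequency and H_w the mean of the two within-diversities;
  F_ST = (ΣH_t − ΣH_w)/ΣH_t as a **ratio of locus sums**, which is less
  noisy than averaging per-locus ratios. Many F_ST estimators exist
  (ratio-of-averages, ANOVA-based, weighted); this Nei-style choice is
  isolated behind one function so an alternative can be swapped without
  touching callers.

## Structure analysis

* **PCoA** is classical metric scaling: Gower double-centering of −½D²,
  eigendecomposition, coordinates scaled by sqrt(λ). Negative eigenvalues
  (possible for non-Euclidean input) are excluded both from the reported
  axes and from the percent-variance denominator. Axis signs are fixed by
  making the first nonzero loading positive.
* **Ward trees** use scipy's Ward linkage on the distance matrix, i.e. the
  Ward.D2 convention (squared distances inside the Lance–Williams update).
  Tie-breaking follows scipy's deterministic nearest-neighbor chain; ties
  are measure-zero for the continuous inputs used here.
* **Neighbor joining** is the classic Saitou–Nei algorithm with the
  standard Q-criterion and a deterministic row-major argmin. BIONJ's
  variance weighting is not implemented: both are exact on additive
  matrices, which is the property the tests pin down. Negative branch
  lengths are clamped to zero with the deficit moved to the sibling
  branch, preserving the pair's path length.
* **Genotype simulation for external ancestry software**: model-based
  ancestry programs need individual multilocus genotypes, so 5 individuals
  per landrace are simulated as Binomial(2, p) per locus under
  Hardy–Weinberg equilibrium within the landrace, on 2500 loci chosen by
  even spacing over the locus index (a stand-in for "independent SNPs";
  a seeded random subset is available behind a flag). The external
  program's Q-matrix is read back and averaged over each landrace's
  individuals. The ancestry program itself (and its choice of K) is out of
  scope.
* **Assignment rule**: a landrace is assigned to its argmax group iff that
  membership exceeds 0.6, otherwise labelled "admixed"; ties at the
  maximum (within 1e-12) are admixed. Group allele frequencies are
  unweighted means over assigned members.

## Ancestry regression

min_β ‖f − Gβ‖² subject to β ≥ 0 and Σβ = 1, solved by an exact
active-set method: on the current free set the equality-constrained KKT
system is solved directly; variables driven negative are fixed at zero, and
fixed variables whose KKT multiplier is negative are released. For K ≤ a
few dozen groups this terminates in a handful of iterations, is fully
deterministic, and satisfies the KKT conditions to machine precision
(checked in tests against a dense simplex grid search). "Positive"
coefficients are implemented as ≥ 0 — strict positivity has no meaning in
a QP. No intercept is included: response and regressors are frequencies on
a common scale and an intercept would break the simplex interpretation.
Missing loci are excluded per landrace, so different landraces may use
different L; the per-row L is reported alongside the residual sum of
squares.

## Phenotype pipeline

**Mixed model.** Per trait: y = variety (fixed) + trial (random intercept,
iid N(0, σ²_t)) + residual, fitted by REML via statsmodels MixedLM.
Varieties are coded as cell means (no intercept), so each fixed coefficient
is directly the variety BLUE; in a balanced complete design this equals the
raw variety mean (verified to 1e-8). Variance estimates are floored at
zero. The optimizer is BFGS with a Powell fallback — the default L-BFGS
implementation can converge to a corrupt point when the random-effect
variance hits the boundary. An optional replicate-within-trial variance
component is available behind a flag.

**Derived traits.** ASI = DS − DT (days; negative values mean silking
before anthesis) and EPHR = (EH/PH)×100 (%). Two modes are supported and
recorded in the output: (A, default) derive per record, then fit the mixed
model to all six traits; (B) fit the four raw traits and derive ASI/EPHR
from the BLUE columns. The modes differ only through unbalancedness (A)
versus exact post-hoc identities (B).

**PCA.** Correlation-matrix PCA of the standardized BLUEs; eigenvalues sum
to the number of traits (6). Components with eigenvalue > 1 are retained
but never fewer than two: a single retained dimension makes the
15-cluster preclustering degenerate, and the second component is needed to
separate flowering-interval variation from the overall size/earliness
axis. A warning is logged when the >1 rule alone would keep fewer.

**Two-stage clustering.** Stage 1: seeded k-means (k-means++ with 100
restarts, best inertia kept) into k = 15 preliminary clusters on Euclidean
distance over the retained scores; the pseudo-F statistic is reported as a
diagnostic, with a scan helper, but k is fixed at 15 by default. This is a
deterministic approximation of one-pass leader clustering; the planted-
partition tests show it recovers well-separated clusters exactly. Stage 2:
agglomerative average linkage over the 15 preliminary clusters, initial
distances = Euclidean centroid distances, Lance–Williams update
d(i∪j,k) = (n_i·d_ik + n_j·d_jk)/(n_i + n_j) with n the member counts; the
tree is cut into 5 main clusters labelled A, B, … in dendrogram leaf
order. With equal sizes the procedure reduces to UPGMA (tested against
scipy's average linkage).

## Synthetic data generator

The generator emulates the statistical structure of a pooled-genotyping
landrace study so that every stage has a testable truth:

* **Groups**: ancestral frequencies Uniform(0.05, 0.95) per locus; each of
  K groups drifts via Balding–Nichols, p_kl ~ Beta(p(1−F)/F, (1−p)(1−F)/F),
  with per-group F. Balding–Nichols is the standard structure simulator
  because F maps directly onto the expected differentiation.
* **Landraces**: admixture rows with one dominant component ≥ 0.75 for
  assigned landraces (dominant groups cycled), or flat-Dirichlet rows
  rejection-sampled until no component reaches 0.6 for admixed landraces —
  so the synthetic truth labels coincide with the downstream 0.6
  assignment rule by construction. The latent landrace frequency is the
  admixture mixture of group frequencies, drifted within-landrace by
  Balding–Nichols with a small coefficient (default 0.01), and the
  observed pool frequency is Binomial(2n, f)/(2n) with n = 15 plants.
* **Fluorescence**: latent FIR mean = invlogit(a + b·logit(f)) for
  interior f (default identity link a=0, b=1) and cluster means μ_A = 0.02,
  μ_B = 0.98 for fixed pools; observed FIR is truncated-Gaussian on [0, 1]
  with σ = 0.02; channel intensities are emitted so I_B/(I_A+I_B)
  reproduces the FIR exactly. The calibration table holds 1000 controlled
  pools with known frequencies cycling over the 31-point gamete grid,
  split into two series (train/validate). The real noise law of array
  fluorescence is unknown; a truncated Gaussian with a logit-linear mean
  is the simplest model consistent with a GLM-calibratable relationship,
  and the end-to-end recovery bound (MAE ≤ 0.05) is the property the
  suite enforces.
* **Trials**: group-level trait means ladder over maturity (days to
  tasseling 60–85 d, silking 2–3 d later, plant height 120–210 cm, ears at
  45% of plant height); landrace deviations, random per-location effects
  and residual noise are Gaussian with per-trait SDs (e.g. 2.5/1.5 d for
  phenology, 8/6 cm for height); silking never precedes tasseling in
  expectation; each landrace is assigned to 2–9 of the locations and five
  check entries are grown everywhere. The admixed fraction defaults to
  0.44, the kind of proportion seen in heavily worked genebank
  collections.

Desk-scale defaults are L = 2500 loci, K = 9 groups and 120 landraces —
scaled down from the tens of thousands of SNPs and several hundred
accessions of a real study; tests use smaller sizes still. What the
passing tests show is therefore *calibration and correctness of the
estimators under the assumed generative model* — they cannot show
robustness to real-data features the generator deliberately omits: linkage
disequilibrium along chromosomes, per-SNP calibration differences, probe
failure and batch effects, genotype–environment interaction, or spatial
field trends.

## Numerical conventions

* Logit clipping at 1e-6; frequencies clipped to [0, 1] after prediction.
* All CSV output at 10 significant digits so pipeline reruns are
  byte-comparable (hash-checked in tests).
* Every random stage takes an explicit seed; the pipeline config derives
  per-stage seeds from one master seed deterministically.
* Distance matrices are validated symmetric (1e-12), zero-diagonal and
  nonnegative on construction; admixture rows must sum to 1 within 1e-8.
* Degenerate inputs: zero total fluorescence intensity → missing entry
  with a warning; all-missing landraces are excluded from summaries;
  G_st is NaN when every locus is fixed for the same allele; empty groups
  yield size-0 rows in group tables but are an error where group
  frequencies are required.

## Known limitations

* The F_ST estimator is one of several in use; absolute values are not
  comparable across estimators, only the properties (bounds, symmetry,
  monotonicity in differentiation) are guaranteed.
* The global FIR calibration ignores per-SNP dye and hybridization
  differences; on real arrays a per-SNP model performs better.
* The mixed model treats trials as exchangeable random draws; systematic
  maturity-range differences between locations are only captured through
  the unbalanced assignment, not modelled.
* Average-linkage over preliminary centroids approximates average linkage
  over the underlying members after the first merge (exact for equal
  sizes); this mirrors the standard two-stage practice rather than exact
  all-pairs UPGMA on the full data.
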