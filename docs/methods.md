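# Methods

## Scoring model

MSAP compares two digests of the same DNA: EcoRI + HpaII ("H") and
EcoRI + MspI ("M"). Both isoschizomers cut 5'-CCGG-3', but HpaII is
blocked by internal-cytosine methylation while MspI is blocked by
external-cytosine methylation, so the joint band pattern at a fragment
locus reads out the methylation state of the site. Each
individual × locus cell maps deterministically to a type:

| (H, M) | type | reading                                   | degree |
|--------|------|-------------------------------------------|--------|
| (1, 1) | I    | unmethylated                              | 0      |
| (0, 1) | II   | full methylation of the internal cytosine | 1      |
| (1, 0) | III  | hemimethylation of the external cytosine  | 1      |
| (0, 0) | IV   | both/external cytosines methylated, or a  | 2      |
|        |      | site mutation (band absent in both)       |        |

Mixed scoring expands each four-state epilocus into four binary
indicator subepiloci (one-hot per cell), so frequency-based
dominant-marker statistics apply unchanged. The expansion is exactly
invertible; the four columns of a locus are linearly dependent (they
sum to one), which matters for the structure sampler (below).

### Methylation levels and conventions

Group levels are percentages of all (individual, locus) cells:
total = II+III+IV, non = I in every convention. Two conventions for
the full/hemi split circulate in the MSAP literature and this package
exposes both:

* `printed` (default): full = II + IV, hemi = III. This is the
  biochemically standard reading — type II is internal-cytosine *full*
  methylation, type III is *hemi*methylation — and the one regional
  rice surveys actually tabulate.
* `footnote`: full = III + IV, hemi = II, as table footnotes sometimes
  state.

Both satisfy full + hemi = total and total + non = 100. Type IV is
counted as methylated by default, despite its mutation ambiguity.

Group comparison uses one-way ANOVA on per-individual level vectors
plus Duncan's multiple range test: the critical range for means
`p` ranks apart uses the studentized range at Duncan's protection
level 1 − (1 − α)^(p−1) on the ANOVA within-group mean square (harmonic
mean group size for unequal n); the compact letter display assigns one
letter per maximal non-significant run of sorted means. Ties in means
are broken by group order, so output is deterministic.

### Locus accounting

A locus is *polymorphic* iff its pattern varies across individuals;
the default compares the joint (H, M) pattern (`"hpa"`/`"msp"` compare
one digest). A locus is a *methylation locus* under the default rule
(`"any"`) iff ≥1 individual shows type II/III/IV. Note that under this
rule a nonmethylated locus is all-type-I and hence monomorphic; survey
tables in which polymorphic loci outnumber methylation loci implicitly
use the alternative rule (`"differential"`): only HpaII/MspI
differential types II/III mark a methylation-susceptible locus, and
pure I/IV variation counts as AFLP-like presence/absence polymorphism.
Both rules are exposed because published tables do not state which was
used.

## Diversity statistics

Subepiloci are one-hot state indicators, not dominant genotypes, so
the within-group band frequency p is used directly as the allele
frequency — no dominant-marker √(null-homozygote) correction is
offered, since it would be wrong on one-hot data. Per subepilocus:
h = 1 − p² − q², Ne = 1/(p² + q²), I = −(p ln p + q ln q) (natural
log; 0 ln 0 ≡ 0). Means are over **all** subepiloci, monomorphic
included; PLP% counts subepiloci with 0 < p < 1. Nei's normalized
identity uses mean gene identities across subepiloci,
I_xy = mean(J_xy) / √(mean(J_x) · mean(J_y)), D = −ln I_xy; by
Cauchy–Schwarz I_xy ≤ 1, so D ≥ 0.

## AMOVA

With squared Euclidean distances on 0/1 data (= Hamming counts),
SS_total = (1/N) Σ_{i<j} d²_ij and SS_within = Σ_g (1/n_g) Σ_{i<j∈g}
d²_ij reproduce the coordinate-space deviation sums exactly.
Components follow the standard one-level unbalanced estimator:
σ²_w = MS_w, σ²_a = (MS_a − MS_w)/n0 with
n0 = (N − Σ n_g²/N)/(G−1) (= n for equal groups), Φst = σ²_a/σ²_T.
Negative σ²_a is reported as-is with a warning (Φst floored at zero
only in the report table). The permutation test shuffles individuals
among groups with sizes fixed; p = (b+1)/(n_perm+1) counts permuted
Φst ≥ observed, with the observed configuration included — the
default n_perm is 9999. A completely homogeneous data set (SS_total
= 0) reports Φst = 0 with a warning rather than NaN.

## Ordination and trees

PCoA Gower-centers the squared-distance matrix
(B = −½ J D² J), eigendecomposes, keeps positive eigenvalues, scales
eigenvectors by √λ, and reports % variance over positive eigenvalues;
each axis's first nonzero loading is made positive so coordinates are
reproducible across BLAS builds. Neighbour joining follows Saitou–Nei
with Q(i,j) = (r−2)d(i,j) − Σd(i,·) − Σd(j,·); ties break on the
lowest (row, column) pair; negative limb lengths are clamped to zero
with the deficit moved to the sister limb. Individual-level trees use
Euclidean (√Hamming) distances on subepiloci — Nei's frequency-based
distance is undefined for single individuals — while group-level
trees use Nei's D; both are exposed.

## Structure inference

The admixture model is deliberately haploid-Bernoulli rather than
STRUCTURE's diploid-genotype model: subepiloci are one-hot presence
states, and a diploid likelihood would double-count them. Priors are
P_ks ~ Beta(1,1) and Q_i ~ Dirichlet(α·1) with α fixed at 1 (no
Metropolis update on α; configurable). Gibbs sweeps alternate
Z | Q,P → P | Z,X → Q | Z; the recorded statistic is
log P(X | Z, P) after burn-in, whose mean across recorded sweeps is
the L(K) estimate. Because a locus's four indicators are dependent,
the default sampler input drops the type-I column per locus (three
informative columns); a flag retains all four.

MCMC defaults are desk-scale — burn-in 5,000, 20,000 sweeps, thin 10
(the pipeline default uses shorter schedules; survey-scale
100,000/1,000,000 runs are a config change). On the small matrices
this package targets, replicate runs at these schedules separate
K values by far more than their replicate scatter, which is what ΔK
consumes.

Evanno ΔK is mean_r |L_r(K+1) − 2L_r(K) + L_r(K−1)| / sd_r(L(K)) over
replicates paired by index; rows with zero sd are flagged undefined
rather than dropped, and best_K is the argmax over defined rows. Note
the numerator averages per-replicate absolute second differences, so
with per-replicate offsets that are constant in K it reduces to the
familiar |L''| of the means. Replicate runs are aligned to the first
run by the column permutation of Q maximizing summed column-wise dot
products, solved exactly as a (K × K) assignment problem — exact at
every K, so no greedy fallback is needed; full CLUMPP resampling is
out of scope.

## Synthetic data generator

The generator emulates a regional survey: G groups (default the five
regions FZ, CHY, JSJ, XS, WC, 10 individuals each), 8 primer pairs
totalling 551 loci with fragment lengths drawn uniquely per pair in
37–495 bp, and a latent subpopulation map (default {FZ, CHY, JSJ} → 1,
{XS, WC} → 2). For subpopulation k and locus l,
θ_kl ~ Dirichlet(α_c · base_type_probs) with
base_type_probs = (0.515, 0.16, 0.14, 0.185) — realistic mean type
proportions for temperate japonica rice surveys; individuals draw
types i.i.d. from their subpopulation's θ, types map to (H, M) bands,
and each band flips independently with probability 0.01, mimicking
scoring error on bands (so noise can create any type, including IV).

The concentration α_c is the differentiation dial: Φst decreases
monotonically in it. The default α_c = 6.15 was fixed once by running
`calibrate_differentiation` (bisection on log α_c, Φst averaged over
5 seeds) to the moderate-differentiation regime Φst ≈ 0.085 that the
package's analyses target. One scalar cannot simultaneously match
that regime and a ~50% within-group monomorphism rate; with Φst
calibrated, within-group PLP sits near 70% and h near 0.24, somewhat
above typical survey values. What passing tests show is therefore
that the *methods* behave correctly on data with the survey's
geometry and differentiation — not that the generator replicates any
particular survey's diversity indices. The generator also omits
within-region covariance (field effects): individuals within a region
are exchangeable. A truth record (subpopulation assignments, θ, true
types, seed) is written alongside outputs for recovery tests and is
never read by analysis code.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; the pipeline derives stage seeds from one master seed
  via `SeedSequence.spawn`, and every stage's seed is logged.
* Distance matrices are validated symmetric (1e-12), zero-diagonal,
  nonnegative; Nei identity ≤ 0 is an internal assertion (impossible
  for binary frequencies).
* Report tables round to the conventional display precision (2
  decimals for level percentages, 1 for accounting percentages, 3 for
  distances); full precision is kept internally.
* Missing band-matrix cells are rejected by default; an explicit
  `drop-locus` policy removes affected loci. Fragment-length
  filtering is off unless requested — size-selection windows in
  published methods sometimes contradict the tabulated length ranges,
  so the filter is never implicit.
* Degenerate inputs: all-identical individuals → Φst reported 0 with
  a warning; zero within-group variance with equal means → all groups
  share Duncan letter "a"; K = 1 → Q ≡ 1.

## Test-suite problem sizes

Stochastic checks run at desk scale chosen for tight seeded behaviour:
AMOVA null calibration uses 500 simulated 20 × 60 data sets with 199
permutations (Pr(p ≤ 0.05) within 0.05 ± 0.02); ΔK recovery uses ten
trials of a 2 × 10-individual, 60-locus strongly differentiated design
(Φst ≥ 0.3), K = 1..4 with 3 replicates (≥ 8/10 must select K = 2);
Φst calibration is verified at 5 × 6 individuals and 120 loci against
the 0.085 ± 0.02 band on fresh seeds.

## Known limitations

* Binary band calls are taken as ground truth; chromatogram peak
  calling, intensity thresholds and size standards are upstream.
* One-level AMOVA only (no nested regions), no confidence intervals
  on diversity indices, no bootstrap supports on trees.
* The structure model omits linkage and correlated-frequency (F-model)
  priors; α is fixed by default.
* Nei identity/distance is computed on subepiloci frequencies; raw
  band-locus frequencies would give slightly different values.
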