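# Methods

## The analysis problem

Two morphologically cryptic, broadcast-spawning snail species co-occur
at four coastal sites; one lives in bull-kelp holdfasts (and can raft
on detached kelp), the other on rock.  The pipeline asks whether their
population-genetic connectivity differs in level or in geographic
pattern, using seven highly polymorphic microsatellites with abundant
null alleles.  Every statistic here is allele-identity-based; no
mutation model is assumed anywhere.

## Species assignment

The no-admixture clustering model: individual *i* belongs wholly to
one of K clusters (uniform prior); cluster k has allele-frequency
vectors p_{k,l} per locus with a symmetric Dirichlet(λ) prior;
genotypes within a cluster follow HWE (p_a² homozygote, 2p_a p_b
heterozygote); missing loci contribute likelihood 1.  A Gibbs sampler
alternates frequency draws from the Dirichlet full conditional with
membership draws from the multinomial full conditional.  Q-values are
posterior membership frequencies over post-burn-in sweeps.

Choices that matter:

- **λ = 1.0** (uniform Dirichlet), the common default.
- **Label switching** is resolved sweep-to-sweep by matching cluster
  frequency blocks to the previous accepted orientation with minimal
  total-variation distance (Hungarian assignment); chains are aligned
  to the first chain by the same criterion on Q.  For K = 2
  well-separated clusters this is fully adequate.
- **Chain lengths** default to 2,000 burn-in + 10,000 sweeps × 5
  chains, which on two-cluster mixtures at divergence 0.3 recovers
  ≥ 95% of true labels at the 0.8 threshold; the heavier published
  settings (50,000 + 200,000) are available via `ClusterModel`.
- **Convergence** is declared when the minimum over chain pairs of the
  Pearson correlation of Q matrices is ≥ 0.99; failure sets a warning
  flag rather than raising, since partial mixing still yields usable
  Q-values for clearly assigned individuals.
- **Q exactly at the threshold** counts as ambiguous (the qualifying
  rule is strictly "greater than").
- The sampler assigns its per-individual random draws through the
  id-sorted order, so results are equivariant under permutation of
  input rows at a fixed seed — a property the tests assert exactly.
- Apparent genotypes are used as-is; no null-allele modelling inside
  the clustering.

## Null alleles

The observation model: with visible-allele frequencies p_i (summing to
1 − r) and null frequency r, true genotypes follow HWE over the
augmented vector; true (i,j) is seen as a heterozygote, (i,i) and
(i,null) as apparent homozygote i, (null,null) as a blank.  The EM
estimator splits each apparent-homozygote count between (i,i) and
(i,null) proportionally to p_i : 2r in the E-step and re-estimates
{p_i, r} from expected allele-copy counts in the M-step, to tolerance
1e-8 (max 10,000 iterations).  Because EM converges sublinearly at the
r = 0 boundary, estimates below 1e-3 are snapped to exactly 0 when the
null-free model has at least the same observed-data likelihood.

Two blank modes are exposed: `blanks-as-nulls` (default; blanks are
counted as (null,null) — appropriate here because repeated
amplification failure indicated genuine nulls) and `blanks-excluded`
(likelihood conditioned on a non-blank outcome).  Monomorphic and
empty cells return r = 0 with an explanatory note rather than being
dropped silently.

The homozygote-excess test pools the 2n observed allele copies,
re-pairs them at random, and counts homozygous pairs;
p = (1 + #{perm ≥ obs})/(1 + n_perm), never exactly 0.  Because the
statistic is discrete the test is slightly conservative (measured
type-I rate ≈ 0.036 at nominal 0.05 with n = 50 and 10 alleles).

The artefact diagnostic partitions the heterozygote deficit across
quartiles of allele-size difference (quartile boundaries weighted by
expected heterozygote mass).  Null alleles thin heterozygote classes
uniformly, so deficits computed from *normalized* class shares cancel;
large-allele dropout thins the top size-difference quartile
specifically.  Dropout is called when the top-quartile deficit both
dominates (> half the total) and exceeds twice its binomial sampling
SD.  This is a deliberately simplified stand-in for a full published
scoring-artefact battery; its power is modest — ~80% detection of a
0.5-rate dropout needs a few hundred individuals per cell, so the test
suite exercises it at n = 400 and treats paper-scale cells (n ≈ 16–35)
as below its resolution.

## Differentiation statistics

- **H_S / H_T** use Nei–Chesser bias corrections with the
  harmonic-mean sample size ñ: H_S = ñ/(ñ−1)·(1 − mean_k Σp²),
  H_T = 1 − Σp̄² + H_S/(kñ).  Note these corrected *estimators* can
  order H_T < H_S slightly on identical populations (the invariant
  H_S ≤ H_T holds in expectation, not per-sample), which is why D_est
  and G″_ST can be marginally negative under near-panmixia — the
  published global tables show the same behaviour for F_ST.
- **D_est** is computed per locus from raw frequencies and averaged
  arithmetically.  The bootstrap CI resamples, per locus, alleles
  within populations when every population passes the
  homozygote-excess test at α = 0.05 there, genotypes otherwise
  (1,000 replicates).  Because data resampling adds apparent
  differentiation, the interval is the *recentred* (basic) percentile
  interval — without recentring the point estimate can fall outside
  its own CI.
- **Weir's θ** uses the standard multiallelic variance components
  combined as a ratio of sums over alleles and loci.  The **ENA**
  variant replaces observed frequencies with EM-corrected visible
  frequencies (null class excluded, renormalized) and the observed
  heterozygote carriage with its expectation under the fitted null
  model, 2q(1−q)·(1−r)/(1+r) — the expected *apparent* heterozygosity
  when a null at frequency r hides inside apparent homozygotes.  The
  plain HWE form 2q(1−q) would undo the het depression that the raw
  estimator's observed-het term carries and biases θ(ENA) upward by
  ~0.003–0.005 at F = 0.05, r = 0.2; the damped form is centred.
  A caveat the simulations make explicit: with a faithful null
  observation model, apparent allele spectra equal the conditional
  visible spectra exactly, so raw θ is itself nearly unbiased under
  uniform nulls and the ENA correction mainly trades estimator noise,
  not bias, at these parameter values.
- **G″_ST** is evaluated from over-loci averaged heterozygosities
  computed on null-corrected frequencies with the null class included
  as one allelic state; k = 2 for pairs (pair-specific H values, per
  the equation's definition of k), k = number of populations globally.
- **N_m** = (1 − G″_ST)/(4·θ_ENA); θ ≤ 0 yields the ∞ sentinel.
- F_ST CIs bootstrap loci (1,000 replicates, percentile); with only 7
  loci these intervals are wide, matching the published ones.

## Distances and spatial tests

Chord distances use the bounded (2/π)√2 convention; INA augments each
corrected visible vector with its null class so the null participates
as one shared allelic state, and with r̂ = 0 everywhere the INA and
plain matrices coincide exactly.  Mismatched allele universes are
unioned with zero frequencies.

Geographic distances are an *input* whenever real marine routes
matter; the built-in great-circle matrix (haversine, R = 6371.0088 km)
is a documented fallback, and all geography-dependent conclusions in
the tests are property-level for exactly this reason.  The habitat gap
is a binary indicator over a two-group partition of sites.

Mantel tests correlate upper triangles and permute the *predictor*
matrix (30,000 permutations by default); the partial variant uses the
first-order partial correlation and permutes the predictor
(Smouse–Long–Sokal).  One-sided p-values with the +1 correction.  On
4×4 matrices the permutation p matches exhaustive 24-permutation
enumeration within Monte-Carlo error (asserted in the tests).

SAShA locates every allele copy at its carrier's site; OM pools
same-allele pair distances across alleles and loci, EM is the
all-pairs mean per locus averaged with the same pooling weights
(same-allele pair counts), so OM and EM are directly comparable;
within-site pairs count at distance 0.  The null permutes allele
identities within loci (10,000 permutations); the two-sided p uses
|OM − EM| exceedance.  Singleton-only loci are skipped with a warning.

## Synthetic data generator

Population visible-allele frequencies are Balding–Nichols draws:
Dirichlet centred on an ancestral vector with concentration
(1 − F)/F, so the configured F is exactly what the estimators target
(F = 0 short-circuits to identical frequencies).  A two-species
mixture repeats the construction one level up at divergence
`f_species`.  One shared null allele per locus per species sits on top
with configurable per-locus × population frequency, plus an
independent per-genotype amplification failure.  Sites lie along a 1-D
coastline with an optional gap before the last site.

The study-scale preset uses 2 species × 4 sites with the study's
sample sizes, per-locus allele counts spanning 6–38, per-locus null
ranges of 0–0.30, an 8% amplification-failure rate (total missingness
lands at ~10–13%, inside the study's 9–17%), within-species F = 0.01,
between-species divergence 0.3, 12% habitat mismatch, and site
spacings 96/96/180 km (372 km span).

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: microsatellite mutation (no stepwise
homoplasy), linkage, population-specific sampling artefacts beyond
MCAR amplification failure, drift of the null allele itself (its
frequency is set, not evolved), and real marine-route geometry.

## Numerical conventions

- Allele labels are integer fragment sizes, opaque to all statistics
  except the size-difference diagnostic; Genepop output uses 3-digit
  coding.
- Half-called genotypes are rejected at parse time; a genotype is
  complete or blank.
- Sample SD (n − 1) in null-frequency summaries; a single value has
  SD 0 by convention.
- Permutation/bootstrap engines take explicit seeds everywhere;
  fixed-seed runs are bit-identical end to end (hashed-report
  determinism is a pipeline test).
- Populations with fewer than 10 assigned individuals are excluded
  from connectivity statistics (configurable), mirroring the study's
  exclusion of undersized samples.
- The "scored at ≥ 4 loci" filter is applied before assignment; the
  original ordering is not documented and this choice is flagged for
  sensitivity analysis.

## Known limitations

- The artefact diagnostic is underpowered at study-scale cell sizes
  (see above) and defaults to the null-allele verdict when fewer than
  four size-difference classes exist.
- θ(ENA)'s heterozygosity term is a model expectation, not data — a
  necessary approximation since null-corrected individual genotypes do
  not exist.
- Pairwise G″_ST uses pair-specific H values; a convention computing
  them from the global table would give slightly different pairwise
  values.
- The hybrid status of ambiguous individuals is out of scope: they are
  excluded, never modelled.
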