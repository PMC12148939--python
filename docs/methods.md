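# Methods

`evorepeat` re-implements, as a tested pipeline over synthetic data, the
statistical machinery of an evolve-and-resequence (E&R) repeatability
analysis of thermal adaptation: replicate selection lines from three
differentiated genetic backgrounds evolve at a cold (23 °C) or hot (35 °C)
regime, are pool-sequenced against ancestor proxies, and are phenotyped for
seven life-history traits at both assay temperatures.  This note documents
the models, the estimators, the numerical choices, and what the synthetic
experiments can and cannot establish about real data.

## Study design encoded in the generator

`ExperimentDesign` fixes the conditions every analysis assumes:

| parameter | default | meaning |
|---|---|---|
| backgrounds | Brazil, California, Yemen | differentiated source populations |
| replicates per cell | 2 | independent lines per background × regime |
| divergence generations | cold 60, hot 64 | proxy-adjusted time between samples |
| pool size | 60 diploids | individuals pooled for sequencing |
| mean depth | 50 reads | Poisson-distributed per SNP and sample |
| ancestor proxy generation | 3 | heat-line generation sequenced as "ancestor" |
| true Ne | cold 250, hot 180 | simulator's drift intensity per regime |

Because the direct ancestors were never sequenced, the generation-3 samples
of the two heat-adapting lines per background stand in for them.  Evolved
samples are therefore separated from their proxy by `nominal + 3`
generations for cold lines and `nominal − 3` for hot lines
(`adjust_generations`); lines are simulated to their nominal sampling
generations (57 cold, 67 hot) so the adjusted divergence times are exactly
60 and 64.  The per-regime true Ne defaults put stronger drift in the hot
regime, with a study-wide mean near 215 diploids — the scale at which the
whole analysis operates.

The ancestral pools are Balding–Nichols draws around a common uniform
frequency (F_ST-like `differentiation` parameter, default 0.05–0.1 in the
scenarios), discretised through a 300-diploid founder population.  The
discretisation is what produces differential fixation between backgrounds —
shared polymorphism plus private fixed differences — which the offset
analysis needs.  `differentiation` is exposed as a free parameter because
no among-background F_ST is available to anchor it.

Selection classes follow the pleiotropy taxonomy: synergistic (SP, same
sign in both regimes), antagonistic (AP, opposite signs), private-cold and
private-hot (one regime only), neutral.  The per-generation update is
`p' = p(1+s)/(1+ps)` followed by binomial drift over 2·Ne chromosomes; 0
and 1 are absorbing.  Loci are unlinked and sampled independently — the
drift null downstream is single-locus, so linkage, draft and epistasis are
deliberately out of scope, and nothing the tests show speaks to those
forces in real data.

Pool-seq noise is two-stage binomial: chromosomes into the pool
(`2 × pool size`), then reads (`depth`).  The resulting variance
coefficient `f = 1/(2n) + (1 − 1/(2n))/depth` is used consistently by the
Ne estimator.

Trait panels are linear-additive: each line's trait mean is an ancestral
baseline (with a ~3% multiplicative background deviation, so ancestors are
differentiated in trait space) plus `effects^T Δp` over its true frequency
changes, plus Gaussian measurement error whose standard deviation is also
the reported standard error.  Effects are identical at both assay
temperatures; assay-temperature-specific effects would refine the offset
scenarios but are not needed for any property tested.  Real trait data are
noisier in structured ways (block effects, missing cells) that the
generator does not emulate.

## Drift null and candidate detection

The classical null for a frequency moving from `p0` to `pt` in `t`
generations at effective size `Ne` is the beta approximation with
`F = 1 − (1 − 1/(2Ne))^t`:

    pt | p0 ~ Beta(p0(1−F)/F + 0.001, (1−p0)(1−F)/F + 0.001)

`drift_null_pvalue` implements exactly this, two-sided as
`2·min(CDF, 1−CDF)`.  It is accurate in the bulk but its tails deviate
from the discrete Wright–Fisher chain by up to ~30% relative at moderate
drift (measured against 10⁶-replicate simulations at Ne = 50, t = 20), and
it assigns zero tail mass to observed fixation, which the chain reaches
with percent-level probability in this parameter regime.

Candidate detection therefore uses a compound discrete null on the evolved
*read count* (`sampling_aware_pvalues`):

1. a flat-prior posterior over the `2Ne + 1` copy-number grid for the true
   ancestral frequency, given the ancestor pool's own read count through
   the two-stage sampling likelihood;
2. `t` generations of the exact neutral WF transition (binomial kernel
   raised to the t-th power; `drift_model="beta"` substitutes the beta
   kernel for comparison);
3. binomial pool sampling and binomial read sampling.

Discreteness is resolved by randomized tail probabilities (uniform within
the observed count's atom; `midp` and conservative `none` variants exist),
which makes null p-values uniform by construction.  Measured on 10⁶
neutral loci at Ne = 200, t = 60, pool 60, depth 50, the per-tail flag
rate matches q within three binomial standard errors at q = 10⁻², 10⁻³ and
10⁻⁴; the beta kernel in the same machinery is 1.3–1.7× inflated at the
extreme tails.  Randomization is seeded and reproducible.  The transition
matrices are cached per `(Ne, t, pool)`; the matrix power costs ~0.05 s at
2Ne = 400 and the per-locus work is grouped by distinct
`(r0, depth0, depth_t)` triples.

Two consequences of an honestly calibrated null are worth stating:

* a completed sweep's p-value saturates at the null's own absorption
  probability (1e-3 to 1e-1 depending on the starting frequency), so
  two-time-point data cannot rank "impossibly strong" selection below
  that floor, and candidate quantiles mix true sweeps with neutral
  extremes — the capture tests assert enrichment, not totality;
* alleles swept to *loss* from low frequencies are routinely produced by
  drift plus finite reads and are genuinely undetectable, which is why
  antagonistic pleiotropy — requiring four concordant significant tails —
  is rarely recoverable under the default conditions.

Thresholds: detection uses per-tail probability 10⁻⁴ (the
0.01th/99.99th-percentile criterion), class assignment the relaxed 10⁻²
(1st/99th).  The per-tail reading (rather than a doubled two-sided
threshold) is the default; both are exposed.

## Temporal Ne estimation

`estimate_Ne` computes the standardized variance
`F_c = (p0 − pt)² / (z(1−z))`, `z = (p0+pt)/2`, over ancestrally
polymorphic loci, subtracts the expected two-stage sampling contribution at
both time points, and inverts the cumulative drift formula.  Parameter
recovery on neutral pool-seq simulations (10⁴ loci, t = 60, pool 60, depth
50) is within ±5% across Ne ∈ {50, 100, 215.4, 500}, comfortably inside the
±15% contract.  The estimator assumes the loci are overwhelmingly neutral:
in synthetic scenarios where ~10% of loci carry |s| = 0.1, selection
inflates `F_c` and the genome-wide estimate drops well below truth.  Real
applications average over millions of SNPs, where this contamination is
negligible; the classification tests parameterize the null with the
scenario's known Ne for this reason.  When the corrected F is ≤ 0 the
estimate is flagged (`no_drift`) rather than inverted.

## Selection coefficients

The per-SNP coefficient is the logit slope
`s = (logit(p̃t) − logit(p̃0))/t` with frequencies clamped to
`[1/(20·pool), 1 − 1/(20·pool)]` (pooled data hit the boundary by sampling
alone; the clamp is flagged).  This is the exact inverse of the
deterministic selection update in the large-Ne limit and recovers
deterministic-trajectory coefficients within ±0.005.  It deliberately
ignores drift — the offsets only need |s| as a relative weight — and the
interface isolates it so a likelihood-based estimator can be slotted in.

## Change-vector geometry

Traits are mean-scaled by the ancestral grand mean per trait and assay
temperature, making rates proportional changes per generation.  Angles
between change vectors use the normalized (un-centered) dot product.
When two vectors were computed against the *same* measured ancestor, the
shared error inflates both the dot product (by `Σ se²`) and each squared
norm (by the same term).  The default correction removes the term from the
numerator and both norms; on 1,000-replicate simulations with a true 45°
angle and shared-error variance 10% of the signal, the corrected mean is
within 1° of truth while no correction biases low (~1.5°) and a
numerator-only correction biases high (+6°).  Numerator-only and
uncorrected variants remain available flags.  When a corrected squared norm
is non-positive, or the corrected cosine exceeds 1 beyond 10⁻⁶, the angle
is reported undefined ("error exceeds signal") — the analogue of the
inestimable within-background case in sparse real data.  Genomic vectors
(frequency changes on the candidate union set) use no correction, since
replicate ancestral pools are available per background.

Divergence is `E_d − S_d` with the shared-ancestor error term
`Σ(ae² + be²)` subtracted under the square root of `E_d` and floored at
zero (flagged); scaled divergence divides by the distance between the two
most differentiated ancestors.  The rotation invariance of `E_d − S_d` is
property-tested with random orthogonal maps.

The random-angle null draws isotropic unit vectors (normalized standard
normals); its 7-dimensional mean is 90° and lower dimensions are more
variable, as concentration of measure dictates.  The regime contrast
(hot − cold in mean pairwise angle, rate, or any custom pairwise statistic
such as a divergence closure) is tested by permuting regime labels within
each genetic background, with the (k+1)/(n+1) correction.  With 3
backgrounds × 4 lines only ~216 distinct relabelings exist, so attainable
p-values bottom out near 1/108 — tests and users should not expect
p < 0.01 from this design.  The stratified scheme is a design choice:
exchanging labels across backgrounds would conflate regime effects with
background history.

## Classification and overlap

A regime "hit" requires both replicate lines beyond the class threshold
with the same direction; SP/AP/private/None assignment follows from the
two regimes' hits and is mutually exclusive by construction.  Relabeling
cold↔hot everywhere maps the private classes onto each other and fixes
SP/AP (property-tested).  Under neutrality the per-regime concordant-hit
rate is 2q² as expected.  Genes inherit classes from the SNPs inside their
annotated gene body (1-based inclusive GFF3 intervals; an exon-resolved
CDS mode exists); a gene can appear in several classes only via distinct
SNPs, and a gene containing both private-cold and private-hot SNPs counts
in both sets.  Cross-background repeatability is summarized by upset-style
exclusive intersection counts and Jaccard indices.

The drift expectation for cross-background sharing re-simulates the whole
design neutrally: each iteration draws the same random loci for every
background from the ancestral frequencies, evolves each line at its own
(Ne, t), applies pool-seq sampling and the same classifier, and counts
loci assigned the focal class in all backgrounds; `p = (k+1)/(n+1)`.  Ne
is fixed per line across iterations.  Defaults are 1,000 iterations ×
10,000 loci; the bundled analysis driver runs 200 × 2,000, which already
bounds p below 0.005 when the observed sharing is far outside the null.

## Offsets

The reference line per background × regime is the replicate with the
highest laboratory fitness (lifetime offspring per couple / egg-to-adult
days — a proxy for the intrinsic growth rate) at its own temperature; ties
break lexicographically and are flagged.  The reference's candidate set is
the smallest `offset_quantile` (default 0.001) of its *empirical* p-value
distribution, ties included and flagged — distinct from the parametric
per-tail detection rule; both semantics are explicit in the config.  Each
candidate SNP carries the reference's |s| as weight.

* genomic offset: `Σ |p_ref − p_test| · |s_ref|` (a weighted L1 metric —
  symmetry and triangle inequality are property-tested);
* phenotypic offset: Euclidean distance in the seven mean-scaled traits at
  one assay temperature (hot, 35 °C, is the primary surface);
* fitness offset: test fitness / reference fitness.

Ancestor pseudo-lines enter as test points with the mean frequency of the
background's two ancestor pools.  Random-SNP controls redraw equally-sized
loci sets with unit weights (no s is defined off the candidate set — a
documented divergence from candidate weighting).  Correlations are pooled
per group (within/between background) and the group contrast is tested by
OLS `offset ~ genomic × group` with the interaction F — the covariance-
adjusted comparison — rather than comparing correlation coefficients.

The qualitative contrast — genomic offsets predictive within but not
between backgrounds — is established on a scenario with strictly
background-private heat-selected loci (each background's selected alleles
fixed absent elsewhere, selected alleles raising LRS and shortening
development time).  A single 42-line experiment yields a between-background
r with a seed-to-seed standard deviation of ~0.2–0.3, so the acceptance
test averages |r| over four scenario replicates; the within-background
correlation is strong (|r_Fit| ≈ 0.98) and stable.

## Recoverability of planted classes

For the classification-recovery contract, a planted SNP counts as
*recoverable* when, in every replicate its class requires, the idealized
observation of its true frequency change — reads exactly proportional to
the true frequency at the design depth — has a per-tail probability below
q/5 under the sampling-aware null.  The factor 5 covers the dispersion the
two actual sampling stages add around the idealized observation; the
definition is fixed once and documented here.  Under the default
conditions ≥ 90% of recoverable planted SNPs receive their correct class,
SP↔AP confusion is below 1%, and AP is rarely recoverable at all (four
concordant tails, one of which usually points into the absorbing
boundary) — consistent with antagonistic pleiotropy being the hardest
signal for this design to certify.

## Reporting utilities

`rolling_log10p` produces Manhattan-style tracks: rolling means of
−log₁₀ p over 20-SNP windows that never span scaffolds, centred on the
middle SNP, with the upper 0.1% quantile of window means returned as the
outlier threshold (the "0.001th quantile" line, read as the top of the
−log₁₀ p track).

## Problem sizes and determinism

Bundled analyses run 20,000 SNPs × 18 samples end to end in under a
minute; the calibration check uses 10⁶ loci (~15 s); the acceptance script
simulates 10⁴ loci.  Every stochastic step derives from one master seed
via `SeedSequence` spawning, per line and stage, so identical configs
reproduce every artifact byte for byte; the summary JSON is written with
sorted keys for the same reason.

## Known limitations

* Single-locus theory throughout: no linkage, draft, or epistasis in
  either the generator or the null.
* The plug-in null conditions on the observed ancestor frequency through
  a flat-prior grid posterior; a strongly informative genome-wide
  frequency spectrum would sharpen it slightly.
* The logit-slope s ignores drift and compresses at the clamp boundary.
* Trait effects are additive and temperature-constant; the offset
  scenarios encode local adaptation through private polymorphism rather
  than genotype-by-environment interaction.
* The Ne estimator assumes neutrality of the bulk of loci (see above).
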