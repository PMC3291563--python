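# Methods

`xqtlscan` implements a differential extreme-QTL (X-QTL) analysis for
*S. cerevisiae* BY × RM crosses: it detects **readthrough-dependent
loci** — genomic regions whose allele-frequency response to selection
differs between a wildtype cross and a cross in which both parents carry
a partial loss-of-function allele of the release factor gene *SUP35*
that elevates stop-codon readthrough — together with the quantifications
that surround such an experiment (growth-rate ratios from plate-reader
OD600 curves, percent readthrough from dual-luciferase reporters, and a
2×2×2 factorial growth model).  Everything runs end to end on synthetic
data with known ground truth; this note records the models, the
defaults, and the design decisions, including what the synthetic data do
and do not establish about real arrays.

## 1. Synthetic segregant pools and selection

**Genome.** The default synthetic genome has 16 chromosomes of 750 kb
(12 Mb total) carrying 18,000 markers placed uniformly — the marker
density of the allele-specific genotyping array used for BY/RM X-QTL.
Alleles are coded 1 = BY, 0 = RM.

**Meiosis.** Each haploid segregant chromosome starts from a fair-coin
parental allele and receives `Poisson(r)` crossovers at positions
uniform in bp, with no interference.  The default `r = 2.9` crossovers
per chromosome per meiosis reproduces the ~4,400 cM yeast genetic map
spread over 16 chromosomes (≈0.37 cM/kb on this genome).  Real
chromosomes vary 4-fold in length and recombination is non-uniform;
neither matters for the pipeline's statistics, which only see marker
coordinates.

**Selection.** One round of sampling without replacement with
probability proportional to multiplicative fitness: a BY carrier at a
QTL of effect `e` gets factor `1 + e`, an RM carrier `1 − e` (so
`|e| < 1`).  Sampling is implemented exactly (Gumbel top-k, the
Plackett–Luce construction).  This stands in for two days of
competitive plate growth, which is not modelled mechanistically.  A
caveat that matters for oracle tests: the fitness-weighted allele
frequency equals the expected post-selection frequency only in the
small-surviving-fraction limit; at a 40% surviving fraction the
without-replacement draw measurably shrinks skews toward 0.5 (≈0.05 in
frequency at effect 0.5).  Defaults use 2,000 survivors from pools of
10,000 segregants.  The real experiment's plating densities are
unknown, so pool and survivor counts are free parameters.

**Arrays.** Each marker has a BY-specific and an RM-specific probe; the
sample channel is proportional to the pool's BY (resp. RM) allele
frequency and the reference channel — a BY/RM diploid common to all
hybridizations — to 0.5.  Noise, all multiplicative on the log10 scale:

| parameter | default | meaning |
|---|---|---|
| `affinity_sd` | 0.3 | per-probe affinity shared by both channels (sequence effects; cancels in sample/reference ratios) |
| `noise_sd` | 0.1 | per-probe measurement noise on the sample channel; a skew value then carries sd √2·`noise_sd` |
| `dye_bias` | 0.0 | one global log10 offset on the sample channel (Cy3/Cy5 imbalance) |

Frequencies are clipped to `[1e-3, 1 − 1e-3]` so intensities stay
positive.  Not emulated: spatial artifacts, probe saturation,
cross-hybridization, and intensity-dependent (banana-shaped) dye bias —
so passing tests show the pipeline's statistics are correct under a
clean multiplicative noise model, not that the normalization would
fully tame a particular scanner.

## 2. Skew tracks

Per array, intensities are normalized by **rank-invariant scaling**: all
probes whose intensity rank differs between sample and reference
channels by less than 2% of the probe count (excluding 2.5% tails) form
the invariant subset, and the geometric-mean reference/sample ratio on
that subset rescales the sample channel.  A pure dye bias is removed
exactly.  The proprietary feature-extraction normalization used on the
original arrays is not reproducible; this documented substitute removes
exactly the structure the generator plants.  Non-positive intensities
are floored to the smallest positive observed value (logged); more than
50% non-positive is an error.

The **skew** at a marker is
`log10(sample_BY/ref_BY) − log10(sample_RM/ref_RM)` — positive means
BY-enriched.  Ratios against the common reference are used (rather than
raw sample intensities) so probe-affinity effects cancel; this is an
interpretation choice, flagged here, since the original description
does not state which variant was computed.  Missing probes become NaN
gaps that propagate and are excluded, never imputed.  Pool-construction
artifacts are removed by subtracting the unselected (control)
population's track from the selection track, marker-wise.  40-kb
sliding-window means (closed windows centred on each marker, never
crossing a chromosome boundary) reproduce the plotted representation.

## 3. The differential scan

The scan input is `mean(sup35 selection replicates) − mean(wildtype
selection replicates)` of background-subtracted tracks (2 replicates
per cross by default; any count is accepted).  A locus that affects
growth independently of readthrough skews both crosses equally and
cancels; a readthrough-dependent locus survives the difference.

**Smoothing.** Savitzky–Golay filtering = local least-squares
polynomial regression evaluated at each marker, order 3, window 101
probes (the nearest odd size to 100; both configurable), per
chromosome, in probe-index units, skipping gaps.  Interior points use
the closed-form SG convolution weights; points within half a window of
a chromosome end are fitted on the truncated one-sided window, so the
output equals brute-force local regression everywhere (tested to
1e-10).  Order 3 preserves local maxima, which is the point of using SG
rather than a moving average.

**Edge margin in calling.** The truncated one-sided fits at chromosome
ends are extrapolative: at standard noise their sd is ≈0.11 versus
≈0.02 in the interior.  Left unguarded, the empirical-FDR threshold is
set by the 32 chromosome-end spikes of the null track and interior
power collapses (planted-QTL recovery dropped to 75%).  Locus calling
and false-discovery counting therefore exclude a half-window margin
(50 probes ≈ 33 kb) at each chromosome end, identically on null and
observed tracks.  Smoothed values in the margin are still computed and
reported; they are just not eligible for calls.

**Empirical FDR.** Candidate thresholds are 200 even grid values from 0
to 1.1× the (margin-excluded) maximum |null smoothed value|.  The null
differential is built exactly like the observed one but from the
matched rich-medium (YPD) experiment.  For each threshold `t` the
calling algorithm runs on the null track (false discoveries `f(t)`) and
on the observed track (`r(t)`); the chosen threshold is the smallest
`t` with `f(t)/max(1, r(t)) ≤ 0.05`.  Discoveries are counted as loci
by default; marker counting is selectable (`units="markers"`).  Note
that locus counts can be locally non-monotone in `t` when a run
fragments into pieces farther apart than the merge gap; marker counts
are strictly monotone.

*What this calibration does and does not control.*  With a single null
realization the chosen threshold is, on null data, essentially the null
track's maximum.  The observed and null maxima are exchangeable there,
so a QTL-free scan still produces ≥1 (false) call with probability ~1/2
— measured 50% over replicate simulations.  The procedure guarantees
that the *estimated* FDR at the chosen threshold is ≤ the target, and
it ranks and thresholds real signal sensibly when signal exists; it is
not a family-wise error control, and a single control experiment cannot
make it one.  Users who need a conservative null should average several
independent control experiments or raise the target quantile
explicitly.

**Locus calls.** Contiguous same-sign runs of |smoothed| ≥ threshold;
runs on one chromosome with equal sign separated by < 50 kb merge (the
merge gap is a package choice; no rule was published); the peak is the
marker of maximal |value|, ties leftmost.  Calls export as BED6
(0-based, score = scaled peak value, strand = skew direction) and a
full-field TSV.

**Confirmation t-test.** Welch's two-sample t-test on a moving window
of 6 consecutive probes, pooling replicates × probes per arm
(12 vs 12 values at 2 + 2 replicates), with Bonferroni correction.  The
divisor defaults to the number of windows actually tested
(≈ markers − 5 per chromosome); the printed constant 2.78e-6
(= 0.05/18,000) is available via `n_tests=18000`.  Windows with zero
variance in both arms get p = 0 (means differ) or 1 (equal), logged.
Power note, derived from the noise model: at array noise 0.1 the
expected Welch t for an effect-difference-0.4 QTL is ≈4.5 (p ~ 1e-4),
short of Bonferroni; at noise 0.05 it is ≈9 and both methods call the
locus.  The t-test is a confirmation scan for strong loci, not a
substitute for the smoothed scan.

## 4. Growth rates and ratios

Rates are the OLS slope of ln(OD600) versus time over readings with
0.05 < OD < 0.5 (natural log, so units are 1/h; the log base cancels in
every ratio).  At least 4 in-window points are required; fewer is a
flagged failure.  The generator produces logistic curves
`OD(t) = K·od0·e^{rt}/(K + od0(e^{rt} − 1))` sampled every 30 min for
20 h with additive Gaussian noise (sd 0.003; plate-reader noise is
approximately absolute at low OD), defaults `od0 = 0.02`, `K = 1.2`.

A quantitative caveat: with `K = 1.2` the fitting window tops out at
OD = 0.42·K, where the instantaneous log-slope is already 0.58·r; the
OLS estimand over the window is 0.84·r (0.336/h for r = 0.4/h), a
deterministic ~16% shortfall that no amount of replication removes.
The tests assert this verified estimand.  The bias is common to every
strain measured the same way and cancels in the growth-rate ratio,
which is the quantity the analysis actually uses.

The **growth-rate ratio** for a strain background and condition is
`mean(sup35 rate)/mean(wildtype rate)` after normalizing each genotype
by its own mean YPD rate.  Replicate-level ratios (each sup35
measurement over the wildtype mean — the mean-denominator convention;
pairing of individual wells was not published) feed Welch t-tests of
BY versus RM per condition; dispersion is delta-method propagated from
replicate SDs; estimates with fewer than 8 measurements or 4 biological
replicates are flagged, not dropped.  A one-sample t-test against 1
expresses "ratio not different from one" in rich medium.

**Multiple testing** uses Storey q-values: `pi0` estimated as
`#{p > λ}/(m(1 − λ))` on λ = 0.05…0.90, smoothed with a cubic spline
and read at the largest λ, clipped to (1/m, 1]; fewer than 20 p-values
force the conservative `pi0 = 1`.  Then
`q(p_(i)) = min_{j≥i} pi0·m·p_(j)/j`, monotone and capped at 1.  The
reported FDR at the p < 0.05 gate is a q-value readout, not a hard
filter.

## 5. Dual-luciferase readthrough

Percent readthrough = 100 × mean(stop-construct firefly/Renilla ratios)
/ mean(sense-construct ratios), after subtracting the mean no-lysate
blank from every signal.  Per-replicate ratios are averaged
(mean-of-ratios) because independent per-assay values exist and carry
the reported dispersion (SD of the per-replicate stop ratios on the
percent scale).  Replicates whose Renilla signal does not exceed the
blank are dropped with a flag; firefly signal at or below blank clamps
to 0 (zero readthrough), keeping the estimate non-negative.  The
estimate is invariant to separate global rescalings of all firefly and
all Renilla readings.

## 6. Factorial growth model

Growth rate (YPD-normalized) is modelled by OLS on the full 2×2×2
factorial of genetic background × SUP35 allele × SKY1 allele with all
interactions — 8 coefficients.  Treatment coding uses RM background,
mutant SUP35 and RM SKY1 as references, so the contrasts read
"BG (BY)", "SUP35 (WT)", "SKY1 (BY)" and their products, matching the
conventional R `lm` presentation of such designs.  The design matrix is
built explicitly (no formula machinery) and rank-checked; empty cells
raise an error naming the cell.  On a balanced design the fit
reproduces cell means exactly.

The mRNA-residualized variant first regresses rate on the relative SKY1
mRNA level (intercept + slope; the covariate enters linearly on the
measured scale — a log transform was considered and left configurable)
and refits the factorial model on the residuals.  A constant covariate
degenerates to centring, flagged.  The underlying qRT-PCR
quantification is out of scope; only the relative mRNA level enters.

## 7. Problem sizes and determinism

Every generator takes a seed (or a shared `numpy` Generator) and is
bit-reproducible.  The test suite runs its end-to-end scans on a
reduced genome (3,200 markers, 16 chromosomes) with the full-scale
scenario (18,000 markers, 10⁴ segregants, noise 0.1) reserved for the
recovery tests; `scripts/acceptance.py` re-runs the full-scale scan, an
8-replicate recovery experiment, and the oracle cross-checks, writing
its numbers as JSON.  These sizes were chosen so the whole analysis
re-runs comfortably on a laptop-class single core.

## 8. Known limitations

- No diploid phase, no sequence-level simulation, no [PSI+] prion
  aggregation dynamics — readthrough enters only through cross-specific
  selection effects.
- One selection round stands in for continuous competitive growth;
  effect sizes are selective advantages per round, not growth-rate
  differences.
- The empirical-FDR calibration inherits the single-null-realization
  limits described in §3.
- No spatial array QC; the normalization removes a scalar dye bias
  only.
- Real deposited arrays (the study's GEO series) are not reprocessed
  here; the pipeline's file formats accept such data, but all
  quantitative guarantees in the tests refer to the synthetic noise
  model.
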