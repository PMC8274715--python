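# Methods

## The measurement model

The unit of observation is one synapsed bivalent (SC) traced at pachytene:
its arc length L (μm) and the ordered positions of its crossover-fated foci
along the trace. Two conventions are fixed throughout:

* **Orientation is arbitrary.** Traces start at whichever telomere the
  microscopist picked, so every statistic must be invariant under
  x ↦ L − x per SC. CoC distances and adjacent gaps are; the test suite
  asserts this by reversing whole cohorts.
* **Coincident focus centers are invalid.** Each focus center is traced
  individually; two identical coordinates indicate a digitization error and
  are rejected at load time rather than merged.

Per-nucleus totals (focus count, summed SC length) are computed only on
complete 7-SC nuclei; partial nuclei are retained for per-SC analyses (CoC,
gaps) and counted separately.

## Crossover placement: stationary gamma renewal

Inter-crossover distances under interference are modeled as i.i.d.
gamma(ν, θ) gaps, ν ≥ 1, θ = μ/ν, μ the mean gap. ν = 1 is the
no-interference Poisson limit; larger ν gives more even spacing. Placement
on [0, L] starts in equilibrium: the first event lies at a distance drawn
from the forward-recurrence density g(x) = (1 − F(x))/μ, whose CDF has the
closed form

    G(x) = x (1 − F_ν(x)) / μ + F_{ν+1}(x),

with F_a the gamma CDF. Sampling inverts G on a cached 4096-point grid in
units of θ (one grid per ν, exact scale equivariance). The stationary start
makes event density position-independent and E[count] = L/μ exactly — the
property the calibration rests on.

**Obligate crossover.** When enabled, an SC drawn with zero events is
rejected and resampled wholesale (cap 10,000 per SC, then an error advising
a parameter change). Rejection slightly inflates the realized mean count;
at the bundled presets' densities the inflation is ≤ 0.35 foci per nucleus
(measured at 2,000 nuclei), far inside the calibration bands, so the mean
gap is not adjusted for it.

**Chromosome lengths.** Seven per-chromosome means in the fixed proportions
1.30 : 1.17 : 1.00 : 0.95 : 0.90 : 0.85 : 0.83 (summing to 7; a package
convention — the source cohorts only establish that the chromosomes are
distinguishable by length). Length noise is independent per chromosome,
Normal(mean_c, sd) with sd = (per-nucleus total SD)/√7 so the per-nucleus
total reproduces the published SD. Draws are clipped at 20% of the mean;
clipping was chosen over resampling because at the presets' noise levels
resampling visibly inflated the mean (+0.5 μm per nucleus for the dcl1
preset) while clipping perturbs it by < 0.2 μm.

**Presets.** Each preset encodes one published cohort: its gamma shape ν,
mean ± SD of total SC length, mean focus count, and nucleus count
(wt: ν 5.03, 52.9 ± 4.5 μm, 22.6 foci, 98 nuclei; dcl1: 2.40, 75.2 ± 9.0,
31.5, 29; dcl2: 4.01, 56.1 ± 4.6, 24.9, 21; qde2: 4.28, 58.1 ± 4.7, 25.1,
31). The mean gap is μ = total length / focus count. All genotype presets
enforce the obligate crossover, as observed in every scored bivalent of
those cohorts; `poisson-null` (ν = 1, obligate off) is the negative
control. One root seed spawns per-nucleus child streams, so cohorts are
bit-reproducible and order-independent.

## Coefficient of coincidence

Intervals are defined per SC in *relative* coordinates — n equal intervals
of that SC — and occupancy is binary (≥ 1 focus; multiplicity within an
interval is ignored, matching the "SCs with a crossover in both intervals"
counting convention). For each unordered pair (i < j) over N SCs of a
chromosome class, observed = #{both occupied}/N, expected = f_i · f_j, and
CoC = observed/expected. Pairs with expected = 0 carry no information and
are withheld (their count is reported, so sparse cohorts are diagnosable)
rather than mapped to 0 or ∞.

Because chromosomes of different lengths are pooled within a class, a
pair's physical distance is reported as (j − i) × (class mean SC
length)/n — an explicit convention, since pooling heterogeneous lengths
admits no exact answer. The binned curve averages CoC over pairs falling in
each distance bin (default bin width: one interval width).

The default interval count follows the quarter rule: the smallest n such
that (class mean length)/n is strictly below a quarter of the class mean
inter-focus gap, floored at 2. The rule bounds interval width from above;
finer partitions are legitimate and are used where well-populated distance
bins are needed.

Two properties of the pooled-class convention are worth knowing. First,
relative intervals on SCs of unequal lengths induce a slight positive
co-occupancy (longer SCs have wider intervals, hence higher occupancy in
*both* intervals of a pair): a no-interference cohort with the presets'
length spread reads CoC ≈ 1.05 rather than 1.00 when all chromosomes are
pooled. Grouping into long/short classes keeps this small. Second, with
binary occupancy, very coarse partitions blunt short-range interference;
the quarter rule exists to prevent this.

## Gamma-shape estimation

The two-parameter gamma MLE (location fixed at 0) is computed on pooled
inter-adjacent gaps; fewer than 10 gaps is an error. Gaps can be pooled in
μm or as percent of their own SC's length (default for heterogeneous real
cohorts, where percent normalization removes between-SC scale differences).
The shape is scale-free within an SC, so the choice only matters across
SCs.

Bootstrap SEs resample *nuclei* with replacement (default 1,000 resamples
in the CLI, 200 minimum in the library default), preserving within-nucleus
correlation; resampling individual gaps would understate the SE.

**Censoring bias and the recovery experiments.** Only gaps with both
endpoints observed on the SC enter the fit, which under-samples long gaps
near SC ends and biases ν̂. A pre-study at the presets' densities (20
replicate seeds per regime, `recover` machinery) measured the bias:
μm-pooled fits on fixed-length cohorts run +3% to +5% (wt +3.4%, dcl1
+3.2%, dcl2 +4.5%), with single-replicate errors up to 11%. The recovery
experiments therefore use fixed chromosome lengths and μm pooling — with a
single generating scale θ the pooled sample is a pure gamma, whereas
percent pooling would reintroduce a seven-component scale mixture through
the unequal chromosome lengths — and the recovery tolerance is 15%,
covering bias plus replicate noise without being met trivially.

## Group comparisons

"Brown–Forsythe ANOVA" names two different tests in the literature; since
the use case here is comparing *means* followed by mean-comparison post
hocs, the implemented F* is the means-under-heteroscedasticity version,

    F* = Σ nᵢ(x̄ᵢ − x̄)² / Σ (1 − nᵢ/N) sᵢ²,

with k − 1 numerator df and Satterthwaite denominator df (for two groups
F* = t²_Welch exactly, verified numerically). The median-centered Levene
test is provided separately for variance comparisons.

Games–Howell refers q = |Δx̄|/√((sᵢ²/nᵢ + sⱼ²/nⱼ)/2) to the studentized
range (k groups, Welch df per pair); it is cross-checked against an
independent implementation (pingouin) to 3 decimals. Dunnett T3 refers
|t| to the studentized maximum modulus with m = k(k−1)/2, computed by
numerical integration of P(M ≤ x) = ∫ (2Φ(xs) − 1)^m f_χ(s) ds; adjusted
p-values are accurate to about 2 decimals (for m = 1 the law reduces to
the two-sided t, verified). Focus counts are treated as approximately
normal; no count-model alternative is offered.

## What the simulator does and does not emulate

It emulates: seven chromosomes of unequal length; genotype-specific total
SC length (mean and SD) and focus density; spacing evenness via ν; the
obligate crossover. It does **not** emulate: within-nucleus correlation of
SC lengths (lengths are independent across chromosomes, so covariation of
per-nucleus totals with counts is weaker than in real nuclei); two-pathway
(interfering + non-interfering) crossover mixtures; centromere effects or
any positional non-uniformity; measurement error in tracing. Passing
recovery tests therefore shows the estimators are correct for a
single-pathway stationary renewal world at realistic densities — not that
real cohorts satisfy those assumptions.

## Numerical and interface choices

* Equilibrium inversion grid: 4,096 geometric nodes to the 1e−14 tail
  quantile; monotonicity guarded against floating-point plateaus.
* A focus exactly at position L falls in the last interval; positions are
  validated to [0, L] with strict increase.
* Result tables are TSV with fixed %.6g floats (byte-stable); focus-map
  tables use shortest-repr floats so write → read round-trips to an
  identical in-memory cohort.
* CLI exit codes: 0 ok, 1 usage, 2 validation, 3 runtime; every run writes
  a key-value manifest with parameters, seed and package version.
* Problem sizes in the validation suite (≈ 100–300 nuclei per simulated
  cohort, 1,000 replicates for the type-I-error and Welch checks, 200 for
  the ANOVA power check) were chosen so each check's Monte-Carlo error is
  several times smaller than the tolerance it guards.

## Known limitations

* The censoring bias of the gap-based gamma MLE is characterized, not
  corrected; a boundary-censored likelihood would remove it but would no
  longer be the conventional estimator this package mirrors.
* The pooled-class CoC distance convention (class mean interval width) is
  one defensible choice among several; curves from cohorts with very
  heterogeneous lengths should be read with the ≈ +0.05 pooling offset in
  mind.
* Percent-of-SC-length gap normalization treats each SC's length as exact;
  tracing error propagates into the gaps undamped.
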