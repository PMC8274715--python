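# meioco

Crossover-interference analysis of cytological focus maps.

During meiotic prophase, crossover-fated recombination sites are visible as
discrete foci (e.g. of the E3 ligase Hei10) along the synaptonemal complex
(SC) of each bivalent. Because crossover interference makes nearby double
crossovers rare, the spatial statistics of these foci — how evenly they are
spaced, how often two intervals carry a focus simultaneously — quantify the
strength of interference. `meioco` is for cytogeneticists who have traced
SCs and digitized focus positions (genotype, nucleus, chromosome, SC length
in μm, ordered focus coordinates in μm) and want the standard downstream
analyses, plus a calibrated generative model to test them against.

## What it computes

**Coefficient of coincidence (CoC).** Each SC is cut into *n* equal
intervals (*n* chosen so the interval width is below one quarter of the
mean inter-crossover distance). For an interval pair (*i*, *j*),

&nbsp;&nbsp;&nbsp;&nbsp;CoC(*i*, *j*) = f(*i* ∧ *j*) / [f(*i*) · f(*j*)],

the frequency of SCs with a focus in both intervals over the frequency
expected under independence. Plotted against inter-interval distance
(center to center), CoC ≪ 1 at short range is the classical interference
signature; the curve rises to ≈ 1 where crossovers occur independently.
Curves are computed for the two long chromosomes (1–2), the five short ones
(3–7), and pooled.

**Gamma-shape fitting.** Inter-adjacent focus distances are pooled and a
two-parameter gamma distribution is fitted by maximum likelihood. The shape
ν measures spacing evenness: ν = 1 is a Poisson process (no interference),
larger ν means more even spacing. Standard errors come from a bootstrap
that resamples nuclei, not individual gaps.

**Cohort statistics.** Per-nucleus focus counts and total SC lengths, the
obligate-crossover check (every bivalent ≥ 1 focus), crossover-count versus
SC-length regression, and heteroscedastic group comparisons: Brown–Forsythe
ANOVA (the means-under-unequal-variances F\*), Games–Howell and Dunnett T3
post hoc tests, Welch t.

**Simulator.** A stationary gamma-renewal process places crossovers along
simulated SCs: gaps are gamma(ν, θ) with θ = μ/ν, and the first event is
drawn from the equilibrium forward-recurrence density (1 − F(x))/μ, so
event density is position-independent and the expected count per SC is
exactly L/μ. Obligate crossovers are enforced by rejection. Bundled presets
(`wt`, `dcl1`, `dcl2`, `qde2`, `poisson-null`) reproduce published cohort
summaries of *Sordaria macrospora* wild type and RNAi-pathway mutants.

## Worked example

```python
import meioco as m

params = m.preset_params("wt", seed=42)          # 98 nuclei, wild-type-like
cohort = m.simulate_cohort(params, "wt")

s = m.summarize(cohort)
print(f"foci/nucleus: {s.mean_focus_count:.1f} +/- {s.sd_focus_count:.1f}")
print(f"total SC length: {s.mean_total_sc_length_um:.1f} +/- {s.sd_total_sc_length_um:.1f} um")

fit = m.fit_gamma_cohort(cohort, normalization="um", n_bootstrap=200, seed=0)
print(f"gamma shape nu: {fit.shape_nu:.2f} +/- {fit.se_nu:.2f} (n={fit.n_gaps} gaps)")

curve = m.coc_curve(m.coc_pairs(cohort, "all"))
print(curve.binned.head(4).to_string(index=False))
```

prints

```
foci/nucleus: 22.6 +/- 3.1
total SC length: 52.7 +/- 4.3 um
gamma shape nu: 5.19 +/- 0.20 (n=1531 gaps)
 bin_center_um  mean_coc  n_pairs
      0.753541  0.205810       14
      1.255902  0.638653       13
      1.758263  0.945537       12
      2.260624  1.180866       11
```

The simulated wild-type cohort averages 22.6 foci over 52.7 μm of SC per
nucleus; the fitted ν ≈ 5.2 recovers the generating shape (5.03, within the
estimator's censoring bias), and the CoC curve shows the expected strong
suppression below ~1 μm rising through 1 by ~2 μm.

The same pipeline runs from the shell on focus-map tables (CSV/TSV with
columns `genotype, nucleus_id, chromosome_id, sc_length_um,
focus_positions`, the last a `;`-separated μm list):

```
meioco simulate --preset wt --seed 42 --out-dir run/
meioco gammafit --input run/wt_focus_map.tsv --out-dir run/
meioco coc --input run/wt_focus_map.tsv --chrom-class all --out-dir run/
meioco summarize --input run/wt_focus_map.tsv --out-dir run/
meioco recover --preset dcl1 --seed 1 --out-dir run/
```

Every command writes TSV result tables plus a `manifest.txt` (parameters,
seed, package version) sufficient to re-run it bit-identically.

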