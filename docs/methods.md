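# Methods

## Growth model

Tumors are modelled as spheres whose volume grows exponentially, so that the
volume doubles every TVDT days and the diameter follows
d(t) = d(0)·2^(t/(3·TVDT)). The inversion used for estimation is
TVDT = ln2·Δt/(3·ln(d₂/d₁)), written so that a growing tumor yields a
positive doubling time. Exponential growth with a spherical shape is the
standard choice for the tumor sizes seen in mammographic screening
(roughly 5–35 mm); sigmoidal (Gompertz-type) laws matter mainly outside that
range and are deliberately not implemented.

Degenerate measurements are first-class outcomes, not silent drops: equal
sizes at the two rounds map to a *no-growth* sentinel (infinite doubling
time), a smaller later size to a *shrinkage* sentinel (or, with the
`shrinkage="signed"` policy, a negative halving time). Downstream analyses
exclude sentinels pairwise and report the exclusion count.

Screening intervals are 18 months for ages 40–54 and 24 months for ages
55–74, converted at 365.25/12 days per month by default (18 mo ≈ 547.9 d,
24 mo ≈ 730.5 d); a `month_length` option provides the simpler 730/548-day
convention. The worked 24-month projection of a 4.0-mm tumor with TVDT
317 d gives 6.8 mm under either convention.

## Clinical fit of TVDTs

Clinical doubling times are strictly positive and right-skewed; they are
represented by a gamma distribution with the location fixed at zero. The
canonical "clinical fit" is built from published summary moments
(mean 297 d, SD 169 d) by moment inversion — shape = μ²/σ² ≈ 3.0884,
scale = σ²/μ ≈ 96.16 d — because the underlying raw values are available
only as a histogram. When raw values are supplied, maximum-likelihood
fitting is the default (`fit_distribution`); whether the original fit used
ML or moments is not documented, so both are provided.

Family selection uses the Anderson–Darling A² statistic against the fitted
CDF with a **parametric bootstrap** p-value (default 1000 replicates,
parameters re-estimated per replicate). Tabulated AD critical values assume
fully specified parameters; with estimated parameters they would be
anti-conservative, hence the bootstrap. The A² computation is implemented
directly (the standard sorted-sample form) because no installed routine
covers the gamma family with estimated parameters.

## Virtual cohort

Each of n patients (default 30) draws: a TVDT from the clinical fit; an age
uniform on [40, 74] (an empirical age table can be supplied instead — the
age distribution only matters through the 18/24-month interval split); a
first-round diameter uniform on 3.5–13 mm, just below the reported range of
clinically detectable lesions so that the second round lands in a
clinically relevant range; breast volume uniform on 450–950 mL and percent
dense compartments uniform on 5–60% as metadata; and a lesion location
uniform in a normalized unit cube (metadata only — location affects a
rendered phantom, not growth). The second-round diameter follows
deterministically from the growth law, so the noise-free cohort round-trips
its assigned TVDTs exactly. Tumors exceeding palpable size (> 20 mm) at the
second round are flagged but retained: interval cancers are deliberately
not simulated, which slightly truncates the fast-growing end of what a real
screening population would present.

## Observer model

The simulated radiologist reads each tumor twice per round (the "largest"
and the "orthogonal" direction) in three repeated sessions. Because the
tumors are spheres, both directions see the same true diameter; the two
sizes are i.i.d. reads

    size = round₀.₁(true_d + bias + N(0, sd)),

truncated below at 0.1 mm. Defaults: bias 0, **sd 0.5 mm per direction**.
The intrareader error magnitude of a human reader is not published — only
its downstream consequences — so the sd is an explicit tunable chosen so
that the measured-vs-true size regressions behave like published reader
data (slope ≈ 1, second-round R² above first-round R²); it is a model
parameter, not a clinical fact. Each session consumes an independent
substream spawned from one seed, so the Friedman null across sessions holds
by construction. The mean of the two sizes per round enters the growth-law
inversion to give per-patient, per-session estimated TVDTs.

## Lesion patch surrogate

`patch.py` is a lightweight 2-D surrogate of a full VCT imaging chain: the
projection of a sphere contributes intensity proportional to the chord
length, s(ρ) = √(r²−ρ²)/r for ρ ≤ r, sampled at mammographic pixel pitch
(0.07 mm) on an isotropic 1/f^β power-law texture (β = 3, a standard
mammographic-texture surrogate). The automatic caliper subtracts the
corner-estimated background, thresholds at 10% of peak (which spans
0.995·d of a noiseless sphere) and reports the above-threshold extent along
two orthogonal axes, rounded to 0.1 mm; on quiet backgrounds it recovers
diameters within 2 pixel pitches over 3.5–13 mm. No x-ray physics, detector
model, anatomy simulation or vendor processing is attempted, so comparisons
with human-reader statistics must go through the observer model, not this
module. Pixel convention: row-major, positions at pixel centers, origin at
the patch center.

## Statistical battery

All tests report individually at α = 0.05 with no multiplicity correction,
matching common practice for this kind of method evaluation:

- **Shapiro–Wilk** per TVDT data set (skewed gamma-like data are expected
  to fail normality at realistic n).
- **Friedman** χ² across the three sessions per round (reproducibility);
  identical sessions are reported as (0, 1) rather than an error.
- **Two-sample Kolmogorov–Smirnov + Wilcoxon signed-rank** per pair of data
  sets; KS uses scipy's exact small-sample computation where available.
  Zero differences are dropped from the signed rank (the classic
  convention) with the count reported; an all-zero comparison is reported
  as degenerate/no-difference. The two tests are deliberately
  complementary: a small systematic reader bias shifts paired ranks
  (Wilcoxon detects it at n = 30) while leaving the empirical distributions
  nearly identical (KS does not) — the test suite reproduces this
  signature with a 15-day shift plus 25-day paired noise, chosen by power
  analysis (signed-rank power ≈ 0.89, KS power ≈ 0).
- **Median difference (assigned − estimated) with IQR** per session;
  quantiles use the linear-interpolation rule. The sign convention
  (assigned minus estimated) is documented here because the convention is
  otherwise ambiguous.
- **OLS regression** of measured on true size per round; under equal
  absolute noise the second round has the higher R² simply because the
  tumors are larger.
- **Growth classes**: fast = lowest, slow = highest quartile of assigned
  TVDT, each ⌊n/4⌋ members, rank ties broken by patient id (deterministic).
  The per-patient absolute relative error |est − assigned|/assigned is
  compared between classes by two-sample t-test. Note for calibration
  studies: only *multiplicative* measurement noise makes the relative-error
  law identical across classes; additive TVDT noise inflates relative
  errors in the fast class and is a genuine alternative, not a null.

Type-I calibration of the whole battery is asserted in the test suite at
1000 replicates per test with an acceptance band of 2.5–8.5% around the
nominal 5%, wide enough for binomial noise and the small-sample
discreteness/approximation error of the rank tests.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 10⁶ draws for sampler and
ML-recovery checks (2% parameter tolerance), 1000–2000 replicate cohorts of
n = 30 for sampling-distribution checks (cohort-mean SE ≈ 169/√30 ≈ 31 d),
500-sample/200-bootstrap family-selection checks, and 20-point sweeps over
the 3.5–13 mm size range. These sizes make every check decisive at desk
scale while keeping the full suite around ten seconds.

Seeding: one master seed (int or `SeedSequence`) deterministically spawns
per-stage and per-session substreams; every public sampler takes a seed or
Generator, and fixed seeds reproduce bit-identical artifacts end to end.

## Known limitations

- No interval cancers, no randomized jitter of screening dates, exactly two
  rounds in the shipped pipeline.
- Spherical tumors only; no spiculation, no shape change over time, no
  masking by surrounding parenchyma — the lesion-patch surrogate therefore
  understates real reader difficulty.
- The observer noise law (unbiased Gaussian, fixed sd) is a stand-in; real
  intrareader error may scale with size or density. Passing the battery
  under this generator shows the pipeline's statistics are calibrated and
  sensitive, not that a particular human reader behaves this way.
- The clinical fit is anchored to two published moments; with access to raw
  clinical TVDTs, `fit_distribution` + `select_family` should be used
  instead.
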