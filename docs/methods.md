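# Methods

This note documents the models implemented in `shellseasons`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generator does and does not emulate.

## 1. Oxygen-isotope palaeothermometry (`shellseasons.isotopes`)

### Model

Shell aragonite is assumed to precipitate in isotopic equilibrium with
ambient seawater. The water–aragonite fractionation factor is the ratio

α = (1000 + δ¹⁸O_shell) / (1000 + δ¹⁸O_water),  both on the VSMOW scale,

and temperature follows the synthetic-aragonite calibration
1000 ln α = 17.88 · (10³/T) − 31.14 with T in kelvin. The equation is
solved in closed form (T = 17 880 / (1000 ln α + 31.14)); no iteration is
involved, and `shell_d18o_from_sst` is its exact algebraic inverse, used by
the generator and by round-trip tests (identity to better than 1e−9 °C).

Carbonate measurements are reported against VPDB; the water value against
VSMOW. Shell values are converted with the standard affine relation
δ_VSMOW = 1.03091 · δ_VPDB + 30.91 before entering the fractionation ratio.
Whether a given published study applied this conversion or fed VPDB values
in directly is often unstated; conversion is the default here because the
fractionation equation is defined on the water scale, and
`smow_conversion=False` reproduces the other reading.

### Water correction

δ¹⁸O_water = modern mean (default 0.90 ‰)
           + 0.011 ‰ × sea-level offset in metres (offsets ≤ 0 for lower
             past sea level — the Fairbanks ice-volume correction)
           + (−0.3 ‰ if the unit is flagged as meltwater-affected).

Per-unit sea-level offsets are supplied in configuration (they come from an
external relative sea-level curve, not from the shells). The meltwater term
represents the freshening of North Atlantic surface water during the
8.2 ka event; removing the flag warms every reconstructed SST by ≈1.44 °C.
That shift is constant only to first order: because the thermometer is
nonlinear it drifts by roughly 0.01 °C per °C of SST (≈0.18 °C across the
full 8–26 °C range).

### Per-unit summaries and the smoothing window

Each shell's seasonal extremes are taken after a centred moving average of
5 samples along the growth axis (`smooth_window`, set to 1 for raw
extremes). The window exists because raw per-sample extremes are biased
outward: with δ¹⁸O noise of 0.15 ‰ (≈0.7 °C) the maximum of the several
samples sitting near a seasonal peak overshoots the true peak by about
1 °C, inflating seasonality by ~1.5–1.9 °C. A 5-sample window suppresses
this extreme-value bias while attenuating a 3–7 °C-amplitude annual cycle
by under 0.2 °C at realistic sampling densities (≥ ~35 samples/year);
wider windows over-attenuate, narrower ones under-smooth. With it, mean
recovered seasonality is within 0.5 °C of truth (50-seed averages across
amplitudes 3–7 °C).

Unit summaries aggregate shells by `mean-of-extremes` (default; robust to
unequal sampling density between shells) or `pooled` (global extremes of
all samples). Out-of-range SSTs (outside −5…40 °C) raise a warning rather
than an error so diagenetically altered samples surface in logs without
aborting a run; shells ≥ 17 mm diameter likewise warn (the sampling
protocol targets juveniles, whose growth is not yet slowed).

## 2. Assemblage quantification (`shellseasons.quantification`)

MNI formulas operate on non-repetitive skeletal elements:

* bivalves, per side: COMV + FRAV + FCH + max(AHF, PHF), MNI = max of the
  two side totals — a valve whose hinge split can contribute one anterior
  and one posterior fragment, hence the max;
* spiralled gastropods: COMI + FRAI + max(APIF, STOF + UMBF) — the stoma
  and umbilicus are adjacent parts of one base region, so one broken
  individual yields a stoma fragment or an umbilical fragment, not both;
* non-spiralled gastropods (limpets): COMI + FRAI + APIF.

Undiagnostic fragments (FTS, unsided bivalve fragments) are stored but
never counted. Property tests verify each formula against an independent
minimal-individual packing enumeration on random tallies.

Indeterminate limpets are apportioned over identified *Patella* species
proportionally to their per-unit MNI, with largest-remainder rounding so
the grand total is conserved exactly; remainder ties break by descending
species MNI then name, making the allocation deterministic and
permutation-equivariant. Units with no identified limpets keep the
indeterminate row unassigned.

Simpson's index is configurable: `dominance` (Σp²; default, reads high
when few taxa dominate) or `diversity` (1 − Σp²). The two always sum to 1.

## 3. Limpet biometrics (`shellseasons.biometrics`)

Exposure: score = 0.142·L − 0.06·H + 0.0489·W − 5.328 (mm); strictly below
−0.15 ⇒ exposed shore, otherwise sheltered (the boundary value itself is
sheltered — the inequality is strict, as the discriminant is defined).

Intertidal zone: L/H strictly above a regional control ratio ⇒ lower shore
(flatter shells), otherwise higher. The control ratio has **no default**:
it comes from a modern control collection and must be supplied in
configuration, forcing explicit provenance. The direction convention is
flippable (`flatter_is_lower=False`) since it derives from ecological
calibration work, not from this package.

Size selection: Shapiro–Wilk on per-unit shell lengths; units with n < 30
are reported "not evaluated"; otherwise p < 0.05 ⇒ "selection". α = 0.05 is
the conventional single-test level; no multiplicity correction is applied
because each unit is read as an independent question. The W statistic is
location/scale-free, so verdicts are invariant to unit changes (mm vs cm).

## 4. Radiocarbon chronology (`shellseasons.chronology`)

### Calibration

Curves use the standard 5-column comma-separated format (cal BP, ¹⁴C age,
1σ error, Δ¹⁴C and its error — the last two ignored), '#' comments,
linearly interpolated in mean and error. Calibration evaluates, on a
regular calendar grid (default 1 y), the likelihood
N(CRA; μ_curve(θ), σ_date² + σ_curve(θ)²) under a uniform prior and
normalises. This matches brute-force dense evaluation to total variation
< 1e−6 and collapses to the measurement Gaussian on an identity curve.

Marine shell dates are first reservoir-corrected: corrected age =
measured − ΔR, σ² summed in quadrature. The sign convention (subtracting
ΔR from the age rather than adding it to the curve) is equivalent to the
curve-offset reading and is documented here because conventions differ
between software packages. ΔR is species-specific (different habitats and
diets give limpets and topshells different reservoir ages).

HPD intervals accumulate grid points by descending density until the
target mass (default 0.954, the two-sigma radiocarbon convention) and may
be disjoint on multimodal posteriors.

### Phase-sequence model

In cal BP (larger = older), with phases ordered oldest first:

start_j ≥ θ_i ≥ end_j (dates i in phase j);  end_j ≥ start_{j+1}.

Priors: each date is uniform *within its phase* — a 1/(start_j − end_j)
factor per date, the standard uniform-phase prior. This matters: with a
purely flat boundary prior the marginal of a single unconstrained date
would be tilted by a (start − θ)(θ − end) factor and would not reduce to
plain calibration; with the uniform-phase prior the single-date model
reproduces `calibrate()` to TV < 0.05. Boundaries are otherwise uniform
over the curve coverage subject to ordering — a deliberate simplification
relative to full span-neutral boundary priors. Gaps (hiatuses) between
phases are allowed.

Outliers: each date carries a Bernoulli indicator (prior 0.05). When
active, the measurement likelihood swaps from the Gaussian to a Student-t
(ν = 5) whose scale adds 100 ¹⁴C y in quadrature, approximating a t-shift
outlier model with the shift marginalised. A misfit date inside a pinned
sequence is flagged with posterior probability near 1; note that in a
*single* unconstrained phase with few dates, stretching the phase can be
cheaper than flagging — outlier detection draws its power from the
stratigraphic constraints, as in the real deposits.

Sampling is Metropolis-within-Gibbs: vectorised random-walk Metropolis on
calendar ages (proposal sd = 2 × each date's total σ); exact inverse-CDF
Gibbs draws for boundaries (their full conditionals are truncated power
laws (s − e)^(−n_j)); exact Gibbs for indicators. Initialisation places
each date at its independent calibrated median and squeezes phases
old-to-young; dates that cannot fit their stratigraphic position are
clamped (outlier candidates), and only if an entire phase cannot fit is
the model reported unsatisfiable. Runs are bit-for-bit reproducible for a
fixed seed. Default 20 000 iterations with 2 000 burn-in mix well for
20-date models (acceptance ≈ 0.5); boundary-recovery checks use 8 000.

Phase estimates report posterior medians and shortest-interval HPDs,
rounded to the nearest lustrum (5 y) — reflecting the ~5–10 y
run-to-run reproducibility scale of such models — with `rounding=1`
giving raw values.

## 5. Synthetic data (`shellseasons.synthetic`, `shellseasons.study`)

The generator emulates the statistical structure the analysis assumes:

* **SST**: T(t) = mean + amplitude·cos(2π(t − phase)) per unit. The default
  five-unit scenario spans an Early Holocene-like sequence: a cold,
  strongly seasonal basal unit (mean 16.3 °C, amplitude 6.9 °C → winter
  9.4 °C, seasonality 13.8 °C), a warmer middle, two meltwater-flagged
  units with damped summers, and a warm top; sea-level offsets −14…−5 m.
* **Shells**: 45 micro-samples 0.3 mm apart spanning 1.3 years of growth,
  with growth rate decaying exponentially toward the apex, so
  equal-distance samples cover increasing time spans — the ontogenetic
  distortion real shells show. δ¹⁸O comes from the inverse thermometer
  plus Gaussian noise (default 0.15 ‰, the order of the larger
  instrumental error reported for such measurements).
* **Assemblages**: species proportions are logistic in the unit's mean SST
  (cold-adapted limpet vs warm-adapted topshell, matching the strong
  two-taxon dominance of real middens); individuals are fragmented into
  valid categories such that every individual leaves exactly the
  diagnostic elements the MNI formulas count — so in the loss-free regime
  recovery is exact, which the tests exploit. A configurable fraction of
  broken limpets is recorded as indeterminate *Patella* sp.
* **Sizes**: Normal(mean − pressure·2 mm, sd), truncated positive, with an
  upper-truncation mode that produces the non-normal distributions read as
  size selection.
* **Curves and dates**: calibration curves are a linear trend
  (slope 0.95 ¹⁴C y/cal y) plus smooth sinusoidal wiggles whose derivative
  is capped below the trend slope, keeping the mean monotone; the marine
  curve carries a 550 y reservoir offset. Measured ages are
  curve mean + ΔR + Gaussian(0, √(σ² + σ_curve²)).

Every generator is a pure function of (scenario, seed).

**What passing tests do and do not show.** The generator draws noise as
i.i.d. Gaussian, growth as deterministic, fragmentation as independent per
individual, and the seasonal cycle as a pure sinusoid. Real shells stop
growing in extreme seasons, real noise includes diagenesis and vital
effects, real fragmentation is spatially correlated, and real calibration
curves have plateaus that multiply calibrated solutions. Recovery on
synthetic data therefore validates the *computational chain* — formulas,
corrections, samplers, accounting — not the field validity of the
underlying proxies.

## 6. Pipeline and configuration

One YAML file carries every analysis constant (water parameters and
per-unit offsets, Simpson variant, L/H control, ΔR table, phase structure,
MCMC settings, rounding, seed), so nothing numeric hides in code.
Validation collects schema errors with row numbers before aborting and
emits warnings for protocol deviations (≥ 17 mm shells, n < 30 biometric
units). Outputs (`unit_sst_summary.csv`, `mni_by_unit.csv`,
`biometrics_summary.csv`, `phase_estimates.csv`, `date_outliers.csv`,
`diversity.csv`, `sst_by_sample.csv`, `report.json`) are a deterministic —
byte-identical — function of (inputs, config, seed).

### Input schemas

* `isotopes.csv`: shell_id, species, unit_id, diameter_mm, position_mm, d18o_vpdb
* `fragments.csv`: unit_id, taxon, taxon_class, side (L/R/NA), category, count
* `biometrics.csv`: unit_id, species, length_mm, height_mm, width_mm (blank allowed)
* `dates.csv`: lab_id, unit_id, material (bone/charcoal/shell), species, cra_bp, sigma
* curves: IntCal 5-column format, '#' comments

## 7. Problem sizes

Defaults used by the bundled study and the reproduction script: 5 units ×
4 shells × 45 samples for isotopes; 15 500 individuals across assemblages;
80 measured shells per unit pair for biometrics; 20 dates over 5 phases
(8 000 MCMC iterations, 1 500 burn-in); 20 replicates of a 3-phase,
15-date design for boundary-recovery coverage. These sizes make the whole
chain run in about a minute on one CPU while leaving every estimate's
Monte-Carlo error well below the effects being measured.

## 8. Known limitations

* The Bayesian model is a documented simplification of full
  chronological-modelling software: uniform boundary priors, a single
  t-type outlier class, no agreement indices, no charcoal-offset models,
  no wiggle matching.
* Aragonite only; no calcite or mixed-mineralogy thermometer.
* No growth-stoppage detection; the juvenile-shell selection rule is
  assumed to have handled seasonal growth cessation.
* Apportionment assumes indeterminate limpets share the identified
  species' composition — the same assumption the recording protocol makes.
* Sea-level offsets and the L/H control ratio are inputs, not estimates.
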