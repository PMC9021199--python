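# shellseasons

Analysis toolkit for shell-midden palaeoclimate and subsistence studies:
seasonal sea-surface temperature (SST) from sequential shell δ¹⁸O profiles,
shell-assemblage quantification (MNI, relative abundance, Simpson's index),
limpet biometrics (shore exposure, intertidal zone, size-selection testing),
and a simplified Bayesian radiocarbon phase-sequence chronology. Every stage
can be exercised end-to-end on synthetic data with known ground truth.

It is written for archaeomalacologists and palaeoclimatologists working with
stratified coastal deposits — sequences of occupation layers full of
harvested mollusc shells, where each shell is both a palaeothermometer and a
radiocarbon sample.

## The science in brief

**Palaeothermometry.** Aragonitic shells precipitate carbonate in isotopic
equilibrium with seawater. The water–aragonite fractionation factor
α = (1000 + δ¹⁸O_shell)/(1000 + δ¹⁸O_water) (both ‰ VSMOW) obeys

```
1000 ln α = 17.88 · (10³ / T) − 31.14        (T in kelvin)
```

which is solved in closed form for T. Shell values measured against VPDB are
first converted with δ_VSMOW = 1.03091·δ_VPDB + 30.91. The ambient-water
value is the modern local mean (0.90 ‰) corrected by +0.011 ‰ per metre of
sea-level rise (negative offsets for lower past stands) and, for units
deposited during glacial meltwater outbursts such as the 8.2 ka event, a
further −0.3 ‰ freshening. Sequential micro-samples along the growth axis
trace the seasonal cycle; per-unit winter/summer SST and seasonality
(max − min) summarise it.

**Quantification.** Fragment tallies in standard recording categories give
the minimum number of individuals per taxon:
bivalves max over sides of COMV + FRAV + FCH + max(AHF, PHF);
spiralled gastropods COMI + FRAI + max(APIF, STOF + UMBF);
non-spiralled gastropods COMI + FRAI + APIF. Indeterminate limpets
(*Patella* sp.) are redistributed over the identified limpet species pro
rata with largest-remainder rounding, conserving totals exactly.

**Biometrics.** For *Patella vulgata*, the exposure discriminant
0.142·L − 0.06·H + 0.0489·W − 5.328 (< −0.15 ⇒ exposed shore) and the L/H
ratio against a regional control value (flatter shells ⇒ lower intertidal)
classify harvesting habitats; a Shapiro–Wilk test on shell lengths
(n ≥ 30) probes deliberate size selection.

**Chronology.** Dates are calibrated on a calendar grid (Gaussian
likelihood with curve error in quadrature; shell dates first corrected by a
species-specific marine ΔR). Stratigraphic phases with start/end boundary
parameters are arranged in an ordered sequence and sampled by
Metropolis-within-Gibbs under the standard uniform-phase prior, with
Student-t outlier indicators (prior 0.05) absorbing misfit dates. Reported
estimates are rounded to the nearest lustrum (5 y).

## Worked example

Generate a five-unit synthetic study (scenario truth: e.g. unit 108 has
winter SST 9.4 °C and seasonality 13.8 °C; 15 500 individuals across units;
deposition intervals from 8995–8760 down to 7945–7795 cal BP) and run the
whole pipeline:

```
shellseasons synth --out demo --seed 42
shellseasons run --config demo/run.yaml
```

which prints/writes, among other tables:

```
unit_id  sst_min  sst_max  seasonality  n_shells      aggregation
   101B    12.49    24.66        12.17         4 mean-of-extremes
    105    11.14    22.44        11.30         4 mean-of-extremes
    107    11.59    24.38        12.80         4 mean-of-extremes
    108     9.53    22.55        13.03         4 mean-of-extremes
   112C    10.79    22.65        11.86         4 mean-of-extremes

phase  start_median_bp  end_median_bp  duration_median_y
  108           8975.0         8870.0              110.0
  107           8520.0         8330.0              205.0
  105           8280.0         8210.0               65.0
 112C           8090.0         8000.0               95.0
 101B           7880.0         7795.0               90.0
```

Unit 108's winter SST is recovered at 9.5 °C against a scenario truth of
9.4 °C, and its seasonality at 13.0 °C against 13.8 °C (four shells, δ¹⁸O
noise 0.15 ‰); the meltwater-flagged units (105, 112C) show the damped
seasonal range the scenario encodes. Phase medians fall inside the true
deposition intervals, durations are non-negative by construction, and none
of the 20 simulated dates is (correctly) flagged as an outlier.
`mni_by_unit.csv` reproduces the simulated assemblage exactly — e.g. unit
108 is dominated by the cold-adapted *P. vulgata* (69 %) over the
warm-adapted *Phorcus lineatus* (28 %), as its 16.3 °C mean SST dictates.

The same machinery accepts real data: point `run.yaml` at your own
`isotopes.csv`, `fragments.csv`, `biometrics.csv`, `dates.csv` and IntCal
5-column curve files (schemas in `docs/methods.md`).

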