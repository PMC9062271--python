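# Methods

## The estimation problem

Savanna woody vegetation under chronic disturbance (elephants, fire,
browsing, woodcutting, abiotic dieback) violates the assumptions of
conventional inventory allometry. Heavily damaged individuals — called
gullivers here — have heights that no longer track their stem dimensions;
stems break, burn, or die below breast height; topkilled trees resprout as
shrubs while their dead trunks dwarf the living regrowth by orders of
magnitude. This package computes, per woody individual, both the standing
(living, post-disturbance) aboveground biomass and the biomass lost to each
disturbance agent, and upscales both to stand level. The central accounting
identity,

    AGB_ex = AGB_standing + Σ_agent loss_agent,

is enforced to 1e-9 relative at the individual, plot, and stratum level.

## Growth classes and dispatch

Classification drives everything. A stem is *adult-sized* when its basal
circumference strictly exceeds 15 cm (a stem of exactly 15 cm is not
adult-sized); an individual is a *gulliver* when its recorded total loss is
at or above 30 % of living biomass. The classes and their workflows:

| class | definition | living-part model | height correction | dead stems |
|-------|------------|-------------------|-------------------|------------|
| JU/GJ | no adult stems, below the juvenile height boundary | canopy | – | – |
| SA/GS | no adult stems, above it | canopy | – | – |
| AA    | living adult stems, loss < 30 % | stem | no | – |
| AG1   | living adult stems only, loss ≥ 30 % | stem | yes | – |
| AG2a  | dead + living adult stems, living loss < 30 % | stem | no | yes |
| AG2b  | dead + living adult stems, living loss ≥ 30 % | stem | yes | yes |
| AG3   | dead adult stems, no living adult stem | canopy | – | yes |

The two model families enter the accounting identity from opposite ends.
The stem model yields the *pre-disturbance* value, from which recorded
percentage losses are deducted (`loss_a = AGB_pre · p_a/100`). The canopy
model reflects the *damaged* state, so the pre-disturbance value is
recovered by reverse damage assessment, `AGB_pre = AGB_post / (1 − P/100)`,
with per-agent losses allocated proportionally to the recorded percentages.
These two directions are exact inverses; a property test checks the round
trip.

Dead adult-sized stems are never part of standing AGB and are excluded from
the visual loss percentages (which refer to the living part only). Their
former biomass is reconstructed through the proxy chain — alternative
reading → basal circumference (taper formula) → surrogate DBH
(proportionality) → reconstructed height (power law) → stem model — and
booked as a loss under the recorded topkill agent; two joint agents split
the loss equally (the protocol names up to two but no weighting, so the
uninformative split is the default and weights are configurable).

Percentage losses are capped at 99 %: total topkill still leaves a living
remainder, which keeps the reverse-damage division well-defined.

## Calibration

The three reconstruction regressions are refit locally from the *healthy
reference subset*: class AA individuals with total loss below the gulliver
threshold and no dead stems, one observation per living stem. The height
model is ordinary least squares of ln h on ln DBH (R² on the log scale);
the DBH and taper models are one-parameter least squares through the origin
(the printed forms are pure proportionalities), with uncentered R² — the
natural goodness-of-fit for a no-intercept model, guaranteed in [0, 1].
The taper model is linearized as `130 (1 − circ(hx)/basal) = t · hx`. When
no local reference trees exist, the printed reference coefficients
(a, b, s, t) = (4.72595, 0.63385, 0.7968, 0.2032) are used, and every
output records the calibration provenance (`local` vs `paper-default`).
Height correction never shortens a tree: the reconstructed height is
`max(h_observed, exp(a + b ln DBH))`.

The regressions are scikit-learn estimators (`fit`/`predict`, fitted
attributes with trailing underscores) and the whole protocol is wrapped in
`BiomassEstimator`, a transformer whose `fit` classifies, builds the
species wood-density table, and calibrates, and whose `transform` emits the
per-individual results table.

## Wood density

Specific wood density (SWD) is oven-dry mass over fresh volume (g cm⁻³),
with volume taken as a cylinder whose diameter is the arithmetic mean of
the five caliper readings — averaging the readings first rather than
averaging per-segment volumes is the simpler of the two defensible
conventions and is pinned by a regression test. Species means feed the stem
model; missing species fall back to the genus mean (genus = first token of
the binomial label), then to an optional global default, always with a
provenance flag. Values at or above 1.5 g cm⁻³ are rejected as data-entry
errors (the densest known woods are ≈ 1.4).

## Upscaling

Each growth-class group (juveniles, saplings, healthy adults, adult
gullivers) is recorded on its own nested subplot; the realized area per
class per plot converts individual values to kg ha⁻¹ via the factor
`10 000 / area` and each individual's plot-edge fraction. Plot summaries
are sums; stratum summaries report means and standard deviations over
replicate plots (inferential statistics are out of scope). AGB_pot per
vegetation type is the arithmetic mean (median by flag) of AGB_ex over the
reference stratum of lowest elephant density. No automatic outlier
exclusion is applied; callers may pass an explicit plot list to drop.

## Synthetic studies and what they can show

The generator reproduces the study conditions: 2 vegetation types × 3
elephant-density levels × 10 plots of 1000 m²; juveniles on a fixed 100 m²
subplot, saplings on 250–750 m², adult gullivers on 750–1000 m², healthy
adults on the full plot. Populations are allometrically coherent (adult DBH
lognormal with median 18 cm, σ = 0.45; heights on the calibration power
law; crown diameter linked to height by CD = 0.5 (h/100)^0.85), with
stem densities chosen to give stand totals in the tens of t ha⁻¹ typical of
semi-arid savanna/woodland. Disturbance regimes draw per-agent Beta loss
fractions with stratum-specific means injecting a gradient — fire losses
fall and elephant losses rise with elephant density — plus topkill and
partial stem death that produce the AG subtypes; drawn totals are rescaled
below the 99 % cap. Measurement noise is multiplicative lognormal on
heights, circumferences, crown diameters, and wood-sample dimensions, off
by default. Randomness is a single master seed with per-plot substreams, so
partial regeneration is reproducible.

Ground truth is computed by running the estimation protocol itself with the
generator's true coefficients and true wood densities on the emitted
observables. This is deliberate — no independent biomass truth exists for
these allometric forms — and it defines exactly what end-to-end tests show:
they verify the *protocol logic* (classification, reconstruction chains,
loss accounting, conservation, upscaling), not the external accuracy of the
allometric models. With all noise at zero the blinded pipeline recovers the
truth to machine precision because the calibration fits recover the true
coefficients exactly. Features of real data the generator does not emulate:
spatial clumping within plots, species-specific allometry, observer bias in
visual loss percentages, and temporal regrowth dynamics.

## Numerical choices

* Canonical units: heights and circumferences in cm, crown diameters in m,
  SWD in g cm⁻³, AGB in kg, areas in m². The stem model consumes height in
  m; the cm→m conversion happens only inside estimation calls, and the
  parameter name (`h_m`) plus a 100^0.976 canary test guard the contract.
* Conservation and identity tolerances are 1e-9 relative throughout.
* The juvenile/sapling height boundary defaults to 150 cm; it is a
  site-specific configuration parameter, not a universal constant, as are
  the 15 cm and 30 % thresholds.
* Unknown disturbance-agent labels map to "other" with a warning, never
  dropped; unknown topkill attributions behave the same way.
* CSVs are written with `%.17g` and read with round-trip float parsing, so
  write → read is the identity on validated records.
* Degenerate fits raise explicit errors: fewer than 3 usable reference
  stems, all-equal DBH, all-zero hx. Taper fits warn and report rows whose
  denominator 130 − t·hx would be non-positive at the fitted coefficient.

## Problem sizes

Default test and acceptance runs use full 60-plot studies (≈ 2 500
individuals), which the whole pipeline processes in a few seconds; the
noisy-calibration check uses 50 replicate fits at n = 500. These sizes make
Monte-Carlo standard errors small relative to the tolerances while keeping
runs interactive.

## Known limitations

* The canopy model's back-transform constant (1.403) is applied exactly as
  published; no alternative allometries are bundled, though the model
  functions are pure and replaceable.
* No uncertainty propagation on AGB estimates; dispersion is reported only
  across replicate plots.
* No belowground biomass or carbon-fraction conversion.
* The XLSX reader is a best-effort adapter with an explicit column mapping;
  the canonical CSV schema is normative.
* Stems whose bases were partially destroyed must arrive with a
  reconstructed basal value or an alternative reading; the package does not
  guess missing circumferences.
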