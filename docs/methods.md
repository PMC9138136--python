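# Methods

This note documents the models behind the simulated rig: what they assume,
what the defaults mean, and what the simulations do and do not establish
about a physical bioreactor.

## System overview

The package reproduces, in software, an automated perfusion culture rig: a
stepper-driven syringe pump, an exclusive multi-port selector routing flow
between the pump, the culture wells, a fresh-media reservoir and a waste
line, per-well stirrers, and a non-contact colorimetric pH sensor mounted
on the waste line. The control program is a small scripted language
(docs/dsl.md); the physical devices are replaced by a simulated device bus
backed by a culture digital twin, behind the same `DeviceBus` contract a
serial backend would implement.

## Pump model and calibration

The pump is parameterised by syringe capacity (default 10 mL, a disposable
10-mL syringe), a steps-per-mL conversion (default 800 steps/mL, typical of
a NEMA17 + leadscrew syringe drive; the true drive geometry is rig-specific
and configurable), and flow rate (default 2 mL/min, max 10 mL/min). A pump
run of volume *v* at rate *r* takes *v/r* minutes. Direction `B` withdraws
into the syringe, `F` dispenses; the convention is configurable at the bus
level. Calibration follows the standard bench procedure: run the pump at
several set rates for one minute each, weigh the dispensed water
(density taken as 1.000 g/mL), and fit ordinary least squares of mass on
set rate; an accurate pump gives slope ≈ 1 g per (mL/min) with r² ≈ 1.

## Colorimetric pH sensing

Phenol red in DMEM shifts yellow → pink over pH 6.8–8.2; redder media
absorb more green light, so the transmitted green intensity falls linearly
with pH over that window. The shipped calibration line is

    green intensity = −57.7 · pH + 1032    (valid pH 6.90–7.83, n = 3)

Intensity units are arbitrary linear counts (the ADC depth of the light
sensor is not fixed; an optional 10-bit quantisation mode rounds and clips
to 0–1023). The forward model used by the simulator adds Gaussian noise on
intensity counts, default sd 2 — on the line's slope that corresponds to a
pH read noise of ≈ 0.035 — as a plausible dispersion for a triplicate-read
photometric channel; it is a config parameter, not a measured quantity.
Readings whose converted pH falls outside the calibration range by more
than a 0.1 guard band have their estimate suppressed (reported as missing)
and are flagged, never raised as errors: monitoring is passive and must not
abort a culture. Calibration fits refuse pH levels outside 6.8–8.2, where
the indicator is uninformative, and need at least two distinct levels.

## Culture digital twin

Each well carries cell count *N*, media volume *V* (mL) and accumulated
acid load *A* (arbitrary acid equivalents). pH is derived through a linear
buffer approximation:

    pH = pH_fresh − A / (β · V)

Dynamics between media exchanges:

    dN/dt = r · f(pH) · N · (1 − N/K)
    dA/dt = q · N

with f(pH) = 1 within ± `ph_tolerance` of the optimum, declining linearly
to 0 one pH unit away. A partial exchange removes well-mixed medium
(scaling *A* by the fraction remaining) and adds acid-free fresh medium;
cells are an adherent monolayer and are never removed with the medium.

Defaults (all configurable):

| parameter | default | meaning |
|---|---|---|
| `r_per_h` | 0.035 h⁻¹ | max specific growth rate (~20 h doubling, healthy fibroblasts) |
| `K_cells` | 1.2 × 10⁶ | carrying capacity per 6-well-plate well |
| `q_acid_per_cell_h` | 3 × 10⁻⁷ | acid equivalents excreted per cell per hour |
| `beta` | 3.0 eq·mL⁻¹·pH⁻¹ | linear buffer capacity (arbitrary units) |
| `fresh_ph` | 7.45 | pH of fresh CO₂-equilibrated DMEM |
| `ph_optimum`, `ph_tolerance` | 7.4, 0.2 | physiologic band for fibroblasts |
| `seed_cells`, `well_volume_ml` | 7 × 10⁴, 5 mL | standard seeding of a 6-well plate |

The twin's functional forms and rate constants are the package's own
design, calibrated analytically (quasi-steady acid balance) to the
qualitative behaviour the rig is built to produce — an unrefreshed well
drifts below pH 7.2 within 72 h, while the 2 mL / 6 h refresh holds every
well inside 7.4 ± 0.2 for 48 h with the logged mean near 7.4 — not fitted
to any measured trajectory. `fresh_ph` is set to 7.45 rather than the top
of the band: fresh bicarbonate-buffered DMEM in a 5 % CO₂ incubator sits
near 7.4, and a fresh-media pH at the band ceiling would make early-culture
readings (which approach `fresh_ph` from below) indistinguishable from
band violations at the sensor's noise level.

**Integration.** Deterministic explicit Euler with sub-steps ≤ 0.1 h
(`sim.dt_max_h`). The dynamics are smooth and slow on that scale; halving
the step changes 48-h pH by well under 0.005 (asserted in the suite). All
stochasticity lives in the sensor noise, so twin trajectories are
bit-reproducible and runs are byte-identical given a seed.

**Identifiability.** `fit_growth_params` refits (r, q) from an observed
cell-count + pH trajectory by least squares over simulated candidates; on a
noise-free trajectory it recovers the generating values to well under 1 %,
confirming the two rates are separately identifiable from the two observed
channels.

**Known limitations.** No CO₂/bicarbonate equilibria (the linear buffer is
only sensible inside the phenol-red window, and pH is unbounded below if
acid accumulates indefinitely), no nutrient depletion, O₂ transport,
suspension effects or contamination dynamics — although a persistently low
pH is a useful proxy for culture failure. Stirring is assumed ideal
(well-mixed) whether or not stirrers run.

## Controller and sensing geometry

The refresh protocol services wells in fixed listed order each cycle; each
well's exchange is the quadruple drain → dispose-to-waste → draw-fresh →
refill, and the disposal is routed past the waste-line sensor, so every
cycle yields one pH reading per well *of the spent medium just drained* —
the log lags the well state by one transfer, and the logged pH is the
pre-exchange (most acidic) point of the well's cycle. The scripted `Wait`
is the full refresh period, so consecutive cycle starts are separated by
the period plus the pump time of the preceding transfers (24 min per cycle
at the defaults); the schedule is open-loop, exactly as scripted, with no
pH-triggered feedback.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the protocol at its native scale
(48-h and 72-h horizons, 6 wells, 0.1-h integration steps), 1 000 random
scripts for interpreter–oracle equivalence, 10 000 random pump operations
for the volume ledger, and 25 replications of the 5-level × 3-replicate
calibration design; the whole suite completes in a few seconds.

## What passing simulations do and do not show

The closed-loop runs demonstrate that the *control software* — parser,
interpreter, scheduling, device accounting, logging and calibration
handling — behaves correctly against a culture with plausible kinetics,
and that the published maintenance behaviour (pH held in band by periodic
partial refresh; refreshed cultures outgrowing static ones) emerges from
the stated mechanism. They do not validate the twin's rate constants
against any particular cell line, medium or incubator; transferring the
protocol to hardware requires the rig's own pump and pH calibrations and,
if quantitative pH prediction is wanted, refitting (r, q, β) to measured
trajectories with `fit_growth_params`.
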