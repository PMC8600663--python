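# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `lakeomp`.

## 1. Lake representation

The water column is discretized into horizontal layers of thickness
1 m with centres at the integer sampling depths 1…18 m, matching a
vertical-profile sampling campaign at 1 m intervals. Hypsography is a
conical bowl: horizontal area decreases linearly from the surface
(12 km² default) to the bottom, with the bottom/surface ratio set so
the continuous basin has the target mean depth (10.9 m default). The
discrete basin then holds ≈1.26×10⁸ m³; the outlet discharge is set so
the lake flushes four times per year on a completely mixed basis,
i.e. Q/V = 4/365.25 ≈ 0.011 d⁻¹. Concentrations live at layer centres,
diffusivities at the internal interfaces; interface areas are the mean
of the adjacent layer areas.

Flows are steady within a simulation window (piecewise-constant
forcing between sampling events). The outlet withdraws from the
surface layer. There is no sediment exchange, sorption, volatilization
or biodegradation term: flushing is the sole export mechanism, with
depth-attenuated photolysis in the epilimnion as the one optional
elimination process.

## 2. Transport terms

**Diffusion.** Interface conductance is Kz·A/Δz (m³/d); fluxes are
pairwise antisymmetric, so the discrete operator conserves mass
exactly and smooths monotonically.

**Inflow insertion.** Each inflow carries a metalimnion fraction
`f_meta` ∈ [0, 1]. When the column is stratified (some interface with
|dT/dz| > 1 °C/m), that fraction is inserted into the metalimnetic
layer whose water density (freshwater polynomial, maximum at 4 °C)
best matches the inflow density; the remainder is distributed
volume-weighted over the epilimnion (layers above 6 m by default).
An unstratified column receives 100 % in the epilimnion regardless of
`f_meta`. Continuity carries inserted water strictly upward from the
insertion depth to the surface outlet; the induced upward advection is
discretized upwind.

**Photolysis.** A single lumped first-order surface rate per compound
(direct + indirect combined) is attenuated with depth by the band mean
of exp(−Kd·z) over each layer and applied only above the epilimnion
depth. Rate constants are inputs, not derived from irradiance.

**Integration.** The per-compound system is linear with constant
coefficients; it is integrated with implicit BDF (analytic Jacobian,
relative tolerance 10⁻⁶, halving the tolerance changes outputs by
< 0.1 %). A direct steady-state solve is also provided. Integrator
round-off below zero is clipped.

## 3. Vertical diffusivity from temperature profiles

The heat-budget (flux-gradient) estimate at each internal interface is

    Kz = (Δ heat content below the interface / Δt)
         ÷ (interface area × time-averaged dT/dz),

with the gradient from centred differencing of the mean of the two
profiles. Defaults: gradient floor 0.02 °C/m below which the estimate
is flagged `indeterminate` and set to the mixed-layer proxy
Kz_max = 8.6×10³ m²/d (~0.1 m²/s); estimates outside
[8.6×10⁻³, 8.6×10³] m²/d are clamped and flagged `capped`
(8.6×10⁻³ m²/d ≈ molecular scale). An exactly zero heat change yields
Kz = 0 unflagged — an informative zero rather than noise — even though
it sits below the clamp floor.

The two-profile time average is exact only while gradients change
little over the interval. Verification therefore uses a smooth
mid-season profile (a sharp onset profile relaxed by 10 d of diffusion)
and a 7 d interval, recovering a known constant Kz = 5 m²/d within
15 % at every usable interface. Sharper profiles or longer intervals
degrade the estimate — a known property of two-profile heat budgets,
not of this implementation.

When only one profile is available (e.g. driving a forward run), a
deliberately coarse two-regime parameterization is used: 86 m²/d above
the shallowest strongly stratified interface, 0.02 m²/d below. This is
what preserves the metalimnetic spike in forward simulations.

## 4. Screening cascade

Filters are a pure conjunction, so application order cannot change the
retained set; the implementation runs cheapest-first (spike → static →
correlation) and records a per-feature audit trail.

Threshold semantics follow the wording they encode: "at least
1.2-fold" is inclusive (≥), "above 10⁵" and "r > 0.7" are strict. The
1.2-fold comparison is taken against **each** adjacent depth
(conjunction), the stricter of the two defensible readings; a zero
adjacent intensity yields an infinite ratio that passes with a flag.
Profiles are max-normalized (peak = 1) by default because observed
wastewater profiles peak at a common maximum; mean-normalization is
available. Peak-shape/symmetry and molecular-formula plausibility
need raw spectra that a feature table does not carry; the audit trail
marks them unevaluated. Ties in the output ordering are broken by
descending peak intensity, then feature id.

## 5. Occurrence statistics

Censored values are substituted at LOQ/√2 (configurable: 0 or LOQ/2),
a common left-censoring convention; detection uses value ≥ LOQ.
Z-scores use the population SD — the n vs n−1 choice is a row-wise
scale factor that cannot change the Euclidean/Ward tree topology.
Zero-variance rows are set to zero and flagged. Clustering is
agglomerative (scipy linkage), Euclidean metric, Ward criterion, cut
at k clusters (k = 4 default, mirroring a wastewater cluster plus
three mixed-source clusters; with the synthetic generator's two-class
truth, k = 2 recovers the classes exactly and k = 4 subdivides the
mixed-source block by home tributary).

EARs convert ng/L to µM via C/MW/1000. Endpoints are summarized by the
maximum (most conservative; median available), per-site exposure is the
mean across samples ("mean exposure scenario"), cumulative EARs are
sums over compounds, and exceedance is flagged at EAR ≥ 10⁻³.
Cumulative-concentration correlations sum detected (uncensored) values
only.

## 6. Load apportionment

Load = Q·C·10⁻⁶ g/d. Ratios and fractions are computed per compound
and event, averaged over compounds within a class per event, then
averaged across events with a spread band (population SD by default —
a descriptive band for n = 2 events; the sample convention is
available). Fractions sum to (L_input/L_output)×100 %, not forced to
100 %. Loads require collocated (Q, C) at a site; a detection-frequency
gate (> 80 %, strict) can restrict the compound set. Transport between
gauges is assumed conservative; ratio deviations from 1 are interpreted
directionally (loss vs unaccounted sources), not modeled.

## 7. Synthetic-data generator

The generator emulates the statistical structure of a wastewater-
impacted, rapidly flushed, dimictic urban lake:

* **Water budget.** Four tributaries (discharge weights 0.40/0.33/
  0.20/0.07 of the non-WWTP flow) plus a WWTP outfall (84 MGD capacity,
  capped at 30 % of the outlet flow) balance the outlet exactly.
* **Stratification.** Sigmoid profiles; July: 25 °C epilimnion, 8 °C
  hypolimnion, thermocline 7 m, sharp (the epilimnion is well mixed to
  6 m and the metalimnion is the 6–8 m band); October: weak (14/10 °C,
  thermocline 12 m). A `stratification_strength` of 0 degenerates to
  uniform columns.
* **Plunging.** Inflow temperatures sit near the 7 m layer temperature
  (±0.3 °C), so density matching inserts interflows at ~7 m.
  Metalimnion fractions span the 10–40 % envelope, with the steadily
  discharged, dense WWTP effluent drawn from the top quarter and
  tributaries from the lower half — the contrast between the effluent's
  and the tributaries' plunging is what imprints the ≥1.2-fold
  metalimnetic spike on wastewater-derived compounds in forward
  simulations (verified across seeds).
* **Compounds.** Wastewater-derived compounds are ~20× more
  concentrated in the effluent (lognormal around 1500 ng/L) than in
  tributaries; each mixed-source compound is ~10× elevated in one
  home tributary (around 300 ng/L). A third of compounds get a lumped
  surface photolysis rate of 0.005–0.05 d⁻¹ (the same order as the
  0.011 d⁻¹ flushing rate); 85 % of LOQs fall below 25 ng/L.
  Molecular weights are uniform on 120–500 g/mol. These magnitudes are
  order-of-magnitude placeholders, not literature values.
* **Observations.** Truth is the forward-simulated profile after 60 d
  (roughly the time from stratification onset to mid-summer sampling)
  from a clean initial state; duplicate measurements apply mean-one
  multiplicative lognormal noise (CV 0.05 by default — additive noise
  was rejected because concentrations span orders of magnitude and
  duplicate field errors scale with the signal) and left-censoring at
  the compound LOQ.
* **Feature tables.** Planted features follow a canonical wastewater
  shape (epilimnetic plateau 0.55, spike 1.0 at 7 m, decaying
  hypolimnetic tail; spike ≥1.5-fold over both neighbours before
  noise) at intensities well above the 10⁵ floor; decoys span the null
  space of the correlation filter: flat, reversed (hypolimnion-
  peaked), i.i.d. random, and random-walk families. m/z is uniform on
  100–1000 Da, retention time on 1.7–27.1 min. Ground-truth labels are
  retained for recall/precision scoring.
* **River network.** Two upstream rivers and a lateral reach are sized
  so the lake outlet carries ~9 % of the basin-outlet flow; river
  concentrations are the lake-outlet level × 0.131 (wastewater class)
  or × 0.331 (mixed class), which places the lake's fractional
  contribution near 43 % and 23 % of the respective output loads. The
  basin outlet carries exactly the summed input loads (conservative);
  an `undeclared_load_fraction` adds unmonitored load to push
  L_input/L_output below 1.

What the generator does **not** emulate: raw spectra and peak shapes,
weather-driven hydrodynamics and inflow transients, in-stream
transformation kinetics, sediment interactions, correlated measurement
error, or matrix effects. Passing tests therefore demonstrate the
correctness of the statistical and transport machinery under the
stated assumptions, not field performance.

## 8. Problem sizes and determinism

Default test/analysis sizes: 18 layers, 16 compounds, 205-row feature
tables (5 planted + 200 decoys), 24-compound clustering matrices, two
sampling events — small enough that the full suite and the acceptance
script run in seconds while every mechanism is exercised. All
generators are deterministic under (seed, parameters); the pipeline
derives per-stage substreams from one global seed and reruns are
bit-identical.

## 9. Known limitations

* The self-recovery PBIAS under 5 % noise concentrates on ~7
  effective depths per profile; its dispersion is ~1.3 % and worst-case
  draws can graze 5 %.
* The heat-budget inversion needs gradual gradient evolution between
  profiles; it is biased for sharp profiles over long intervals.
* Induced vertical advection is assumed strictly upward from the
  insertion depth to the surface outlet (continuity); downwelling
  circulations are not represented.
* The October (weakly stratified) state is generated but the default
  observation window simulates the July state only.
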