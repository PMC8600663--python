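# lakeomp

Tools for characterizing organic micropollutants (OMPs) in stratified
lake–river systems: nontarget LC-HRMS feature prioritization guided by
vertical concentration profiles, source-related occurrence clustering
and exposure–activity screening, one-dimensional lake mass-balance
fate modeling, and river-network load apportionment. The package is
aimed at environmental chemists and water-quality modelers working on
wastewater-impacted lakes, and ships a seeded synthetic-data module so
every stage can be exercised and tested without field data.

## The science in brief

**Screening.** During strong summer stratification, cool (negatively
buoyant) wastewater effluent and tributary water plunge below the
epilimnion and intrude into the metalimnion, imprinting a concentration
spike (here at 7 m) on wastewater-derived compounds. Unknown HRMS
features that share this fingerprint are promising wastewater-derived
candidates. The cascade retains a feature when it

1. shows at least a 1.2-fold intensity increase at the spike depth
   relative to **both** adjacent depths (6 m and 8 m),
2. is present in every vertical-profile sample with a maximum
   intensity above 10^5 (and passes an optional blank-ratio check), and
3. has Pearson *r* > 0.7 between its max-normalized profile and the
   mean normalized profile of confirmed wastewater-derived compounds.

**Clustering and bioactivity.** Compound × site-group matrices of
median concentrations (censored values substituted at LOQ/√2) are
z-score standardized per compound and clustered with Euclidean
distance and Ward linkage, separating wastewater-derived from
mixed-source compounds. Exposure–activity ratios
EAR = C(µM)/ACC(µM) are summed per site and flagged against the
conservative effects-screening threshold of 10⁻³.

**Fate modeling.** The lake is a stack of 1 m layers. Per layer *i*
and compound:

```
V_i dC_i/dt = Σ_s q_{s,i} C_s                 (inflow insertion)
            + Kz·A·ΔC/Δz exchanges            (vertical diffusion)
            + upward advection (continuity)   (insertion → outlet)
            − Q_out·C_surface  [outlet layer] (flushing)
            − k_photo,i·V_i·C_i               (epilimnetic photolysis)
```

Vertical eddy diffusivity Kz comes from the heat-budget method applied
to sequential temperature profiles; a fraction (10–40 %) of each inflow
is inserted at its depth of neutral buoyancy in the metalimnion. Model
skill is scored with PBIAS = 100·Σ(obs−sim)/Σ(obs) (negative =
overestimation) and NSE = 1 − Σ(obs−sim)²/Σ(obs−mean)². A lake flushed
four times per year on a completely mixed basis has a first-order
flushing rate constant of 4/365.25 ≈ 0.011 d⁻¹.

**Load apportionment.** Loads are Q·C mass flows (g/d). Summed input
loads from the lake outlet, upstream rivers, and a lateral reach are
compared with the basin-outlet load: L_input/L_output > 1 points to
in-stream loss, < 1 to unaccounted sources; fractional contributions
are aggregated per compound class across sampling events.

## Worked example

```bash
lakeomp run-all --seed 1 --outdir demo_run
```

generates a synthetic scenario (a 12 km² lake flushed four times a
year, four tributaries plus one WWTP, 8 wastewater-derived and
8 mixed-source compounds), then screens, clusters, simulates,
evaluates, and apportions. The `demo_run/report.json` it writes
contains, among others:

```
"screen":    {"n_in": 205, "n_selected": 5, "recall": 1.0, "precision": 1.0}
"evaluate":  {"median_nse": 0.997, "mean_pbias_pct": -0.127, "n_compounds": 16}
"apportion": {"mean_ratio": 1.0, "lake_fraction_ww_pct": 43.1, "n_compounds": 16}
"generate":  {"flushing_rate_per_day": 0.01095, ...}
```

Reading: all 5 planted wastewater-like features were recovered from
205 candidates with no false positives; the fate model reproduces its
own noisy re-measurements with median NSE 0.997 and essentially zero
bias; the conservative river network closes exactly (L_input/L_output
= 1.0) with the lake contributing 43 % of the wastewater-derived
output load; and the outlet discharge corresponds to a 0.011 d⁻¹
flushing rate. Every stage is also available as its own subcommand
(`generate`, `screen`, `cluster`, `ear`, `simulate-lake`, `apportion`)
operating on CSV tables.

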