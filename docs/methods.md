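# Methods

## Synthetic forage trials

The generator emulates the factorial pot and field experiments that the
economics is anchored to. Expected dry biomass of subject *s* (a pot or
plot) under treatment *T* at harvest *h* is

    E[dry] = baseline_h × multiplier(T)

and realised values are multiplicative log-normal:

    dry(s, T, h) = baseline_h × multiplier(T) × exp(u_s + b_k + e_sh)

* `u_s ~ N(0, subject_sd²)` — drawn once per subject and shared across
  its harvests, mirroring the repeated-measures structure in which each
  pot/plot is a random blocking factor;
* `b_k ~ N(0, block_sd²)` — additive log-scale block effect, field mode
  only (block count = replicates, one replicate of every treatment per
  block);
* `e_sh ~ N(0, residual_sd²)` — independent harvest-level noise.

Fresh biomass is `dry × fresh_to_dry_ratio × exp(N(0, fresh_noise_sd²))`.

The noise model is multiplicative because biomass is positive and all
downstream statistics are percent differences, which are scale-free; a
log-normal keeps every draw positive and makes the zero-noise limit
exact (`cumulative % diff = 100 × (multiplier − 1)`).

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| replicates (pot) | 5 | the trial layout |
| harvest days (pot) | 68, 139, 207, 269, 361, 454 | the trial layout |
| replicates/blocks (field) | 3 (*Brachiaria*), 4 (*Panicum*) | the trial layout |
| baseline (pot), g DM/pot | 7, 14.5, 18, 16, 11, 8.5 | rise-then-fall harvest profile typical of establishing forage; raw per-harvest biomass is not published, so the level is a free parameter (percent differences do not depend on it) |
| treatment multipliers (pot) | cumulative observed differences: *Brachiaria* B 1.274, F 1.118, B+F 1.200, F+I 1.249, B+F+I 1.199, I 0.905, B+I 1.144; *Panicum* B 1.119, F 1.123, B+F 1.255 | calibration anchors; encoded as a full map over treatment combinations (not factor products) so non-multiplicative interactions — B+F sitting between B and F — are expressible |
| treatment multipliers (field) | all 1 | the field trial showed no significant treatment effects |
| subject_sd / residual_sd | 0.10 / 0.15 (log scale) | 10–15 % coefficients of variation, realistic for replicated pot trials of forage grasses |
| block_sd | 0.08 | modest field heterogeneity |
| fresh_to_dry_ratio | 3.8 | grasses run ~25 % dry matter at harvest |

The per-harvest multipliers are held constant across harvests (only the
cumulative row of the observed difference table is typographically
unambiguous in our source material, and the relationship between its
"average" and "cumulative" summaries — the harvest weighting — is not
stated; the generator is therefore calibrated to the cumulative
difference only). What the generator does **not** emulate: soil and leaf
chemistry, germination/drought dynamics, root biomass, harvest-specific
effect profiles (the real *Panicum* effects inverted over time), or
attrition. Passing tests therefore demonstrate correct plumbing and
calibrated cumulative effects, not fidelity to every feature of real
trial data.

## Effect statistics

Percent differences use arithmetic means over replicates (the
aggregation is not otherwise specified; fixed and documented). The
cumulative difference sums *harvest means* rather than per-subject sums —
identical under a balanced design, robust if a pot drops out. With the
multiplicative model the per-simulation cumulative percent difference is
a ratio of two noisy means, so it carries a small positive finite-sample
bias (Jensen's inequality on the control mean in the denominator): at
5 replicates and the default noise, about +0.5 percentage points on a
27.4 % effect. Averages over replicate simulations therefore sit slightly
above the configured multiplier; the acceptance computation reports the
estimator as defined rather than a bias-corrected variant.

### Permutation screen

Mixed-effect REML factorial ANOVA is deliberately not re-implemented —
it is off-the-shelf statistics, not this package's contribution. The
package's own inference tool collapses each subject to its total biomass
across harvests and permutes treatment labels across subjects:

* main factor: statistic = |difference of mean subject totals between
  levels|;
* two-way interaction: |m₁₁ − m₁₀ − m₀₁ + m₀₀| of cell means;
* p = (1 + #{perm ≥ obs}) / (n_permutations + 1), so the smallest
  attainable p is 1/(n+1) and the test is valid (super-uniform under the
  null), which simulation confirms at ~5 % rejection at α = 0.05.

Collapsing to totals discards time-by-treatment interactions; the screen
tests overall level shifts only.

## Valuation

`M = ΔB × r × f × p` with f converted to kg DM/ha and p = local price /
exchange rate. Both the unrounded and floor-to-whole-dollar values are
reported; the published worked figures match the floor convention
(ΔB = 0.274, f = 10 → 191.19 → 191). At f = 17 the product is 325.0
while 324 has also circulated for this case — consistent with an
unrounded ΔB upstream; both the computed value and the floor are
reported, nothing is guessed.

Land-sparing carbon supports three accounting methods because the
published per-hectare figure (91 tCO₂eq/ha, also implied by the state
total 16,383,832/180,000 ≈ 91.02) matches neither 443.7 × 0.27 = 119.8
("naive") nor 443.7 × 0.27/1.27 = 94.3 ("proportional"). The default is
`direct` (the packaged 91), with the other two selectable; the choice is
logged in every report's provenance block.

## Production costs

The kiln planner uses whole-day, whole-cycle granularity (partial cycles
do not count — a conservative ceiling). Per kiln, daily cycles are capped
by the kiln's own maximum and by the 8 h/day labour limit; the 44 h/week
limit then caps operating days per week and how many kilns one worker can
tend in parallel. Labour cost is active worker-hours × wage (a scenario
toggle turns it off); equipment is amortized as
`equipment_cost × cycles_used / lifetime_cycles`.

No kiln throughput table is published for the trial's kilns, so the three
shipped presets are **illustrative**, bracketed so that producing one
hectare's 15 t within a 10-day application window requires 150–583 kilns
and 75–210 workers — the observed fleet-size range. They are calibration
brackets, not measured kiln specifications.

Amendment totals (biochar 6,410; fertilizer 893; inoculant 473; lime 74
US$/ha) are packaged calibrated values; components are recomputed from
unit prices (fertilizer: 562.5 kg thermophosphate × 0.3 + 120 kg
potassium sulphate × 6 = 888.75, transport residual 4.25 — the 562.5/120
split is a documented assumption since the printed composite dose 682.5
cannot be exactly reconciled) with transport/overhead as the non-negative
residual. The inoculant's unit price is mutually inconsistent with its
total (10 kg at U$0.45/g ⇒ 4,500 ≠ 473); the total stands and the
inconsistency is raised as a calibration warning by both the cost table
and `validate_config`, never silently reconciled.

## Finance

End-of-period annual discounting at 6 %/yr. Scenario (a) books the
15-month trial gain, pro-rated by 454/365, at year 1; (b) books
G × (1 − t/10) at years 1..10 (zero in year 10); (c) books G for 10
years. The timing/compounding convention is not uniquely determined by
the headline inputs, so the convention above is fixed, documented, and
attached as a caveat to every scenario report; externally published NPV
ranges computed under unavailable supplementary schedules are not
reproduced and not targeted. The break-even carbon price is
max(0, −NPV)/carbon_per_ha with carbon_per_ha defaulting to
91 + 13 = 104 tCO₂eq/ha (land-sparing-only selectable); by construction a
year-0 subsidy of price × carbon closes the NPV to 0, which is tested to
1e-9 relative tolerance.

## Numerical and design choices

* Determinism: every stochastic path takes an integer seed; the pipeline
  derives child seeds (< 2³¹) from one master seed via `SeedSequence`,
  and identical seeds give byte-identical report payloads (no timestamps).
* Degenerate inputs: zero production targets cost zero; zero amendment
  doses cost zero; missing control or empty harvest cells raise
  informative errors rather than NaN propagation.
* Permutation ties count as exceedances (`≥` with a 1e-12 tolerance), the
  conservative direction.
* Config handling rejects unknown keys; validation distinguishes errors
  (invalid values, panicum+inoculant designs) from warnings (the
  documented source inconsistencies), so a default run is warnings-only.
* Problem sizes: calibration checks average 200 simulated experiments in
  the test suite and 500 in the acceptance script — enough to pin the
  mean cumulative difference to a standard error of ~0.3–0.5 points.

## Known limitations

* The effect model is stationary across harvests; real effects varied by
  harvest and (for *Panicum*) changed sign over time.
* The permutation screen is not a substitute for modelling
  time-by-treatment structure.
* Kiln presets are illustrative brackets, not measured equipment.
* Single exchange rate and meat price; no price dynamics, herd model, or
  life-cycle GHG accounting of biochar production.
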