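# Methods

## Model

`pscea` implements a two-arm, three-state cohort cost-effectiveness model on
a monthly cycle: progression-free (PFS), progressed disease (PD), and death.
State occupancy is obtained by partitioned survival rather than by
estimating a transition matrix — at every month t

    occ_pfs(t) = S_pfs(t),   occ_pd(t) = S_os(t) − S_pfs(t),
    occ_dead(t) = 1 − S_os(t),

where S_os and S_pfs are the arm's overall-survival and progression-free
survivor functions. This embeds the usual partitioned-survival assumptions:
no back-transition from PD to PFS, and PFS ≤ OS pointwise (enforced on
input and after any survival rescaling; violations are errors, never
silently clipped). Monthly conditional transition probabilities,
`tp(t) = 1 − S(t)/S(t−1)`, are derived only where needed — to rescale
survival in sensitivity analyses and to drive the microsimulation test
oracle. When `S(t−1) = 0` the probability is defined as 1; the state is
empty, so the convention cannot affect any output.

The cohort is followed to extinction: residual survivors at the horizon are
moved to death one cycle later (`ArmCurves.with_terminal_death`). Cohort
arithmetic is on fractions; a 1000-patient cohort is a presentation scaling
by linearity.

## Synthetic survivor curves

The trials behind the shipped configuration published their Kaplan–Meier
curves only as figures, so the generator builds constant-hazard
(exponential) stand-ins matched to the printed medians:
`S(t) = exp(−ln 2 · t/median)`. With only medians published, the
exponential is the one-parameter family that uses exactly the available
information; a Weibull shape parameter exists as an extension hook and
defaults to 1. Defaults: FOLFOX4 OS median 6.40 months, PFS 2.93 (the
Chinese-subgroup values 5.9/2.4 can be substituted); sorafenib OS 6.5. The
sorafenib PFS median was never published — it is a mandatory user argument
with no default, because any default would be invented. Examples and tests
use 2.8 months, labelled as an assumption. Default horizon is 60 months,
with a warning when `S_os(60) > 0.001` (the default medians leave ~0.15%
of the cohort alive there, which the terminal-death rule then removes).

`binomial_km_noise` emulates finite-trial sampling error by sequential
binomial thinning at the input curve's conditional survival; it preserves
the curve invariants and matches the input in expectation.

What the synthetic curves do *not* reproduce: the shape of the real KM
curves (plateaus, crossing hazards, censoring artefacts). Consequently the
headline per-arm totals and QALYs of the shipped configuration differ from
the published ones, and — because the sorafenib OS median (6.5) slightly
exceeds FOLFOX4's (6.40) — the base-case QALY difference can take the
opposite sign under exponentials. Tests that pass on synthetic curves
validate the pipeline's accounting, not the clinical conclusion.

## Costing conventions

- **BSA dosing.** BSA = 0.0061·height(cm) + 0.0128·weight(kg) − 0.1529 m²;
  the reference patient (161.5 cm, 61.8 kg) gives 1.62329 m², hence
  per-cycle doses of 138 mg oxaliplatin, 649 mg leucovorin and 3247 mg
  fluorouracil. Rounded doses are for reporting; pricing uses exact mg.
- **Drug pricing.** Proportional (per-mg) pricing is the default because it
  is the only convention that reproduces the published monthly costs;
  `whole_pack` rounds packs up per cycle for wastage scenarios and is never
  cheaper. FOLFOX4 runs 2.14 cycles/month as printed (an `exact_30_14`
  switch gives 30/14). The computed FOLFOX4 monthly cost is $1869.7 vs the
  printed $1865; the gap traces to the printed 5-FU monthly cost ($132),
  which is not derivable from the printed $8/400 mg unit cost (~$139) —
  treated as unit-cost rounding in the source and left as computed.
- **Cost scope.** Drugs, general ward, tests and AE treatment accrue only
  while progression-free (treatment stops at progression); PD carries no
  modelled cost. This is confirmed by an internal reconciliation: the
  published discounted drug total ($6972) at $1865/month implies 3.74
  discounted PFS person-months, and the same 3.74 reproduces the published
  test total ($155 × 2.14 × 3.74 ≈ 1240 vs 1242) and ward total
  (39 × 3.74 ≈ 146 vs 145).
- **Ward billing.** The cost table footnote reads "5 days per cycle", but
  the published ward total and the sensitivity table's "per cycle base 39"
  are only consistent with ~$39–40 per month; the default therefore bills
  5 days × $8 per month, with `ward_per="cycle"` available for the literal
  footnote reading.
- **Adverse events.** Each AE is charged once per patient in expectation
  (trial-period incidence × per-event cost). AEs marked as treated in the
  same encounter (nausea/vomiting with AST/ALT abnormality) contribute
  their combined cost once, at the higher incidence. The lump is spread
  over cycles proportional to survivors, conserving the total exactly. The
  published per-patient AE totals ($69/$4) are not reconcilable with any
  parse of the AE table (ours gives ≈$186/$32); the AE column layout is
  typographically ambiguous, the shipped parse is a documented best guess,
  and no AE total is asserted anywhere.

## Accrual, discounting, utilities

Patients leaving a state do so on average mid-cycle and accrue half that
cycle's costs. On a cohort trace this is exactly the per-state trapezoid
`(occ(t−1)+occ(t))/2 × monthly amount`, which is how the engine computes
it. By default the same half-cycle credit applies to utilities so QALYs and
life-months stay internally consistent; `costs_only_half_cycle=True`
restricts it to costs (utilities then accrue on end-of-cycle occupancy).
Utilities are 0.76 (PFS), 0.68 (PD), 0 (death) per year. The PFS ≥ PD
ordering is not hard-enforced because the published one-way range for the
PD utility (up to 0.82) crosses the base PFS utility.

Discounting is 5%/year. The source states neither cycle timing nor the
monthly conversion; the default discounts cycle t by
`(1+r)^(−(t−0.5)/12)` (annual compounding, mid-cycle), with a
`yearly_step` mode `(1+r)^(−floor((t−1)/12))`. The modes differ by well
under 1% at these horizons (asserted in tests).

## Comparison and perspectives

ΔC and ΔE compare intervention minus comparator. Opposite signs mean
dominance and no ICER is formed; ΔE = 0 yields an explicit `undefined`
marker, never a division or ±inf. INHB(λ) = ΔE − ΔC/λ and
NMB(λ) = λE − C satisfy NMB₁ − NMB₀ = λ·INHB identically. The 3×-GDP
threshold is kept at the printed US$ 22,073 (not 3 × 7358 = 22,074); both
constants are exposed.

The patient perspective multiplies each cost component by its copayment
share. The narrative rule (25% outpatient drugs/AE, 15% inpatient
ward/tests) does not reproduce the published patient totals; the default
`reconciled` map (FOLFOX4 drugs+ward 15% as inpatient care, everything
else 25%) reproduces $1395.3 and $3199.3 against the printed $1395/$3200.
The literal map is retained as `literal_text` to document the conflict.

## Sensitivity analyses

One-way analysis re-evaluates the model at each parameter's published low
and high, reporting INHB at λ = 22,073, sorted into a tornado. The PSA
draws all parameters jointly, 1000 draws by default: gamma for costs
(moment-matched, shape = (mean/sd)², scale = sd²/mean), normal for doses,
utilities and survival multipliers, truncated to each parameter's domain
by redrawing rather than clipping. Survival uncertainty is a per-arm
multiplier f applied as `tp → clip(tp/f, 0, 1)` to the PFS and OS monthly
transition probabilities simultaneously (f > 1 is better survival); the
division convention is used because the published variation acts on
transition probabilities, not medians. Draws producing invalid scenarios
are redrawn and counted; >10% redraws is a hard error.

The printed SD column is authoritative by default even where it
contradicts the narrative 20%/60% rule (e.g. the comparator's monthly-cost
SD is ~30% of base); `sensitivity_specs_from_cv` regenerates the table
under the narrative rule instead. The tabulated base values carry the
published roundings ($1865/month, ward $39, doses in whole mg) and so
differ slightly from the model's internally computed base quantities
($1869.7, $40, exact mg); the degenerate (all-SD-zero) PSA therefore
reproduces, exactly and float-for-float, the deterministic model evaluated
at that same tabulated base vector. Because the model's monthly drug cost
is itself a function of doses, a drawn arm-level monthly cost acts as a
price-level multiplier (draw/base) that composes with independently drawn
doses — both published rows remain active without double-counting.
Boundary PSA draws (a zero delta) are never counted as dominant.

## Numerical choices and degenerate inputs

Curve invariants are validated with tolerance 1e−9; occupancy conservation
holds to 1e−9 and the curve↔TP round trip to 1e−12. ICER with ΔE = 0 is a
label, not a number. An all-dead-at-month-1 trace puts the whole AE lump
in cycle 1. Equal OS and PFS medians give a model that never occupies PD,
in which case QALYs equal 0.76/12 per life-month exactly.

## Verification strategy

The engine is cross-checked against a per-patient microsimulation oracle
(10⁶ patients driven by the monthly transition probabilities with the same
half-cycle and discounting rules, agreement within 3 Monte-Carlo standard
errors on 5-cycle toys), and the costing conventions against the internal
reconciliation of the published cost table above. Property tests cover
hazard constancy of generated curves, conservation of the AE allocation,
order preservation of the survival multiplier, discount monotonicity, and
the net-benefit algebra. Problem sizes in the test suite (10⁶-patient
microsimulations, 10⁵-draw moment checks, 1000-seed noise averages) were
chosen to make 3-standard-error bands decisively tighter than the effects
being checked.

## Known limitations

No AE disutilities, dose reductions or interruptions, grade-stratified AE
costs, tunnel states, or time-varying utilities; no multi-arm frontier or
extended dominance; no EVPI or correlated PSA draws. The synthetic
exponential curves carry none of the published trials' curve shape, so the
shipped configuration demonstrates and tests the method rather than
re-establishing the published clinical comparison.
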