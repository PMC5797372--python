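# Methods

`abqsp` implements a quantitative systems pharmacology (QSP) analysis of how
amyloid-beta low-order aggregates (monomer/dimer/trimer pools of Aβ40 and
Aβ42) shape cognition in Alzheimer's disease, and of what that implies for
amyloid-modulating therapies. This note describes the model, its parameters,
the calibration, the numerical choices and the known limitations.

## Load scale and coupling relations

Aβ40 load `x` and Aβ42 load `y` live on an arbitrary 0–16 unit grid; one
unit is defined kinetically as the amyloid accrued in 13 weeks by an
untreated APOE4 heterozygote. The two couplings are:

* **NMDA conductance** (excitatory–excitatory synapses), biphasic in Aβ40:

  g/g₀ = 1 + δ·(x/x₀) − α*·y            for x ≤ x₀
  g/g₀ = 1 + δ + α·(x₀ − x) − α*·y      for x > x₀

  with peak position `x₀` (default 2 units), maximal relative benefit `δ`,
  post-peak slope `α` and Aβ42 slope `α*` (all per unit of load). With
  `x₀ = 0` only the declining branch is used (peak at the origin), which
  avoids the division. The ratio is floored at 0; no ceiling is applied.

* **α7 nAChR activation**, symmetric in both isoforms:
  activation/activation₀ = max(0, 1 − β·(x + y)).

The constrained "final" set is x₀ = 2, δ = 0.025, α = α* = 0.002, β = 0.03;
the MCI/SUVR-calibration set is δ = 0.015, α = 0.0015, α* = 0.00035,
β = 0.025. Aβ40 and Aβ42 concentrations differ ~10-fold in vivo, so the two
unit scales likely differ by a similar factor; the equations treat units
symmetrically and no conversion is applied.

Evaluating both relations on every integer cell gives a 17×17 effect
matrix. The amyloid-negative/-positive split uses the both-axes rule
(Aβ−: x < cutoff and y < cutoff; Aβ+: x ≥ cutoff and y ≥ cutoff, mixed
cells excluded), cutoff 3 units by default; a complement mode (Aβ+ =
everything outside the Aβ− box) is provided because the population can
also be defined that way.

## Deposition, interventions and quadrature

Deposition is linear in trial time: 0.5 / 1.0 / 1.5 units per 13 weeks for
APOE4−/−, +/− and +/+ respectively, identical on both axes, clamped at the
top of the grid. An intervention removes a fixed fraction of accrual per
isoform — its trial-reported soluble-peptide change, assumed at steady
state from week 0 and never removing baseline load. The shipped dose
library: BACE inhibitor 80 %/60 % (low) and 90 %/80 % (high) for
Aβ40/Aβ42; gamma-secretase inhibitor 40 %/20 % (low, the worked case) and
50 %/30 % (high); solanezumab 5 %/30 % (low) and 10 %/50 % (high).

Treated arms land between integer cells. Matrix values are read per axis
through three-point weights on consecutive cells fixed by three
constraints: they sum to one, the centre weight is 1/3, and their weighted
mean equals the effective load (closed form: on support {m−1, m, m+1} with
load L, w_low = 1/3 + (m−L)/2 and w_high = 1/3 − (m−L)/2). The constraints
make the sampling exact for any affine function of load, and negative
weights (mild extrapolation) are legal. Window anchoring: placebo arms and
integer loads centre on round(L); reduced-deposition arms centre one cell
ahead (floor(L)+1), the cell the untreated dynamics is heading to — the
anchoring that reproduces the worked weighting factors (0.73, 0.33, −0.06)
and (0.64→0.63, 0.33, 0.03) for a low-dose BACE step from load 4. At the
grid edges the window shifts inward, keeping both moment constraints. The
third Aβ40 weight is −0.0667, which rounds to −0.07; the corresponding
published rounding is −0.06, a known one-digit discrepancy (the same
arithmetic yields 0.6333 where 0.64 is printed).

## The cognition surrogate

The original platform maps neurophysiology to ADAS-Cog through a
biophysical cortical network (80 pyramidal cells, 40 interneurons) that is
out of scope here; `abqsp` replaces it with a calibrated latent-reserve
surrogate. A scalar reserve R (percent-equivalent units; 0 = healthy
cognitively normal) aggregates the state, and two logistic links map R to
the instruments:

* ADAS-Cog = 70·σ(−(R − adas_mid)/adas_scale) — 0–70 points, monotone
  decreasing in reserve;
* 2-back accuracy = 100·σ((R − acc_mid)/acc_scale) — 0–100 %, increasing.

Structural terms enter linearly: synapse density (APOE modifier ±20 %,
trial loss 0.04 %/week), neuron density (0.35 %/week), cholinergic tone
(+30 % compensation in MCI, −30 % deficit in AD), plus a fixed
established-pathology offset for the AD stage. Amyloid enters through two
channels:

**Static (MCI) channel.** The consolidated effect of living at a load:
`g_mci`·gpct·attn − a7_max·S(d), where gpct = 100·(g/g₀ − 1), d is the α7
activation deficit, and

* S(d) is a two-component saturation (half-effects `a7_half` ≈ 0.02 and
  `a7_half_slow` ≈ 0.2–0.5): a high-affinity component producing the steep
  loss over the first units of load and a low-affinity one keeping the
  response graded across the grid;
* attn = 1/(1 + (x+y)/attn_load_half) attenuates the glutamate channel at
  high load — at strong amyloid modulation the range available to express
  a further % conductance change shrinks;
* conductance **gains** above baseline are discounted by `mci_gain_frac`:
  a near-intact network has little headroom for enhancement, while
  deficits register in full. This asymmetry is what lets a strong benefit
  removal (δ → 0) push the Aβ+ mean far out of the clinical band while the
  Aβ− population, which enjoys the benefit, moves much less.

**Trial (AD) channel.** A purely instantaneous map cannot reproduce the
intervention contrasts: at any common week a treated arm's amyloid state
is component-wise no worse than placebo's (lower Aβ42, higher α7
activation, Aβ40 on or below the post-peak branch), so any monotone
instantaneous surrogate makes treated ≥ placebo — yet suppressing
deposition from a low baseline worsens outcomes. The surrogate therefore
accumulates a *functional burden* B(t) on a weekly grid:

dB = p(t)·slack(B)·[ lost_stim_weight·L(t)·dstep + dD ]

* D(t) = a7_burden·a7_max·S(d) − mult(t)·attn·gpct is the transmission
  deficit; its *increments* are stamped in at the glutamate sensitivity of
  the week they occur (`glu_profile`, calibrated at weeks 0/12/26/52/78,
  interpolated linearly), making the burden path-dependent;
* L(t) = mult(t)·attn·100·δ·(1 − min(x, x₀)/x₀) is the *unrealized Aβ40
  stimulation* — nonzero only while the load sits under the peak, the
  regime in which suppressing deposition forfeits the stimulatory effect.
  This level term is what makes BACE inhibition from a near-zero baseline
  costly, and it vanishes identically for all trajectories that start at
  or above x₀, which keeps APOE genotype trajectories parallel;
* slack(B) saturates the burden on both sides: accumulated deficit at
  `burden_sat` (network redundancy is finite) and accumulated net benefit
  at `benefit_cap` ≈ 4.5 reserve points, the mechanism behind treatment
  effects saturating at roughly 1.5–2 ADAS points;
* mult(t) are the printed APOE glutamate-sensitivity multipliers (+11 %,
  +3 %, +1 %, −8 %, −10 % for +/+ vs −/− at the five anchor weeks,
  heterozygotes midway), interpolated linearly.

The reported ADAS sensitivity to a 1 % conductance change is computed by
finite difference of the full surrogate at the placebo state of the given
week; it equals p(w)·attn·slack·|dADAS/dR| and reproduces ≈0.65
points/% at weeks 12–26 versus ≈0.40 at weeks 52–78, with week 0
intermediate.

## Calibration

`calibrate_surrogate` is a weighted least-squares fit (scipy trust-region
reflective, fixed multi-start, deterministic) of 18 free constants to an
anchor set of clinical values: healthy-control ADAS 4.5; best-performance
MCI 4.1; MCI region averages 7.4/10.4 (calibration set, cutoff 3) and
their final-set counterparts biased to the upper half of the 8.5±1/10.7±1
condition bands; the δ = 0 variants; AD baselines 20.2/21.0/22.0 by
genotype with a 1.8-point homozygote gap; placebo 78-week worsening 9.25
(range 8.5–10 across baselines, softly); the five glutamate-sensitivity
values; the APOE slope-spread at and without the benefit; and the
low-baseline BACE-inhibitor contrast −1.5 points. Anchors may be
two-sided or one-sided bounds; the fit aborts with a report naming the
worst anchors whenever any residual exceeds its stated tolerance.

`calibrate_receptor` then fits the cholinergic drive magnitudes (M1
weight, GABA weight, M2 feedback gain) and the accuracy-link position to
the four printed challenge slopes (−1.08/−1.36 %/nM with the benefit,
−1.54/−1.42 without) plus a 75 %-correct drug-free baseline, with hinge
terms encoding the printed δ ≥ 0.02 threshold of the differential
sensitivity. The accuracy-link midpoint is constrained to a window,
derived from an exhaustive ordering-pattern scan, in which the dose sweep
straddles the link's steep zone for the amyloid-positive population only
while the Aβ40 benefit is present — the geometry that produces both the
with-benefit ordering and the δ = 0 reversal.

Both fits are serialized with their anchor residuals to
`src/abqsp/params/defaults.yaml`; `abqsp calibrate` regenerates the file,
and a test asserts that refitting reproduces the shipped values exactly.

**Disclosed circularities.** The MCI region averages, placebo worsening,
glutamate sensitivities, APOE spread and the low-baseline BACE contrast
are calibration anchors; downstream checks of those numbers are
consistency checks of the fit, not predictions. The genuinely emergent
surface is: the condition map across the coupling grid away from the
anchored cell, the scopolamine ordering across the stated parameter
region, the GSI/solanezumab contrast signs and the arm/dose orderings,
and the saturation of contrasts at extreme baselines.

## Receptor competition model

Scopolamine competes with acetylcholine at equilibrium:
act = ACh/(ACh + K·(1 + scop/Ki)), Ki = 1.1 nM (M1) and 1.22 nM (M2).
Baseline ACh is set at its half-activation concentration (100 nM scaled
by cholinergic tone), folding the firing-rate physiology of the original
description into equilibrium constants. Blocking the presynaptic M2
autoreceptor releases negative feedback on ACh release: the ACh
multiplier rises from 1 toward 1 + γ with M2 occupancy loss (closed form,
no fixed-point iteration). Elevated ACh increases α7 drive (scaled by the
amyloid activation factor, so heavily amyloid-inactivated synapses are
rescued less) and α4β2 drive (raising GABA tone, a deficit). Challenge
curves average 2-back accuracy over the region's grid cells at 11 doses
spanning 0–10 nM, summarised by an OLS slope.

## Clinical constraint conditions and the grid scan

Condition 1: some integer cutoff < 4 puts the MCI region averages inside
8.5 ± 1 (Aβ−) and 10.7 ± 1 (Aβ+). Condition 2: |slope(Aβ+)| >
|slope(Aβ−)| for the scopolamine challenge at cutoff 3. Condition 3: all
pairwise APOE trajectory-slope differences ≤ 10 % (relative to the larger
slope) and a week-0 homozygote gap ≥ 1.5 points at baseline 4 units. The
default scan covers δ ∈ {0…0.03}, α, α* ∈ {0.0005…0.0025}, β ∈
{0.005…0.035} at x₀ = 2 (700 cells, ~2 s) and is a pure map over cells.

With the shipped calibration the final parameter set satisfies all three
conditions, the all-met region is non-empty, and the δ = 0 exclusion
holds for 98 of 100 δ = 0 cells. Two honest failures remain, analyzed
rather than patched:

* **Residual δ = 0 cells.** At (δ = 0, α = α* = 0.0005, β ≥ 0.025) the α7
  plateau alone places both region means inside the condition-1 bands.
  Excluding them via condition 1 would need the Aβ+ mean at that corner to
  exceed 11.7 while staying ≤ 11.7 at the final set; the slope-and-β
  footprint between the two corners outweighs the δ footprint, so the two
  requirements are jointly infeasible in any response surface with a
  shared sensitivity. Excluding them via condition 2 would require an
  ordering boundary that is non-monotone in population depth, which no
  accuracy-link geometry provides (an exhaustive midpoint/scale scan found
  no feasible point).
* **Frontier location.** The published frontier (all three conditions only
  for δ > 0.02 and α + α* > 0.003) presumes the Aβ+ elevation is driven
  from below by the Aβ42/post-peak slopes; the published δ = 0 region
  means instead force a large α7/δ-footprint contribution to that
  elevation. Both cannot hold in one surface, and the shipped fit, which
  honors the δ = 0 means, admits all-met cells at weaker slopes.

## Trial conventions

Evaluation weeks default to {0, 12, 26, 52, 78}; cohorts are
patient-matched across arms; contrasts are intervention-minus-placebo in
"points better than placebo" (positive = benefit); ADAS outcomes are
reported to 0.1 point. The SUVR map is linear, anchored at 0 units → SUVR
1.0 and 3 units → 1.34 (florbetapir); the alternative published
identification of "low amyloid" as SUVR < 1.1 corresponds to < 0.9 units
on this map, not to the 3-unit cutoff — the two statements are not
mutually consistent and the 1.34 anchor is authoritative here.

With the shipped calibration, at a high baseline (8 units) all three
therapies beat placebo at 78 weeks, ordered BACE-I > GSI > solanezumab,
and contrasts at baseline 12 stay under 2.5 points. At an
amyloid-negative baseline, BACE inhibition ends worse than placebo (−1.5
points from a zero-load start; a small net worsening for the mixed
sub-cutoff cohort) while the gamma-secretase inhibitor and solanezumab
end between 0 and +0.5 — solanezumab's published range itself extends to
a 0.5-point improvement, but a strict "all three worsen at 78 weeks"
check fails for those two arms and is left failing.

## Synthetic cohorts

Virtual patients carry an APOE genotype (default mix 0.25/0.50/0.25 for
−/−, +/−, +/+; none is published, so a symmetric, configurable default is
used) and a baseline load drawn from a fixed point, a uniform region of
the grid, or an arbitrary 17×17 probability table. Optional Gaussian
ADAS measurement noise is applied to outcomes only (never loads) and
clipped to the 0–70 instrument range; all randomness flows from one
integer seed via `numpy.random.default_rng`. The generator emulates
enrollment composition only — no demographic covariates, dropout,
comorbidity, or load-measurement error — so passing cohort-level tests
demonstrates pipeline correctness, not realism of between-patient
variability in real trials.

## Numerical choices

Burden integration: trapezoidal/Euler on a weekly grid (the integrand is
piecewise-smooth; weekly resolution is well below the 13-week deposition
scale). Quadrature identities hold to 1e−12 and are property-tested.
Finite differences for the conductance sensitivity use a 1e−3 step on the
% scale. OLS slopes use `numpy.polyfit` over the evaluation weeks.
Degenerate inputs: x₀ = 0 switches to the declining branch; empty regions,
non-ascending dose or week grids, out-of-range loads, reductions outside
[0, 1] and invalid genotype frequencies raise `ValueError` with the
offending quantity named.

## Known limitations

The surrogate is a reduced form: no spiking dynamics, no receptor-level
kinetics, no donepezil co-medication, no Aβ aggregation kinetics or
rebound, no tau/vascular pathology, no spatial PET modeling. The
cumulative-burden formulation is one defensible resolution of the
path-dependence the trial contrasts demand; other histories (e.g.,
activity-dependent synapse loss) would fit the same anchors differently.
Magnitudes of intervention contrasts are calibration-dependent; their
signs and orderings are the scientifically meaningful output. The
tensions documented above between published constraint claims are
inherent to reconstructing a network-based analysis from its printed
summaries and are surfaced by failing tests rather than hidden.
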