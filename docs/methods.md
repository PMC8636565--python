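# Methods

## Problem

TNF stimulation drives nuclear translocation of NF-κB; its target genes
respond with widely different time courses, and knocking down the negative
feedback regulator IκBα (siIkBa) — which prolongs nuclear NF-κB — paradoxically
*reduces* the induction of many targets. `grmfit` infers, per gene, which of
four transcription-regulatory mechanisms best explains a measured expression
time course given the measured nuclear NF-κB input:

1. **simple** — Hill-type activation by delayed nuclear NF-κB:

       d[mRNA]/dt = k_syn · (K_D·NFkB(t−τ))^h / ((K_D·NFkB(t−τ))^h + 1) − k_deg·[mRNA]

2. **iffl** — an incoherent feedforward loop: NF-κB also induces a competitor
   transcription factor (p50) that competes for the target promoter,

       d[TF]/dt   = (K_DTF·NFkB(t−τ))^h_TF / ((K_DTF·NFkB(t−τ))^h_TF + 1) − k_degTF·[TF]
       d[mRNA]/dt = k_syn · N₁ / (N₁ + N₂ + 1) − k_deg·[mRNA],
       N₁ = (K_D1·NFkB(t−τ))^h,  N₂ = (K_D2·TF(t−τ_TF))^h

3. **cycle3** — a three-state promoter cycle closed (C) → open (O) → active
   (A) → closed, with backward steps and a saturating A→C return flux,
   driven by the *undelayed* input; mRNA is synthesized from the delayed
   active fraction, d[mRNA]/dt = k_syn·A(t−τ) − k_deg·[mRNA].

4. **v4** — the promoter cycle (state equations driven by the *delayed*
   input) combined with the IFFL competitor acting on the synthesis term,
   d[mRNA]/dt = k_syn·A(t−τ)^h / (A(t−τ)^h + (K_DTF2·TF(t−τ_TF))^h + 1) − k_deg·[mRNA].

The asymmetry between cycle3 (undelayed state drive) and v4 (delayed state
drive), and the delayed-TF term in the iffl TF equation, are part of the
model definitions and are reproduced verbatim rather than harmonized.

Fixed constants: `h = 1, k_syn = 1` (simple); `h = 2, h_TF = 1,
k_degTF = 8.022537e-6 s⁻¹, K_DTF = 100, τ_TF = 7200 s` (iffl, v4);
`k₋₁ = 0.01·k₁, k₋₂ = 0.01·k₂, k₋₃ = 1 s⁻¹, K_D3 = 0.5` (cycle3, v4).
τ_TF is the 2-h processing delay of the p50 competitor. Free-parameter
bounds: `k_deg ∈ (2e-5, 2e-3) s⁻¹`, every `K_D ∈ (0.001, 1000)`,
`τ ∈ (0, 7200) s`, `k₁ ∈ (6e-5, 6e-3) s⁻¹`, `k₂ ∈ (0.007, 69.31) s⁻¹`
(69.315 for v4 — kept per model as specified upstream).

## Input preparation

Raw nuclear-NF-κB time courses (minutes, per condition and replicate) are
background-subtracted (a constant strictly below the series minimum;
default 0), converted to fold change relative to t = 0, and affinely
rescaled to span 2–100. Replicate 1 is rescaled with a single map from the
pooled min/max of both conditions; replicate 2 — systematically dimmer,
with its raw maximum at late siIkBa times — is anchored to its own control
range, so its control spans exactly 2–100 and its siIkBa series may exceed
100. The scaled series are interpolated to 1-s resolution with monotone
cubic (pchip) interpolation; for t < 0 the grid holds the t = 0 value
(pre-stimulus steady state). The 2–100 range and the replicate-specific
scaling rules follow the upstream assay-normalization procedure.

## Simulation

Simulation runs from −60 min (start of the steady-state window) to 180 min,
initialized at the steady state under the constant pre-stimulus input; the
promoter-cycle equilibrium is reduced to a single bracketed root in A and
solved to machine precision. The cascade structure (input → TF/states →
linear mRNA balance) allows layer-by-layer integration on the 1-s input
grid instead of a general delay-ODE solver:

* linear balances (mRNA, TF) are advanced with the exact per-step solution
  for a piecewise-linear drive (exponential integrator; series-evaluated
  step coefficients avoid cancellation at small rates);
* the promoter-state pair (O, A) uses classical RK4 — 2-s macro steps when
  the fastest local rate allows, 1-s steps with stability substepping
  otherwise — and an A-stable exponential (Rush–Larsen-type) update in the
  stiff regime (fast rate ≥ 3 s⁻¹, where the open state is quasi-static).
  C = 1 − O − A is eliminated analytically, so conservation holds to
  machine precision by construction.

Cross-checked against `scipy.integrate` at rtol 1e-10: relative state error
< 1e-7 (non-stiff), ≤ 3e-4 (stiff draws). Delays are whole-second index
shifts with the pre-window value held constant. mRNA fold change is taken
relative to t = 0; MFI (max fold induction) and AUC (trapezoid over
0–180 min) summarize each condition.

## Objective and two-step fitting

For a candidate parameter vector both conditions are simulated; simulated
and measured fold changes are max-normalized jointly over the two
conditions (the pooled series spans [0, 1], preserving the ctrl:siIkBa
amplitude ratio); the objective is the RMSD of the target condition's
normalized series (nRMSD) plus the steady-state drift |m̂(0) − m̂(−60 min)|
on the same normalized scale. Failed simulations return a large sentinel
(1e6) so the derivative-free search continues.

Per gene, model and replicate:

1. **Stage 1** (control target): initial vectors are drawn log-uniformly
   (τ uniformly) inside the global bounds; to make a reduced multistart
   budget effective on these multi-decade landscapes the protocol draws a
   15-fold candidate pool, evaluates the objective once per candidate and
   starts local searches from the best `n_starts` (importance-screened
   starts). Each start is optimized with a bounded derivative-free local
   search.
2. Records with control nRMSD < 0.5 (escalating to 0.6 then 0.7 when fewer
   than two survive; the two best records as a last resort) define
   narrowed per-parameter (min, max) bounds.
3. **Stage 2** (siIkBa target): a fresh screened multistart inside the
   narrowed bounds; every record is finalized with both conditions' nRMSD
   plus MFI/AUC from the fitted simulation.

When the pipeline fits both replicates, replicate 2's stage-2 multistart
seeds up to half its starts with replicate 1's optimized parameter sets
(clipped into replicate 2's bounds).  The replicates share the expression
data and differ only through the NF-κB input, so replicate-1 optima are
near-optimal replicate-2 starts; the seeding also anchors the weakly
identified parameter directions to common values across replicates, which
is precisely what the concordance score rewards.

The local optimizer is Powell's bounded conjugate-direction search in a
transformed space (log10 for rates and affinities, kiloseconds for τ) with
relative tolerance 1e-4; it reaches the attracting basin from random starts
markedly more often than a simplex at the same evaluation budget, which is
what limits fit quality at reduced budgets. The library default follows the
full protocol (100 starts per stage, 2000-evaluation cap); the desk
configuration used by the synthetic benchmarks runs 20 starts per stage
with caps of 250 (stage 1) and 120 (stage 2) evaluations.

## Concordance across replicates

All stage-2 records of replicate 1 are paired with all of replicate 2
(100 × 100 = 10,000 pairs at the full budget). Each pair is scored by
(i) the larger/smaller ratio of each scored rate or affinity parameter,
(ii) the delay difference |τ₁ − τ₂|, and (iii) the summed nRMSD of the two
records (each record contributes control + siIkBa of its own replicate's
finalized fit); the pair minimizing the total is the gene's concordant
pair. Scored parameters: `k_deg, K_D` (simple); `k_deg, K_D1` (iffl — K_D2
only rescales the near-constant competitor term and is not identifiable
from fold change); `k₁, k₂, k_deg` for the promoter-cycle models on
subcluster-2-like response genes, all free rates/affinities otherwise.
The pipeline expresses the delay term as |Δτ|/7200 (fraction of the delay
bound) so it is commensurate with the dimensionless ratio and nRMSD terms;
with the raw per-second convention the delay difference dominates the score
by 2–3 orders of magnitude and pair selection degenerates to τ-coincidence.
`score_pair` retains the raw convention via `tau_weight=1.0`. Ties break
deterministically (lower nRMSD sum, then lower pair index).

## Classification

A (gene, model) concordant pair is a good fit iff control nRMSD < 0.5 and
siIkBa nRMSD < 0.39 in both replicates (strict inequalities) and the fitted
simulation shows the stronger induction in control (MFI or AUC, replicate 1
by default). Among good-fit models the best fit minimizes the total nRMSD
(four components); genes without a good-fit model are "unexplained" and
reported with their simple-model fit attached.

## Synthetic data

The generator emulates the study conditions. Control NF-κB: baseline 1 plus
two log-normal pulses — dominant peak 10× at 30 min, trough near 75 min,
dampened second peak 5× at 120 min (the distinct second peak is what
separates promoter-cycle refractoriness from input-tracking in the fits).
siIkBa: saturating rise (~60 min) to a 4.5× plateau — prolonged activity at
clearly lower fold change, the defining knockdown phenotype. Replicate 2 is
0.7× dimmer with mildly (a few percent) different pulse widths, second-peak
height and knockdown kinetics; the amplitude scaling is undone exactly by
the min–max rescaling, so the residual shape difference is what the
concordance step has to bridge. Large shape differences are deliberately
avoided: an input mismatch that no parameter set can absorb rewards
over-parametrized mechanisms (which bend to either input) over the true
one, biasing model selection — a property of the nRMSD-sum rule, which
carries no complexity penalty.

Gene tables carry one expression series per condition (the study models the
replicate-mean expression; the two fitting replicates differ through the
NF-κB input), simulated with the replicate-1 grids at 13 samples
(0–180 min, 15-min steps), optionally degraded by mean-one multiplicative
log-normal noise (default CV 0.1 where noise is requested; benchmark
cohorts use CV 0 so that fit-quality differences reflect the mechanisms,
not the noise draw).

Per-model "typical gene" parameters are chosen so the cohort shows the
subcluster-2 phenotype (MFI or AUC higher in control at the true
parameters, verified for every gene) with mechanism-typical dynamics, and
so the mechanisms occupy different response classes: the simple genes sit
in the concave h = 1 class (siIkBa/control amplitude ratio ≥ the input
ratio); iffl genes in the quadratic fold-change-detection class (ratio ≈
squared); the promoter-cycle genes combine a slow open-state integrator
(k₂·occupancy ≈ 1e-3 s⁻¹, a ~20-min low-pass) with fast mRNA turnover — a
slow-rise/fast-decay asymmetry that a single first-order filter cannot
reproduce; v4 adds the quadratic active-state drive. Parameters are
jittered per gene (±0.1 log10 units; ±300 s for τ) and clipped inside the
bounds. What passing benchmarks on this cohort does *not* show: robustness
to measurement noise, to replicate-discordant expression, or to genes whose
true mechanism lies outside the four-model family.

## Numerical and design choices

* Delays are rounded to the grid second; the 1-s resolution bounds the
  induced error.
* The v4 competitor trajectory depends only on the input and fixed
  constants and is cached per input grid.
* Bound handling: parameter vectors are clipped to the global bounds before
  simulation (guards against float fuzz at bound edges, which would
  otherwise wall off the search with sentinels).
* The steady-state penalty is evaluated on the normalized fold-change
  scale; with steady-state initialization it is structurally ≈ 0 and acts
  as a guard against inconsistent initialization.
* Degenerate stage-1 survivor sets (all coincident in a coordinate) widen
  that bound by a small epsilon so stage-2 sampling stays well defined.
* Count normalization (reads → TPM): counts per kilobase, then division by
  library size × RLE normalization factor. The built-in factors are
  DESeq-style median-of-ratios estimates made depth-free (divided by
  library size, unit geometric mean) so the product S·N separates depth
  and composition; explicit factors are accepted verbatim for replicating
  externally computed normalizations.

## Benchmarks and problem sizes

`scripts/acceptance.py` reruns two desk-scale benchmarks from scratch
(20 screened starts per stage, caps 250/120): (i) mechanism identification
on a 20-gene mixed cohort (5 genes per model, zero noise) through the full
pipeline — reporting the fraction of genes whose best-fit call matches the
generating model and the worst siIkBa nRMSD among good-fit genes; and
(ii) k_deg recovery on 20 zero-noise simple-model genes (replicate 1),
reporting the fraction recovered within a factor of two. These sizes keep
a full rerun on one CPU in the tens of minutes; the 100-start protocol is
the library default for real analyses.

## Known limitations

* The promoter-cycle models are only weakly identifiable from 13-point
  fold-change series: k₁ rescales out of the fold change in the
  low-occupancy regime, and k₂ and K_D2 trade off along a ridge. The
  concordance step mitigates but does not remove this.
* With the fixed competitor constants, TF(t−τ_TF) is nearly constant over
  the 3-h window, so the IFFL acts as a static quadratic response rather
  than a dynamic fold-change detector; this is a property of the printed
  constants, not of the implementation.
* Zero-noise benchmarks measure protocol behavior, not noise robustness.
* The stiff-regime state integrator trades accuracy (≤ 3e-4 relative) for
  unconditional stability; outside the stiff regime accuracy is ≤ 1e-7.
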