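# Methods

`synergy-screen` analyzes combinatorial plant-inoculation experiments in
which a panel of N microbial isolates is tested alone (single
inoculation) and in all N(N−1)/2 unordered pairs (dual inoculation),
with mock-inoculum controls grown alongside. The default design mirrors
a 13-isolate fungal screen on *Brassica rapa*: 13 single + 78 dual
treatments plus controls, three response traits (shoot dry weight,
mature-leaf count, SPAD chlorophyll), treatments split into experimental
rounds, and germination scored per treatment.

## Round-standardized growth index

Because the full screen cannot be grown at once, treatments are blocked
into rounds (at most 13 treatments per round, each round containing its
own mock control). Micro-environmental differences between rounds are
removed by expressing every measurement relative to its own round's
controls:

    SG_T(i) = (X_T(i) − mean(X_C)) / sd(X_C)

with the mean and sample SD (n−1 denominator) taken over the round's
control replicates. SG is dimensionless; under a Gaussian control model,
|SG| > 1.96 flags plants outside the controls' two-sided 95% range. The
index is invariant to affine transformations of the raw scale, so units
never matter downstream. Standardization is refused (with the round and
trait named) when a round has fewer than two usable control replicates
or a zero control SD; fewer than five controls triggers a warning.
Integer-valued leaf counts are standardized as real numbers, like the
other traits. SPAD is measured only on a subsample of plants, so
chlorophyll SG records exist only for plants with a reading.

## Pair indices

For a pair (A, B), let m_A and m_B be the mean SG of the two single
inoculations (pooled across all their replicates; standardization has
already removed round effects) and SG_AB(i) the dual replicates. Three
replicate-level indices are computed:

* DMX_AB(i) = SG_AB(i) − max(m_A, m_B) — a positive replicate mean
  means the pair beats the better partner alone (*synergy*);
* DMN_AB(i) = min(m_A, m_B) − SG_AB(i) — a positive replicate mean
  means the pair falls below the worse partner (*offset*);
* DI_AB(i) = SG_AB(i) − (m_A + m_B)/2 — deviation from the singles'
  midpoint; |mean DI| measures non-additivity.

Synergy and offset flags use strict inequalities (a boundary mean of
exactly zero is not flagged). Two exact identities hold per replicate
and are enforced by tests: DMX + DMN = −|m_A − m_B| and
DI − DMX = |m_A − m_B|/2. Replicates are weighted equally when counts
differ between treatments.

## Statistical tests

**Treatment ANOVA.** One-way fixed-effects ANOVA of SG across the 13
single (or 78 dual) treatments, per trait, answering whether treatments
differ at all. Runs on standardized indices by default; a raw-value
option exists.

**Pair interaction ANOVA.** Per pair and trait, a 2×2 factorial linear
model SG ~ A + B + A:B on presence/absence of each isolate, with cells
(control, single A, single B, dual AB). The interaction F (numerator
df 1) is obtained by Type II model comparison (residual SS of the
main-effects model minus the full model), which equals the classical
two-way ANOVA for balanced cells. Each cell needs ≥ 2 replicates. By
default the control cell pools the control replicates of the rounds in
which the pair's treatments were grown (`control_pool="round"`); pooling
all controls is available. Benjamini–Hochberg FDR is applied across the
pair set within each trait.

**Germination.** Welch's unequal-variance t-test on per-treatment
germination rates (germinated/introduced seeds), single group first so
that better dual germination yields a negative t; Welch–Satterthwaite
df; two-sided p. No arcsine/logit transform is applied by default.

**Single-vs-dual correlation.** Pearson (or Spearman) correlation
between each isolate's single-inoculation mean SG and the unweighted
mean of its dual-treatment means (12 per isolate in the full design).

**Nonlinearity alignment.** Spearman rank correlation between |mean DI|
and the interaction F across pairs: the deviation index and the
factorial test should rank the same pairs as non-additive.

## Synthetic-data generator

The generator reproduces the study design so the whole pipeline is
testable without external data: 20–35 replicate cells per treatment
(drawn uniformly), two seeds per cell for germination
(Binomial(2 × cells, p_kind)), rounds packed with up to 12 non-control
treatments plus their own control, per-round control baselines drawn
per trait, Gaussian replicate noise, leaf counts rounded and floored at
zero, and SPAD generated for a random 15-plant subsample per treatment
as the mean of 3 noisy readings. One RNG stream with a fixed generation
order makes every output reproducible from a single seed.

Effect structure (per trait, in units of the residual SD σ):

* single effects a_k follow a shifted exponential
  (`single_effect_loc + Exp(single_effect_scale)`, defaults −2 + Exp(3.5)
  for biomass). The right-skewed shape matches screens of this kind:
  most isolates near neutral, a thin tail of strong promoters (~+7σ),
  a floor allowing mildly negative effects.
* a dual treatment's mean shift is
  `dual_midpoint_weight · (a_A + a_B)/2 + dual_effect_loc + Normal(0, dual_deviation_sd)`,
  and the realized pair deviation γ_AB = shift − midpoint is stored as
  ground truth — exactly the quantity mean DI estimates, which makes
  parameter recovery a clean end-to-end check. The default weight is 0:
  dual outcomes are drawn independently of the partners' single
  strengths. This choice reflects the defining empirical signature of
  such screens — near-zero correlation between single effects and dual
  averages — and it is what produces the characteristic trend that
  synergy (mean DMX) declines, and offset (mean DMN) grows, with the
  pair's mean single effect. A weight of 1 recovers a purely additive
  midpoint-plus-noise model; note that under that model the identity
  DMX + DMN = −|m_A − m_B| forces the DMX and DMN trends against the
  pair's mean single effect to have the *same* slope, so the observed
  opposite-signed trends are only possible when the dual response is
  decoupled from the midpoint.
* germination probabilities default to 0.9 (control), 0.7 (single),
  0.85 (dual), giving dual treatments the germination advantage seen in
  this kind of screen.
* default raw scales: biomass 100 ± 15 mg (round baselines SD 10 mg),
  leaves 6 ± 1.2 (baselines SD 0.6), SPAD 35 ± 4 (baselines SD 2,
  reading noise SD 1.5).

Explicit per-isolate effects and per-pair deviations can be supplied to
engineer scenarios (e.g. a single non-additive pair in an otherwise null
screen); `null_config()` zeroes every effect for calibration studies.

What the generator does **not** emulate: tray/spatial structure beyond
the round baseline, replicate attrition (all sown replicates are
measured), non-Gaussian residuals, correlations between traits within a
plant, and any mechanistic plant–microbe physiology. Passing tests
therefore demonstrate the pipeline's correctness and calibration under
the stated design, not robustness to those real-data features.

## Calibration: what is and is not exact

The interaction F statistic is invariant to affine transforms of the
response, so when all four cells of a pair's 2×2 model come from one
experimental round, round standardization is a single affine map and the
test is *exactly* calibrated (type-I error 0.05 at α = 0.05 — verified
on single-round null simulations). When a pair's dual and single
treatments sit in different rounds — unavoidable in the full design,
where every treatment is grown once — each treated cell mean carries its
own round's estimated control baseline (error SD ≈ 1/√n_controls), and
the interaction contrast variance is inflated relative to the residual
estimate. Under a fully null generator this raises the per-test
rejection rate at α = 0.05 to roughly 0.2–0.4 per screen. This is a
structural property of analyzing round-standardized indices with
cross-round cells, inherent to the published analysis strategy, not an
implementation artifact. Consequences: interaction F values and FDR
q-values for cross-round pairs should be read as a *ranking* of
non-additivity (which is how the screen uses them, and the |DI|-vs-F
alignment supports), not as exact error rates. Calibration tests in this
package therefore use single-round pair simulations.

## Numerical and design choices

* Sample SDs use the n−1 denominator everywhere.
* Dual pairs are canonicalized lexicographically; (A, B) ≡ (B, A).
* Each treatment belongs to exactly one round; violations are errors.
* BH is the FDR method; q-values are monotone in p and capped at 1.
* Pearson is the default correlation; Spearman is an option.
* Ties in max/min for equal single means collapse DMX = −DMN = DI.
* Problem sizes in tests and the acceptance script (10 screens for DI
  recovery, 200 one-trait screens for trend directions, ~1000
  single-round pairs for calibration) were chosen to bound Monte-Carlo
  error well inside the asserted tolerances.

## Known limitations

* No mixed-effects alternative (round as a random effect); rounds are
  handled by standardization only.
* Chlorophyll analyses rest on ~15 plants per treatment, so their
  indices are noticeably noisier than the biomass traits.
* The germination comparison treats per-treatment rates as independent
  observations and applies no variance-stabilizing transform.
* Triple and higher-order combinations are out of scope.
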