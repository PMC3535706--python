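# Methods

## Generative model

One simulated screen consists of `n_plates = 10` plates of 96 wells
(90 active siRNA wells + 6 NS-control wells), each plate replicated
`r ∈ {3, 6, 9, 12}` times per condition — `r` treated plus `r` untreated
physical plate copies, matching the common "3-replicate plates +drug,
3-replicate plates −drug" design. Every well's viability is drawn
independently around a cell mean:

| well class          | untreated mean | treated mean    |
|---------------------|----------------|-----------------|
| active, non-hit     | μ_NH           | μ_NH·D          |
| active, sensitizer  | μ_NH·C₁        | μ_NH·C₁·D       |
| active, antagonizer | μ_NH·C₂        | μ_NH·C₂·D       |
| NS control          | μ_NH·K         | μ_NH·K·D        |

with Gaussian noise of common SD σ, or gamma noise (below). The number of
true hits per round is drawn from Uniform{n_hit_low..n_hit_high}
(default 10..60, mean 35 of 900), split ceil/floor between the two
directions; C₁ and C₂ are paired so the two effects are equal in
magnitude (7/0.15, 5/0.3, 2/0.5, 1.25/0.8).

**Parameters and defaults.** μ_NH is a free scale (relative viability
units); it defaults to 1.0 and cannot matter, because every implemented
statistic is scale-invariant (a tested property). σ ∈ {0.2, 0.4, 0.8} maps
to the low/moderate/strong noise levels; D ∈ {0.3, 0.6, 0.8} to
strong/moderate/weak drug effect (D multiplies treated means, so smaller
is stronger kill); (C₁,C₂) ∈ {(7,0.15), (2,0.5), (1.25,0.8)} to
strong/moderate/weak RNAi effect. K defaults to 1.1, the middle of the
plausible 1.05–1.2 range for the control-vs-transfected viability gap, and
is configurable. σ = 0.6 and (5, 0.3) remain reachable through explicit
configs.

**Hit-multiplier placement.** By default the hit multiplier applies to
both conditions (untreated mean μ_NH·C, treated μ_NH·C·D): knocking down
a gene that modulates drug response may well shift baseline viability too,
and this reading makes the additive interaction μ_NH(C−1)(D−1) nonzero
while leaving the fold-change expectation at log2(D) for every siRNA —
the mechanism behind the method ranking. The alternative reading, hit
effect in treated wells only, is available as `hit_effect="treated-only"`.
A consequence of the default: the multiplicative SI identity
(Rc/Cc)(Cd/Cc) = Rd/Cc holds in expectation for hits as well, so the SI's
population value is ≈0 for every siRNA and its detection power here comes
only from variance heterogeneity. This is a genuine ambiguity of the
model description; the package treats the placement as a switch rather
than resolving it.

**Gamma (skewed) mode.** When `skewness > 0`, each well is drawn from a
gamma with shape `r = 4/s²` (standard gamma skewness is 2/√r) and scale
`mean/r`, preserving the cell mean exactly; the SD becomes mean·s/2, so
relative noise rather than absolute noise is held constant across cells.
Mean, SD and skewness cannot all be fixed simultaneously — the package
preserves (mean, skewness) because the mean structure carries the signal.
`gamma_params` also exposes the classical moment-matching solution of
μ = rλ, σ² = rλ² for a target (μ, σ).

**Non-negativity floor.** Gaussian noise at near-zero cell means (e.g.
μ = 0.045, σ = 0.2 for a treated antagonizing hit under strong drug)
produces negative draws; viability assays cannot. Values are floored at
ε = 1e−6 (configurable, or disabled with `floor_epsilon=None`). The floor
truncates the lower tail of those cells and biases their empirical mean
upward — moment-fidelity checks therefore run with the floor off.

**Randomness.** Each scenario has one root seed; per-round generators are
spawned from a `SeedSequence`, so a scenario is bit-reproducible and its
rounds could be distributed without changing results.

## Normalization

Raw viabilities are divided by a single global constant: the mean (or
median) of the untreated NS-control wells across all plates. Division, not
subtraction, because fold change and SI live on a ratio scale. A global
constant, not per-plate centering, because scaling treated plates to their
own controls would absorb the very drug effect under study. The median
option tolerates corrupted control wells. Since the constant is one
positive scalar, all method scores are unchanged by normalization (tested);
normalization matters only for interpretability and for real data where
plate batches share a scale.

## Scoring

For the per-siRNA LM fit, the control wells entering the model (and the
SI's Cc/Cd) are all NS wells on the siRNA's own plate across its
replicates, both conditions — this maximizes residual degrees of freedom
while respecting the plate pairing. The full model is the saturated 2×2
drug×RNAi layout, so its RSS is the pooled within-cell sum of squares and
the reduced (drug-only) model's RSS is the within-condition sum of
squares; `score_all` computes both in closed form for all 900 siRNAs at
once, which is exact for arbitrary cell counts and is verified against a
generic least-squares fit to 1e−8. The deviance difference is scaled by
σ̂² = RSS_full/(n−4) and referred to χ²₂; an exact F(2, n−4) variant is
available (`lm_test="f"`) and is a monotone transform, so rankings are
identical. At the default r=6 control wells per plate-condition the null
statistic's mean is ≈ 2·(n−4)/(n−6), within 0.06 of the asymptotic 2.

The t-test is classical pooled-variance Student by default (Welch by
flag). The Wilcoxon rank-sum uses exact p-values up to 10 wells per arm
and the normal approximation beyond; note its p-values are discrete, so
uniformity under the null holds only up to the p-value lattice (the
calibration test uses 12 wells per arm, where the lattice is fine).

Sign conventions are unified before selection: negative fold change,
negative t, positive SI and negative β₃ all mean "sensitizing".

## Hit calling and evaluation

No common significance threshold exists across the four statistics, so
each method calls exactly n_TH hits per round (the round's true hit
count): the ceil(n_TH/2) most extreme scores in the sensitizing direction
and floor(n_TH/2) in the antagonizing direction. Methods without p-values
rank by signed statistic; methods with p-values by signed significance,
direction × (1 − p) — a monotone transform of the signed t, and the one
consistent reading of two-tailed top-n selection for the LM, whose χ²
statistic is unsigned. Ties break lexicographically by siRNA id for
determinism. A called true hit counts as a true positive regardless of
called direction (hit/non-hit comparison); `strict_direction=True` demands
the direction match as well. Top-n_TH selection structurally caps false
positives: FP ≤ n_TH per round, hence FPR ≤ n_TH/(900−n_TH) ≲ 7% and in
practice ≲ 4% on average.

## Problem sizes

Scenario sweeps default to 500 Monte-Carlo rounds; the bundled evaluation
harness and acceptance script use 100 rounds per scenario, which yields
Monte-Carlo standard errors of roughly 0.3–2 percentage points on the
mean rates — small against the between-method FNR gaps of tens of points —
and reports those SEs alongside the means. Null-calibration checks pool
2,700 statistics from three no-hit screens.

## What the simulator does and does not emulate

It reproduces the moving parts the method comparison depends on: relative
effect sizes, replicate structure, control-well offsets, noise level and
skewness, and the unknown, varying number of true hits. It has no plate
spatial effects (edge rows, gradients), no plate-to-plate batch scale
differences (all plates share one scale before normalization), no
correlation between wells, and hit effects are homogeneous within each
direction. Passing tests therefore demonstrate correctness of the
statistics and the comparison machinery under this idealized model, not
performance on screens dominated by spatial artifacts — data like that
needs within-plate corrections out of scope here.

## Known limitations

* Each siRNA must live on a single plate (validated); split layouts would
  need a plate-blocked model.
* The FNR is highly sensitive to n_TH when hits are few, so per-round
  rates are noisy even when their scenario mean is stable.
* Under the default hit-multiplier placement the SI is structurally
  near-null (above); with `hit_effect="treated-only"` it recovers the
  behaviour its construction intends.
* p-values from the LM rely on the χ²₂ asymptotics of the deviance
  difference; at very small n the F variant is preferable.
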