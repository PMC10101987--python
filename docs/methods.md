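# Methods

## Normalization and plate quality

Each 384-well plate carries its own vehicle (negative, 0.1% DMSO) and
full-kill (positive, benzethonium chloride) control wells. Raw luminescence
L maps to percent viability as

    viability% = 100 · (L − μ_pos) / (μ_neg − μ_pos)

with μ the per-plate control means (sample SDs use the n−1 denominator).
Controls are summarized per plate, not pooled across the plates of a
screen, so plate effects stay visible in QC. Viability is deliberately not
clipped at this stage — wells above 100% or below 0% are informative about
plate noise — and clipping happens only inside scoring. The transform is
affine-invariant: any gain/offset change of the reader leaves viability and
Z′ unchanged.

Plate quality is the Z′-factor, Z′ = 1 − 3(σ_pos + σ_neg)/|μ_neg − μ_pos|
(the universal HTS statistic; the ≥ 0.5 gate is the conventional pass
threshold and is configurable). Failing plates are not dropped: their
entries carry a `qc_fail` flag, and a strict mode aborts instead.

## Concentration–response model

Viability against log10 dose x is the four-parameter logistic

    v(x) = bottom + (top − bottom) / (1 + 10^(slope·(x − log EC50)))

fitted by bounded trust-region least squares (top ∈ [50, 120] %, bottom ∈
[−10, 100] %, slope ∈ (0, 10], log EC50 within the tested window ± 2
decades). Initialization is deterministic — top/bottom from the observed
extremes, log EC50 at the dose nearest the half-response, slope 1 — with no
random restarts, so refits are reproducible. Termination is on parameter
change (xtol 1e-15) rather than cost change, which makes noiseless refits
exact to well below 1e-6. An all-flat response is represented exactly as a
flat curve; a fit that fails to converge falls back to the flat curve at
the mean viability and is flagged `poor_fit` (as is any fit with RMSE > 15
viability points — the score is still reported).

## The DSS family and the modified DSS3

Let y(x) = clip(100 − v(x), 0, 100) be percent inhibition over the tested
window [x_lo, x_hi], t the activity threshold (default 10 points,
suppressing noise-level dips), f the viability floor (default 10%, i.e.
inhibition cap c = 90). Define x1 as the first dose where y ≥ t (no such
dose ⇒ score 0, `inactive`) and x2 as the first dose where y ≥ c (none ⇒
x2 = x_hi). The integrated excess inhibition is

    cap rule (default):  A = ∫_{x1}^{x_hi} (min(y, c) − t)₊ dx
    truncate rule:       A = ∫_{x1}^{x2} (y − t)₊ dx

so under the cap rule a maximally potent compound accrues the capped
rectangle past x2 and reaches the ceiling 100·(100 − f − t)/(100 − t) ≈
88.9. The metrics are

    DSS1  = 100·A / ((100 − t)·(x_hi − x_lo))
    DSS2  = DSS1 / log10(d),  d = min(max window inhibition, 100), 0 if d ≤ 10
    DSS3  = DSS2 · (x_hi − x1)/(x_hi − x_lo)
    mDSS3 = DSS1 · (x_hi − x1)/(x_hi − x_lo)

mDSS3 — DSS3 without the division by the logarithm of the curve's upper
asymptote — is the default metric. All four variants and both tail rules
are kept as switches because the base definitions admit more than one
reading and no deposited raw data can arbitrate between them; the switches
bracket the plausible choices rather than collapsing them. Complete kill at
the lowest tested dose sets x1 = x_lo and flags `complete_kill_at_min`.

Integration is closed-form on the logistic (the antiderivative of v is
analytic, and on [x1, x2] no clipping engages for monotone curves with
v(x1) ≤ 100), with adaptive quadrature as the fallback for the remaining
shapes; tests pin both paths to a 10,001-point trapezoid oracle at 1e-4.
Crossings are found with Brent's method at xtol 1e-12.

Singles and fixed-molar combinations are scored identically — a combination
is one curve on its shared concentration axis (each component at the stated
molarity); there is no per-component dose grid and no synergy model.

## Phospho-flow statistics

Marker medians m relative to a reference median r (isotype or unstimulated
control) are expressed as arcsinh ratios, asinh(m/cofactor) −
asinh(r/cofactor). The cofactor defaults to 150, the common choice for
conventional fluorescence cytometry; for signals well below it the ratio is
(m − r)/cofactor to first order. The package computes ratios of medians
(not medians of per-cell ratios); FCS parsing and gating are upstream.
Longitudinal changes are integer percents, 100·later/earlier rounded half
away from zero. Heatmap orderings cluster rows and columns with Manhattan
distance under Ward linkage applied to the raw dissimilarities (hclust
ward.D behavior): scipy's Ward update squares its input, so the linkage is
computed on the square roots of the Manhattan distances, which reproduces
the ward.D merge order exactly; ties are broken by input index, making
orders deterministic. Constant matrices and single-row/column axes skip
clustering with a warning.

## Synthetic screens

The generator's defaults are the standard study conditions: 94 single
agents and 87 combinations, five ten-fold doses 1–10,000 nM, controls in
columns 1 and 24 of each plate (16 wells per role per plate), at most four
plates (the default design fills three). Treatment luminescence is
μ_pos + (μ_neg − μ_pos)·v_true/100 times mean-one lognormal noise with
CV 5% (multiplicative noise matches the scale-dominated error of
luminescence assays); control wells are normal draws truncated at zero.
Control truth defaults to μ_neg = 200,000 and μ_pos = 10,000 RLU with
σ = 0.05·(μ_neg − μ_pos)/3 per arm, i.e. an expected Z′ of 0.9 — a clean
screen comfortably above the 0.5 gate. True curve parameters are drawn
once per seed: top ~ N(100, 3) clipped to [90, 110], bottom ~ U(0, 15),
log EC50 uniform over the tested window, slope ~ U(0.8, 2).

Serial samples reuse one base truth and shift log EC50 additively per entry
and time-point (+1 models a tenfold potency loss under therapeutic
pressure; returning to 0 models reversal after treatment stop) — a
phenomenological device, not a mechanistic claim. Marker medians are a
per-marker baseline times a per-time-point multiplier over a constant
reference; the flow noise defaults to zero so the marker model is exact
structure, with lognormal noise opt-in.

What the generator does not emulate: spatial/edge effects within plates,
dispensing artifacts, inter-replicate biology (one screen per sample by
design), cell-level flow distributions, or co-culture survival kinetics.
Passing tests therefore demonstrate the correctness of the computations
under the stated noise model, not robustness to every artifact of real
plates.

## Numerical and design choices

- Replicate wells for the same (entry, dose) are averaged at normalization.
- Dose unit is nM throughout; all dose axes are log10.
- Well addresses are letters A–P (rows) × 1–24 (columns), parsed
  case-insensitively, single leading zero tolerated.
- Ranked outputs sort by descending score with ties broken lexicographically
  by entry id; missing entries across time-points stay NaN, never imputed.
- Problem sizes in the test-suite simulations (e.g. 200 noisy refits, 100
  oracle draws, one full 181-entry screen) are chosen as the smallest sizes
  at which the distributional claims are stable across seeds.

## Known limitations

- The DSS base normalizations follow one reconstruction of the metric
  family; published patient-level scores from other implementations may
  differ by the variant switches above.
- Z′ assumes roughly symmetric control noise; heavy-tailed contamination
  is better served by robust variants (not implemented).
- No IC50 confidence intervals or mixed-effects curve sharing; each entry
  is fitted independently.
- No synergy quantification: combinations are summarized by the same
  single-curve score as singles.
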