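# Methods

## The quality characteristic

The reader's job is a linear transfer: commanded T-line grayscale `x`
(the signal, 0–255) in, measured grayscale `y` out. Quality is dynamic
in the Taguchi sense — what matters is the proportionality and tightness
of the whole calibration, not closeness to a fixed target. Each run's
series is summarized by the zero-point proportional fit

    beta = Σ x·y / Σ x²            (least squares through the origin)
    S_d  = sqrt( Σ (y − beta·x)² / (n − 1) )
    S/N  = −10·log10( S_d² / beta² )   [dB]

The zero-intercept convention is the standard one for this S/N form: a
reader with no signal should read zero, and deviations from
proportionality (offsets, clipping, curvature) are penalized through
S_d. The S_d divisor is configurable (`n`, `n−1`, `n−2`); `n−1` is the
default. S/N is scale-invariant (y → k·y leaves it unchanged) and a
perfect fit gives S/N = +inf, which is propagated as a flagged
degenerate result, never silently averaged.

## Synthetic strips and the camera model

Real strips develop colloidal-gold bands whose color varies with
chemistry; the simulator replaces them with strips whose T-line
grayscale is commanded exactly: the red channel is fixed (default 255,
the only value from which the full 125–255 target range stays
reachable) and G = B is solved from BT.601 luma,
`v = round((target − 0.299·R)/0.701)`, giving band grays within ±1 of
target after quantization. Default geometry is a 400×120 px window, C
band rows 60–80, T band rows 140–160, white background.

The camera model is a simulator contract, not device physics. On float
pixels, in fixed order: gain `illuminance/240`; contrast
`p' = 128 + (0.5+c)(p−128)`; saturation scaling chroma about BT.601 luma
by `(0.5+s)`; tone offset `40(t−0.5)`; i.i.d. Gaussian noise (default
sd 2 gray, seeded); clip to [0,255] and quantize. The midpoint settings
(240 lux, 0.5, 0.5, 0.5, no noise) are a strict no-op, verified
bit-exactly.

What the model does and does not emulate: it produces factor structure —
contrast moves the calibration's intercept and slope strongly (level
means span ~17 dB), illuminance acts through β and through 8-bit
clipping, tone adds a ±6-gray offset, saturation is luma-neutral except
through clipping — but no optics, no flow chemistry, no spatial
nonuniformity, no perspective. Passing tests therefore demonstrate the
*analysis chain* (design → S/N → ANOVA → prediction → confirmation) on a
system with known ground truth, not performance on real specimens.

A consequence worth knowing: with the red channel parked at 255, any
gain ≥ 1 combined with above-neutral contrast clips R, and at 240 lux
the clipping lack-of-fit almost exactly cancels the slope advantage over
200 lux — the noise-free illuminance level means are (−11.18, −11.20,
−18.73) dB. The generator's designed optimum is therefore defined as a
*set* per factor: every level within 0.5 dB of the noise-free best
(illuminance {200, 240}; contrast {0.53}). The recovery tests assert
selection within these sets, with the noise-free study recomputed at
test time as the oracle. Likewise the generator's "influential" factors
are defined by the one-half criterion on the noise-free response (range
above half the largest range), which yields contrast alone.

## Design and analysis

The canonical L9(3⁴) array (first column 1,1,1,2,2,2,3,3,3, standard
Latin-square completion) is audited by brute force: 3-3-3 balance per
column and all nine ordered level pairs exactly once for every column
pair. Factors are assigned to columns in A, B, C, D order; this choice
only determines which synthetic runs get which settings, not any
downstream statistic, which consumes level means.

Response analysis: level mean = mean S/N of the three runs at that
level; range R = max − min; rank 1 = largest range, ties broken in
factor order. ANOVA on the saturated design: each factor's
`ss = 3·Σ(level mean − grand mean)²` on 2 dof; the four factor SS sum
exactly to the total SS of the nine runs, so the error term comes from
pooling. Auto pooling starts with the two smallest-SS factors (keeping
error dof ≥ 4) and keeps pooling the smallest remaining factor until all
unpooled factors reach 95% confidence or only the largest remains;
explicit pooling sets are also accepted. F-tail probabilities come from
`scipy.stats.f.sf`; for 2 numerator dof this equals the closed form
`(1 + 2F/d2)^(−d2/2)`, which the tests use as an independent check.
Pooled rows carry no F or confidence. A flat response table (zero pooled
error) raises rather than reporting infinite F.

Rounding caveats, documented in tests: on the *printed* reference
response table (1-decimal level means) factor D's range computes to 1.6
where the publication prints 1.5, and factor A's confidence computes to
94.5% where exact-data analysis gives 95.02% — both are artifacts of
feeding rounded summaries back through exact formulas, so the affected
tests carry the printed-input rounding slack and auto-pooling is
asserted against the arithmetic, not the published, outcome.

## Prediction, confirmation, quality loss

Optimal levels are larger-the-better per factor (ties → lowest index).
The additive prediction includes only ANOVA-surviving factors. The
confirmation CI uses `t_{α/2, fe}·sqrt(MSe·(1/me + 1/mr))` with
`me = n_runs/(1 + Σ dof of included factors)`; α defaults to 0.01
(a 99% two-sided interval) and the confirmation runs in triplicate
(mr = 3). With two included 2-dof factors from an L9, me = 9/5. The
quality-loss ratio is `0.5^((S/N_opt − S/N_orig)/3)` — strictly
decreasing in the gain, exactly 0.5 at +3 dB. Calibration linearity is
ordinary least squares *with* intercept: R² = 1 − RSS/TSS, residual SD
with divisor n−2, CV% = 100·(residual SD)/mean(y) (CV is not standard
notation anywhere; this definition is declared, not inferred).

## Pipeline determinism and problem sizes

One study = 9 screening runs plus 3+3 confirmation replicates, 11
images each (the 11 commanded levels 125–255), ~1 s on one CPU. All
randomness flows from `base_seed`: run r uses seed `base_seed + r`
(confirmation replicates use run indices 20+ and 30+), and the image for
level index k adds `1009·k`, so every image has a distinct, reproducible
noise stream and identical configs give byte-identical reports. The
replicate sets used by the property tests are 20 studies at fixed seeds.
The original-design baseline is A3, B2, C2, D2 (280 lux, contrast 0.33,
saturation 0.5, tone 0.5), configurable.

## Known limitations

- The camera model's factor structure is designed, not fitted; effect
  rankings other than "contrast dominates" should not be read as claims
  about any physical reader.
- Band detection assumes bands darker than background by more than the
  threshold offset (default 10 gray); near-background bands (targets
  250–255 on white) require explicit band coordinates, which the
  pipeline supplies from its known geometry.
- The grayscale definition is BT.601 luma throughout; any monotone
  alternative would shift the synthetic calibration but not the Taguchi
  machinery.
- No multi-response optimization, interaction columns, or outer noise
  arrays; the L9 main-effects model is the scope.
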