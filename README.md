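# fixmodal

Multimodality-aware spatial precision analysis for eye-tracking fixation
data.

## The problem

The spatial precision of an eye tracker is conventionally reported as the
standard deviation (SD) of the horizontal or vertical gaze position during
stable fixation. The SD is a well-behaved measure of spread only when the
underlying distribution is unimodal and roughly normal. Fixational eye
movements — slow drift and microsaccades — frequently make these position
distributions *multimodal*: a microsaccade shifts the fixation level
mid-window, drift smears it. For such distributions ±1 SD no longer covers
the familiar 68.27% of samples, and the SD mixes within-mode spread with
between-mode separation, overstating device imprecision.

`fixmodal` is for eye-tracking methodologists and data-quality researchers
who want to (a) test each fixation's position distribution for
multimodality and (b) report a precision estimate that remains
interpretable when the distribution is multimodal.

## The statistic

Each accepted fixation contributes a 500-sample, NaN-free position
distribution per axis (1 kHz sampling). A mixture of K ∈ {1, …, 5}
weighted normal components is fitted by reversible-jump MCMC
(Richardson–Green sampler: within-model Gibbs updates plus split/combine
and birth/death moves across K). With a = P(K>1)/P(K=1) the prior odds of
multimodality and b the corresponding posterior odds estimated from the
kept draws of K, the Bayes factor is

    BF = b / a,        log BF ≤ 1  → no evidence (unimodal)
                       1 < log BF ≤ 3 → positive evidence
                       3 < log BF ≤ 5 → strong evidence
                       log BF > 5  → very strong evidence

(natural logarithm). Two precision estimates are computed per fixation and
axis:

* **ClassicPrecision** — the sample SD of all 500 samples;
* **MaxCompSD** — the SD of the maximum-weight mixture component, which
  measures within-mode spread regardless of modality.

RMS-S2S, median/mean absolute deviation and BCEA are provided for
comparison, together with the empirical ±n·SD coverage that motivates the
analysis.

Upstream of the statistics, a six-step cleanup reduces each 1-second
target epoch to its analysis window: saccade-latency alignment, window
selection (samples 192–691 of the aligned epoch), blink-saccade removal,
velocity-based saccade removal (peak > 55 deg/s, boundaries at local
minima < 30 deg/s), removal of residual parabolic saccade fragments
(27-sample sliding windows, R² > 0.6 and |quadratic coefficient| >
0.00055), and anticipatory-saccade removal. Only trials whose window ends
up with exactly 500 contiguous valid samples are analysed.

A ground-truth synthetic generator emulates the random-saccade task
(targets uniform over ±15° × ±9°, ≥ 2° steps, latency ≈ 237 ± 17 ms,
blinks, drift and microsaccade regimes), so the whole chain is testable
without any recordings.

## Worked example

```python
import numpy as np
from fixmodal import (classic_precision, fit_mixture_rjmcmc,
                      max_comp_sd, sample_mixture)

# a bimodal fixation: two 0.03-deg-SD modes 0.3 deg apart
y = sample_mixture([(-0.15, 0.03, 0.5), (0.15, 0.03, 0.5)], n=500, seed=7)
fit = fit_mixture_rjmcmc(y, seed=11)
print("posterior over K:", np.round(fit.posterior_k, 3))
print("modal K:", fit.modal_k, "| log BF:", fit.log_bf, "| category:", fit.category)
for m, s, w in fit.components:
    print(f"  component: mean={m:+.3f}  sd={s:.3f}  weight={w:.2f}")
print(f"ClassicPrecision = {classic_precision(y):.4f} deg")
print(f"MaxCompSD        = {max_comp_sd(fit):.4f} deg")
```

prints

```
posterior over K: [0.    0.83  0.13  0.035 0.004]
modal K: 2 | log BF: inf | category: very_strong
  component: mean=-0.153  sd=0.028  weight=0.47
  component: mean=+0.151  sd=0.029  weight=0.53
ClassicPrecision = 0.1542 deg
MaxCompSD        = 0.0290 deg
```

No kept draw had K = 1, so the raw Bayes factor is infinite (cohort-level
sanitization replaces it with the cohort's maximum finite log BF). The
classic SD, 0.154°, is dominated by the 0.3° mode separation; MaxCompSD
recovers the 0.03° within-mode spread.

The command-line interface drives the full chain:

```bash
fixmodal simulate --seed 1 --out session/       # synthetic recording + truth
fixmodal run --synthetic --seed 1 --out run/    # cleanup → fits → metrics
fixmodal validate --n-seeds 10                  # power/specificity report
```

`run` writes `results.csv` (one row per fixation × axis: log BF, category,
modal K, ClassicPrecision, MaxCompSD, RMS-S2S, MAD, component table),
`summary.csv` (per-direction category percentages, medians) and
`removal_log.csv` (per-step removal counts).

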