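# Methods

This note documents the models, parameter choices and numerical
conventions behind `sketchvep`, and what the synthetic-data tests do and
do not establish about real data.

## Feature model

**Binarization.** Grayscale images are thresholded at their median;
pixels *≥ median* map to white. The `>=` tie rule is deterministic and
splits continuous-valued images 50/50. Pattern ids encode a 3×3 patch
row-major, top-left pixel as the most significant bit, white = 1 (id 0 =
all black, 511 = all white).

**Patch statistics.** The corpus distribution is estimated from
non-overlapping 3×3 tiles (remainders truncated); a stride-1 sliding
window is used only for sketch filtering, where dense coverage is the
point. Both are exposed through `mode`.

**Efficiency.** Entropy yield per unit cost is `H(p)/C(p)` with
`H(p) = −p log₂ p` (H(0) = 0 by continuity) and
`C(p) = max(p/W, 1/N)`. Frequent patterns are charged for the bandwidth
fraction they occupy, rare ones for the representation slot they
consume; the function is zero at both ends of the probability axis, so
uniform patches and absent patterns are never selected. `C` is a
pluggable callable for experimentation.

**Selection.** `select_optimal` solves the constrained entropy
maximization *exactly*: because probabilities are integer patch counts
over `n_patches`, the bandwidth constraint `Σp ≤ W` is an integer
knapsack capacity `Σcounts ≤ ⌊W·n_patches⌋`, and a 0/1 knapsack dynamic
program with a cardinality dimension (≤ N items) finds the optimum;
backtracking uses √-spaced table checkpoints to keep memory linear. A
greedy alternative (descending efficiency, skip-on-overflow, ties by
ascending id) is available via `method="greedy"`; on random small
instances it is suboptimal in roughly a quarter of cases when the two
constraints interact, which is why the exact method is the default. The
DP is validated against an independent brute-force subset enumeration
on ≤ 12-pattern problems. When the DP table would exceed ~50 M cells the
function falls back to greedy with a warning; at the scales used here
(≤ ~750 k patches) the exact path runs in seconds. Members are returned
in decreasing-efficiency order. Non-optimal sets are the k
lowest-positive-probability patterns (ties by ascending id), padded
with zero-probability patterns plus a warning if the corpus is too
concentrated.

## Stimuli and schedule

Ten 0.3° glyphs are placed by dart throwing, uniformly over the disk in
which a glyph square stays fully inside the 3°-diameter compound
region, rejecting candidates closer than 0.3° to an accepted one; a
stuck layout restarts from scratch (in practice the densities need only
a handful of draws — a property test covers 10⁴ compounds).
"Arranged in an ideal circle" is read as scatter within the disk, since
published example stimuli show scattered rather than circumferential
glyphs; circumferential placement would be a trivial variant of the
sampler. Rendering upsamples each 3×3 pattern to 9×9 px (0.3°/9 px =
0.0333°/px), black = 3, white = 90 cd/m², on a 44 cd/m² background, so
every rendered pixel is one of exactly three luminances.

The session schedule holds 1920 single-stimulus trials (240 per
SNR × field cell) plus 360 2AFC trials pairing SNR 0% with a uniform
draw from {30, 60, 100}%, shuffled within 6 equal blocks. Note the
arithmetic: 1920 + 360 = 2280 trials means blocks of 380, not the
round 360 sometimes quoted for this design — the per-cell totals are
kept and the block size follows from them. ISIs are uniform on
700–800 ms; single stimuli last 25 ms and 2AFC stimuli 24 ms (the 1 ms
asymmetry of the original procedure is preserved as stated). Scaled
schedules (`scaled_schedule_config`) shrink every cell by a common
integer factor so block balance is preserved.

## Spectral analysis

The PSD is the squared modulus of the plain (unwindowed, unnormalized)
2-D FFT of a centered square crop, so Parseval reads
`psd.sum() = n²·Σpixel²`. Radial averaging bins pixels by rounded
integer distance from the DC bin; radius *r* maps to
`r/(n·pixel_angle)` cycles/degree, and every pixel lands in exactly one
bin. Cross-condition comparison treats each radial spectrum as a
power-weighted distribution over frequency and computes the
two-sample KS statistic of the cumulative curves; the p-value uses the
asymptotic KS distribution at an effective sample size of one quarter
of the bin count (bins as resolution elements — a documented
approximation, adequate for the directional comparisons made here).

The theoretical frequency range of a 9 px glyph is one cycle per glyph
width up to one cycle per pattern cell (3 px), i.e. `f_max = 3·f_min`.
Two pixel-angle calibrations coexist in the literature this package
follows: the printed 0.0289°/px (giving 3.84–11.52 c/deg after 2 d.p.
rounding of the lower bound) and the render geometry's 0.3°/9 px =
0.0333°/px (giving 3.33 c/deg). Both are supported
(`theoretical_frequency_range`, `printed_frequency_range`); the
discrepancy is surfaced, not resolved.

## Synthetic data

`make_image_corpus` produces 1/f-amplitude Gaussian noise (exponent 1
by default). After binarization its tiled patch distribution is heavy-
tailed with ~0.35–0.4 of the mass on the two uniform patches — the
qualitative signature of natural images that drives the selection —
while an exponent-0 control yields a near-uniform distribution. It does
*not* reproduce higher-order natural-image structure (edges with
phase alignment, occlusions, textures), so the *identity* of selected
patterns will differ from a natural corpus even though the selection
mechanics are exercised fully.

The EEG forward model plants Gaussian bumps — the simplest waveform
with closed-form peak, width, prominence and onset for oracle testing —
scaled by a fixed 30-channel topography (weight 1 on POz/PO3/PO4/Pz,
0.5 on neighboring posterior channels, 0 elsewhere):

| parameter | default | why |
|---|---|---|
| C1 condition means | 74/71/70/69 ms (SNR 0/30/60/100%) | the latency structure under test |
| C1 amplitude / sd | 2 µV (negative upper / positive lower field) / 10 ms | per-condition averages sit far above the 0.2 µV detection floor while single trials stay noise-dominated |
| C2 amplitude / latency / sd | 1.5 µV (sign opposite to C1 per field) / 130 ms, SNR-independent / 15 ms | negative control: the pipeline must *not* find an SNR effect here |
| subject offset sd | 3 ms (common to all conditions) | latency effects are within-subject, as in the real design |
| trial jitter sd | 5 ms | trial-to-trial latency variability |
| pink noise | 10 µV RMS/channel (1/f power) | dominant EEG background |
| line noise | 5 µV at 50 Hz | exercises the notch |
| drift | 20 µV below 0.05 Hz | exercises the high-pass |

2AFC trials place compounds in both fields (each field's C1 latency
follows that field's SNR) and are excluded from EEG averages by kind.
Behavior follows `P(choose higher SNR) = λ/2 + (1−λ)·σ(s·ΔSNR)` with
s = 0.03, λ = 0.1, giving preferences of ~0.69/0.82/0.91 for ΔSNR
30/60/100 — a strong, SNR-graded preference of the size reported for
this paradigm. The model omits eye/muscle artifacts, alpha rhythm,
channel-correlated noise and realistic volume conduction; recovery
results therefore demonstrate the *pipeline's* correctness on data
satisfying its assumptions, not robustness to every failure mode of
real EEG.

Sessions serialize to plain 16-bit EDF (1 s records, per-channel
symmetric physical ranges, quantization step `2·phys_max/65534`) plus
an events TSV; reading goes through MNE's EDF reader, which doubles as
an independent format check.

## VEP pipeline numerics

* High-pass (0.1 Hz) and notch (49–51 Hz) are Blackman-window sinc FIR
  kernels sized for a 0.2 Hz transition (~13 751 taps at 500 Hz),
  combined by convolution and applied with centered overlap-add, so the
  filter is exactly linear-phase and symmetric pulses keep their peak
  sample. Re-referencing subtracts the common average.
* Epochs span −150…+300 ms (the baseline window plus enough to cover C1
  and C2); baseline is the mean of the 150 ms before onset. Trials with
  missing samples, incomplete epoch support, or cluster peak-to-peak
  amplitude above 150 µV are dropped and counted — an automated,
  reproducible stand-in for visual trial inspection.
* Condition VEPs average the cluster mean across trials, then apply the
  35 Hz 4th-order Butterworth zero-phase (forward-backward). The
  difference wave is lower-minus-upper, which makes C1 positive.
* C1 is the largest local positive peak in 40–100 ms with prominence
  and absolute height > 0.2 µV (the height criterion is applied to the
  absolute peak value); C2 uses sign-flipped logic in 90–180 ms.
  Latency and amplitude are refined by 3-point parabolic interpolation
  (2 ms sampling is coarser than the millisecond precision of interest);
  width is full width at half prominence; onset is the last pre-peak
  crossing of 50% of the peak amplitude. Non-detection is a value
  (`detected=False`), not an error, and participants lacking a C1 in
  any SNR condition are excluded from group analysis.
* An upper-field-only path (sign-flipped upper VEP) reuses the same
  measurement for the supplementary analysis style.

## Statistics

One-way repeated-measures ANOVA (F and p via pingouin; uncorrected df,
with sphericity correction deliberately not applied) reports classic
eta-squared `SS_condition/SS_total` computed from the sums of squares
directly. Pairwise comparisons are paired t-tests with Bonferroni
adjustment `min(1, m·p)` and paired Cohen's d = mean(diff)/sd(diff),
with a normal-approximation 95% CI, `se(d) ≈ sqrt(1/n + d²/2n)` —
chosen for its closed form; zero-variance differences are reported as
d = 0 with an explicit flag. Preference–latency association uses
Spearman rank correlation (average ranks on ties). All tests are
validated against hand-computed toy tables.

## Problem sizes

The shipped tests and the acceptance script use: a 100-image 256×256
corpus (722 500 tiled patches) for selection; 10⁴ compounds for the
geometry property; 21 simulated participants with full 2280-trial
sessions (~240 single trials per SNR × field) for latency recovery; and
20 independent 6-participant cohorts at 1/10 schedule scale for the C2
null control. These sizes give sub-millisecond standard errors on the
recovered grand means (subject-offset sem ≈ 0.65 ms dominates) while
keeping a complete run to a few minutes on one CPU.

## Known limitations

* The exact cost function of the original reference model is not
  published; `C(p) = max(p/W, 1/N)` reproduces its qualitative
  selection behavior (uniform and rare patterns rejected, intermediate
  probabilities favored) but the selected-set identity on any given
  corpus is specific to this choice.
* The surrogate corpus licenses no claim about which 50 patterns the
  real McGill-corpus pipeline selects.
* The KS p-values for spectra are asymptotic under a documented
  effective-n convention; use the statistics comparatively.
* EDF output is plain EDF (continuous recording + sidecar events TSV),
  not the annotated EDF+ dialect.
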