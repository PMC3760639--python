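# Methods

## Scope and data model

`exocargo` analyses paired exosome/donor-cell microarray profiles. It does
not touch scanner images or vendor probe-level files: the dual-channel
workflow consumes quantified spot tables (foreground and local background
per spot, as image-analysis software exports them), and the single-channel
workflow consumes background-corrected expression values together with
Present/Marginal/Absent calls produced upstream. Re-deriving expression
values or P/M/A calls from probe-level data is explicitly out of scope; the
simulator's call generator is a stand-in for that upstream step, not a
reimplementation of it.

All tabular formats are tab-delimited text with a header row; results are
CSV plus a JSON summary. Readers validate uniqueness, vocabulary and
numeric ranges and reject bad input with errors naming the offending row
and column — no silent row dropping.

## Dual-channel (miRNA) pipeline

Channel orientation is fixed: Hy3 carries the exosome sample, Hy5 the donor
cells; every ratio is exosome over cell.

**Backgrounds.** Two distinct backgrounds are used on purpose. The absence
rule compares each replicate spot's foreground with that spot's *local*
background estimate from the quantification file. The detectability limit
uses the *slide-wide* channel background: the median of all foreground
signals of that channel on the slide (every replicate spot of every probe).
Median convention: mid-mean of the two central order statistics for even
counts.

**Detection status per slide.** With k replicate spots (default 4):
*absent* when foreground ≤ spot background on ≥ ⌈k/2⌉ spots — the "2 or
more of 4" rule, generalized to preserve the fraction for non-default
designs; the comparison is inclusive, so a spot exactly at background
counts against the probe. Otherwise the probe's summarized signal — the
median of the replicate foregrounds — must exceed `detect_multiplier`
(default 3) × the slide background to be *detectable*; otherwise it is
*below_limit*.

**Aggregation.** A probe is *detected* in a channel only when detectable on
at least `min_slides` slides; the default is all available slides, which
for the standard triplicate design encodes "detected on fewer than 3 of 3
slides is unreliable". "Detected" for this rule means status `detectable`,
the stricter of the two possible readings (the alternative — merely
not-absent — would let probes below the detectability limit into the
detected sets).

**Normalization.** Replicate spots are summarized by the median foreground
per (probe, slide, channel) before ratios are formed — robust to a single
damaged spot; no background subtraction is applied before the log
transform, because subtraction can produce non-positive signals with
undefined logs. Probes with a non-positive summarized signal in either
channel are excluded from that slide's fit, returned as missing and
reported. Per slide, M = log₂(Hy3/Hy5) is regressed on
A = ½·log₂(Hy3·Hy5) with Lowess (statsmodels implementation; span 0.3, one
robustness iteration by default, exact computation with `delta=0`) and the
fit is subtracted. The span is a conventional choice for global intensity
normalization; both span and iteration count are configurable. Applied to
data whose M-vs-A trend the local-linear smoother represents exactly
(constant or linear), normalization is idempotent to floating-point
precision; swapping the channels negates the normalized ratios exactly.

**Summaries.** The per-probe mean and sample SD (n−1 denominator, the
conventional reading of "± SD" over triplicates) are taken over the slides
on which the probe was not excluded; a probe excluded everywhere has a
missing mean, never zero, and is left unclassified. Fold-change classes use
inclusive boundaries — *elevated in exosomes* when mean ≥ t, *elevated in
cells* when mean ≤ −t, *equal* strictly between — with t = 2.0 on the log₂
scale (4-fold) by default. The published table this rule emulates is
notationally ambiguous between t = 1 and t = 2; the accompanying text
("at least 4-fold") supports 2.0, and the threshold is a parameter.
Ranking of enriched probes sorts by mean normalized log₂ ratio (descending
for the exosome direction) with ties broken lexicographically by probe id.

**Set algebra.** Venn counts are exact set operations on the detected probe
id sets; the identities exo_only + shared = exo_total (and symmetrically)
are asserted invariants.

## Single-channel (mRNA) pipeline

Arrays are first scaled column-wise to a median of 100 (the standard
"median array intensity 100" convention that makes arrays comparable).
The intensity filter computes, per array of a group, the (1 − 0.25)
quantile of that array's values with linear interpolation between order
statistics, and keeps a probe only if its value is ≥ the cutoff on *every*
array of the group. Per-array cutoffs (rather than one pooled group cutoff)
were chosen because the groups are normalized separately and the phrase
being implemented reads as a condition on each signal value; the pooled
variant would be a one-line change. Boundary inclusiveness makes the filter
well-defined on constant data (everything ties the cutoff and passes).

The presence filter requires a P call on every array of the group; the
unique-to-group set requires P on every own-group array *and* A on every
other-group array. Marginal calls count as neither present nor absent, so
an M anywhere breaks both presence and uniqueness — the strict reading of
"present calls for all" / "absent calls for all". Detection is the
intersection of the two filters; the two are conjunctive and
order-independent, so no re-ranking sequence needs to be pinned.

The detected-fraction summary reports |exosome detected| / |cell detected|
and its percentage rounded half-up to the nearest integer (1,849/12,346 =
14.98% → 15%, matching the published rounding).

## Simulator

The truth table assigns each probe a compartment class, a base intensity
(log-uniform on 2048–32768, a typical fluorescence working range), and a
true log₂ enrichment. Class counts are floors of the configured fractions
with the remainder going to `shared`. Beyond the three informative classes
the simulator includes an `absent` class — unexpressed in both
compartments — sized as the complement of the three configured fractions.
This is essential realism: the slide-median detectability limit and the
top-25% intensity filter only behave as designed when most probes on an
array are unexpressed, as on real arrays. The default fractions
(3.2% exosome-only, 5.3% cell-only, 10.5% shared on 850 probes) mirror the
detected-set structure of the HMC-1 experiment the pipelines emulate.

Shared-probe enrichment effects are drawn Normal(0, `enrichment_sd`)
(default SD 1.5 — a free simulation parameter, not an empirically derived
one) and truncated at ±4 log₂ so that an expressed probe's abundance in its
weaker compartment stays above the detection floor; single-compartment
probes have their off-compartment abundance set to 5% of the background
level, below the background regime, so detection rules — not the simulator
— decide set membership. Enrichment is split symmetrically
(±true_log2fc/2) around the base intensity.

Dual-channel foregrounds are
`abundance × 2^(±δ(A)/2) × lognormal(cv) + background × lognormal(cv)`,
with the reported spot background an independent draw around the background
level (default 100). The dye bias δ(A) is a quadratic in standardized true
mean log-intensity scaled by `dye_bias_amplitude` (default 0.5 log₂ units)
and applied with opposite sign to the two channels, so A is unchanged and a
global Lowess fit of M on A is exactly the right remedy. Lognormal noise
factors have mean 1 and coefficient of variation `noise_cv` (default 0.1).
Single-channel signals are `abundance × lognormal(cv)` — background-corrected
by construction, emulating what the consumed upstream processing outputs —
and calls follow the stated rule P: signal > 3 × background level,
A: signal ≤ background level, M: between.

All randomness flows from the single config seed through named child
generators (truth / slides / expression), so each artifact is independently
reproducible and full runs are bit-identical for a fixed seed.

**What the simulator does not emulate:** probe-sequence effects and
hybridization thermodynamics, scanner saturation, spatial slide artifacts,
print-tip structure, dye-swap designs, and correlated noise between
replicate spots. Passing recovery tests therefore demonstrate that the
pipeline rules are implemented correctly and are the right remedy for the
modeled distortions (smooth dye bias, multiplicative noise, additive
background); they do not certify performance on artifacts outside the
model.

## Validation conditions and numerical choices

Noiseless recovery tests (noise and bias off) check that detected sets,
unique sets and Venn counts equal the simulator truth *exactly*. Noisy
recovery runs use `noise_cv` 0.1 at 5,000 probes and require ≥ 95%
agreement of detection membership and fold-change class with truth. For the
class-recovery condition the shared-probe effects are pinned to
{0, ±3} log₂: a true effect exactly equal to the ±2 classification
threshold sits on an inclusive decision boundary where symmetric
measurement noise misclassifies half the probes in principle, so boundary
accuracy is instead checked through the estimated means. The published
worked examples (27 exosome-only / 45 cell-only from the 116/134/89 totals;
15% from 1,849/12,346) are recomputed through the same set-algebra and
summary code paths used by the pipelines.

Degenerate inputs are pinned: empty truth tables propagate to clean empty
outputs; a probe excluded from every slide is missing, not zero;
`sd_log2_ratio` is undefined (missing) with a single contributing slide;
an empty cell detected set makes the detected fraction missing rather than
infinite. Ratio tables are written in a deterministic order (descending
mean, missing last, ties by probe id).

## Known limitations

* The Lowess span (0.3) and robustness iteration count (1) are conventions,
  not fitted choices; very sparse slides (< 8 usable probes) are rejected
  rather than smoothed.
* The intensity filter's pooled-group variant is not implemented as a
  separate code path (per-array is the default and only built-in).
* The simulator's P/M/A generator thresholds on the known simulated
  background; real call algorithms use probe-level statistics the package
  deliberately does not model.
* Between-slide normalization (e.g. quantile) is out of scope; slides are
  only comparable through their normalized ratios.
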