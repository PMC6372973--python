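# Methods

## Expression model and gene-set derivation

Expression values are log2 normalized intensities (microarray-like).
Replicates are averaged in log2 space before any ratio is formed, so a fold
change is the ratio of geometric means: `FC(g) = 2^(mean log2 A − mean log2 B)`.
Up-regulation uses a strict inequality (`FC > threshold`, default 2): a gene
exactly at 2-fold is excluded, matching a "more than 2-fold" rule.

Three crosswise day-8 comparisons define the gene sets HK (high- vs
low-KLF4), KER (keratinocyte vs MEF) and ESC (mESC vs MEF). The Venn
partition is exact set algebra over the shared gene universe. The
transient-MET set is `(HK ∩ KER − ESC)` plus the rescue rule: a triple-
intersection gene is re-admitted when its replicate-mean day-8 high-KLF4
expression strictly exceeds its mESC mean — transient induction that
overshoots the embryonic level even for mESC-expressed genes.

Dynamics classification compares each gene's replicate-mean time course
against the MEF baseline with `Δ = log2(fold_threshold)`: *induced* when
some day exceeds baseline by more than Δ; *transient* when additionally the
iPSC level returns to within Δ of baseline; *sustained* when the iPSC level
itself is induced. The silencing tolerance is deliberately symmetric with
the induction criterion, so a single fold threshold governs both calls.

Term enrichment is a one-sided hypergeometric over-representation test with
raw p-values ranked ascending and a fixed reporting cutoff (default
p < 10⁻³). Benjamini–Hochberg correction is available but off by default,
since the fixed-raw-p convention is what the enrichment lists reproduce.

Anti-correlation screening computes Pearson r between each gene and a
reference over the replicate-averaged high-KLF4 series ordered by day (the
MEF mean is prepended as the pre-induction point when MEF samples exist);
genes with r in a closed band (default [−1.0, −0.9]) are selected.
Zero-variance profiles have no defined r and are excluded with a warning.

The two-sample test used throughout is the pooled-variance Student's t
(two-sided).

## Synthetic expression data

The generator emulates a two-condition reprogramming time course (days
0–18, default 0/2/4/6/8/18, 2 replicates) plus terminal MEF, mESC, iPSC and
keratinocyte samples. Six planted gene classes define template profiles
(fibroblast decline; sustained-MET induction retained in iPSC/mESC;
transient-MET induction from ~day 4 only under high KLF4, keratinocyte-
expressed, silenced in iPSC; mESC/iPSC-specific; keratinocyte-specific;
flat background). Defaults: 2000 genes, induction amplitude 2 log2 units,
additive Gaussian log2 noise with SD 0.25 — a typical well-measured
microarray effect-to-noise regime; the per-gene effect-size distribution of
real transient induction is not identifiable from the published summaries,
so a single amplitude is used for scoreability. A configurable 12% of the
transient class (24 of 200 at defaults) is additionally mESC-elevated at
0.6× the amplitude — above the 2-fold cutoff over MEF, below the day-8 peak
— which is exactly the population the rescue rule must recover.

What the generator does *not* model: probe-level effects, batch structure,
correlated noise between genes, partial penetrance of induction. Passing
recovery tests therefore demonstrates the correctness of the set logic and
robustness to independent measurement noise, not performance on real
microarrays.

The anti-correlation simulation plants negative affine transforms of a
reference profile over 9 time points with per-gene noise calibrated from
the design variance: `Var(noise) = b²·Var(x)·(1/ρ² − 1)` gives population
correlation ρ (default −0.95). With a fixed design and noise-only
randomness the sampling SD of r is ≈0.03, so recall of the [−1.0, −0.9]
band is ~0.95.

## Colony counting

Background subtraction is a grayscale white tophat (image minus its opening
with a disk structuring element; default radius 3× the largest expected
colony radius). The published macro's background model is not specified
beyond "background-subtracted images"; the tophat removes any flat or
slowly varying background exactly while preserving colony-scale objects,
and its residual on a linear ramp of amplitude A is bounded by
`A·(2r/width)`.

Channel thresholds follow the stated rule: mean of reporter-negative colony
intensities plus 5 sample SDs (n−1 denominator). Negative references can be
user-supplied annotations or, in the simulated workflow, the measured means
of planted reporter-negative colonies — GFP-negative colonies calibrate the
GFP threshold and mCherry-negative ones the mCherry threshold. Colony
positivity compares the colony-*mean* intensity against the threshold with
a strict inequality (ties negative), consistent with the "mean intensities
of colonies" wording; segmentation uses 8-connectivity and a 50-px minimum
area. Detection runs on the pixel-wise maximum of the subtracted channels,
so reporter-negative colonies are still found via their autofluorescence
base level.

The simulator plants non-overlapping disks (base level in both channels +
class offsets + optional radial falloff) on background + linear gradient +
Gaussian pixel noise, clipped to 16 bits. Default wells are 256×256 px with
25 colonies of radius 5–9 px; at these sizes 50 wells quantify in seconds.
Irregular colony morphology is out of scope — truth scoring requires
unambiguous geometry.

## Flow cytometry

Channels are simulated and analyzed on linear scale; log10 transforms are
applied only for density estimation, mirroring cytometry convention.
Spillover compensation is assumed done upstream. MFI is the sample median
(mean of the central pair for even n). Gates are single-channel thresholds,
by default at the 99.5th percentile of a negative-control distribution;
positivity is strict. Quadrant proportions are invariant under any strictly
monotone transform applied jointly to a channel and its gate.

Bimodality detection: Gaussian KDE with Silverman bandwidth on log
intensities, evaluated on a 512-point grid. A channel is bimodal when two
local maxima exist such that the minor side of the between-modes minimum
holds ≥ 5% of the mass and the valley density sits ≥ 10% below the lower
peak. Both guards exist to keep the false-positive rate on unimodal
log-normals at or near zero (measured ≤ 5% over 200 simulations); a 1%
contaminant population is deliberately *not* called bimodal.

## Screen calling

Control statistics are the sample mean and SD (n−1) of the no-sgRNA
readouts; screening thresholds sit at mean ± 3·SD (multiplier
configurable). Flags use strict inequalities (a value at the bound is
"within"). A gene is a hit for a readout/direction when at least k of its
sgRNAs agree; the default k = all sgRNAs encodes "consistent across all
five guides". Under the null with known thresholds the per-trial false-call
probability is Φ(−3)⁵ ≈ 4.5×10⁻¹⁵ per direction, and the measured count
over 10⁶ simulated gene-trials is 0; the analytic power for a ±6σ₀ shift is
Φ(3)⁵ ≈ 0.993. These operating characteristics are evaluated with the true
control parameters, isolating the rule itself; when thresholds are instead
re-estimated from 10 control replicates per experiment, threshold noise
lowers power to ≈0.97 and dominates the (vanishing) null error — the
estimated-threshold variant is available via
`evaluate_screen_power(estimate_thresholds=True)`. Per-sgRNA readouts are
single measurements taken at face value; no per-sgRNA variance model is
fitted.

## Indel decomposition

The edited trace is modeled as a non-negative mixture of copies of the
control trace shifted by each candidate indel size k in ±W (default W = 10,
the conventional decomposition-window default; configurable). Calibration
first finds the integer alignment offset (±5) and least-squares intensity
scale over the pre-cut region; a normalized upstream RMSE above 0.2 after
the best calibration raises a trace-quality error. Decomposition solves
`min ‖y − S f‖², f ≥ 0` by NNLS over the four stacked base channels in a
region from 5 positions after the cut to W positions before the trace end,
and reports R² = 1 − RSS/TSS. Frequencies are reported unnormalized, with
the shortfall from 1 being unexplained signal; renormalization to a
100%-sum distribution is opt-in and gated on an R² floor. Coordinates are
0-based and the cut site indexes the first base downstream of the blunt
cut; insertions shift downstream signal right (k > 0), deletions left.

Frame classes partition the spectrum exactly: WT = f₀, in-frame =
Σ{fₖ : k ≠ 0, k ≡ 0 (mod 3)}, and the two frameshift classes collect
k ≡ 1 and k ≡ 2, with the mathematical modulus mapping negative sizes into
{0, 1, 2} (a 1-bp deletion is a 3n+2 shift). Population comparison reports
per-class ratios B/A, undefined when the class is absent from A.

An exhaustive simplex grid search serves as an independent oracle for small
windows: resolution 0.01 for W = 1 and 0.02 for W = 2 (the 0.01 grid at
W = 2 has ~10⁸ points and is not worth the runtime; agreement is asserted
to the resolution used).

The trace simulator builds a control chromatogram from a random sequence
(called-base peaks with ±20% amplitude variation plus small background
peaks) and composes the edited trace with exactly the mixture model the
decomposition inverts, optionally scaled and perturbed by multiplicative
Gaussian noise — so noise-free recovery is exact by construction, and the
5%-noise benchmark measures conditioning rather than model mismatch. Real
chromatograms add base-calling artifacts, dye blobs and position-dependent
peak widths that this model does not emulate; AB1 parsing is out of scope
(traces arrive as 4-column peak-height CSV).

## Determinism and problem sizes

Every generator is a pure function of (config, seed); a single master seed
is split with a spawning sequence so sub-streams are independent, and all
derived integer seeds stay below 2³¹. The recovery evaluations use 2,000
genes for set logic, 20,000 for dynamics, 50 wells per imaging condition,
10⁶ gene-trials for screen specificity, 1,000 reps for power, 100 seeds for
indel noise and 200 for bimodality false positives — sizes chosen so each
quantity's Monte-Carlo error is well inside its decision margin while the
whole evaluation completes in well under a minute per stage.

## Known limitations

- Gene counts on real deposited microarray data are not an accuracy target;
  the published 622/200/607 list sizes depend on the original normalization
  pipeline and annotation release, neither of which is reproduced here.
- The "large colony" criterion is exposed as an area percentile with no
  claimed default, since no size cutoff is published.
- The gate-placement rule (control percentile) is this package's
  convention; the original gates were drawn by eye.
- The decomposition significance machinery of the original trace-
  decomposition tool (per-allele p-values) is not reimplemented; R² and the
  residual play that role here.
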