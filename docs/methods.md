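# Methods

`remdiff` implements the pattern-similarity analysis used to ask whether
REM sleep drives hippocampal *neural differentiation* after prediction
errors, together with a synthetic-data generator that plants the effects
the analysis is meant to detect. This note documents the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic data can and cannot tell you about real recordings.

## The measurement model

**Design.** Participants learn A→B scene pairs by statistical exposure.
Each of 6 learning runs holds 16 pairs (8 violation, 8 nonviolation). A run
opens with a snapshot phase — every A and B shown once, randomly ordered,
with the constraint that a pair's B never immediately follows its own A —
followed by a learning phase interleaving per-pair templates: violation
pairs `AB-AB-AB-AX-B-AY-B` (X, Y novel faces; B restudied alone after each
violation) and nonviolation pairs `AB-AB-AB-B-B`. The interleaving keeps
between 2 and 20 intervening pair-events between successive events of the
same pair. Trials are 1 s stimulus + 2 s ISI. Both conditions expose every
B exactly 6 times in session 1. Session 2 re-presents all 96 B scenes in
one 96-trial run and all 96 X/Y faces in another.

The interleaver is a randomized greedy constructor: at each slot, any pair
at its maximum-gap deadline is placed; otherwise a pair eligible under the
minimum gap is drawn with probability proportional to its remaining event
count (this bias sharply reduces dead-ends near the end of a run).
Infeasible partial sequences abort and the attempt restarts, up to 10,000
attempts per run before a `DesignError` reports the attempt count. The
2..20 rule is enforced in pair-events (the units a pair occupies in the
stream), not trials, and applies to the learning phase only.

**Snapshots.** A snapshot is the spatial voxel pattern at the peak of the
hemodynamic response, 4.5 s after image onset — with a 1.5-s TR, exactly
three volumes after onset. Runs are post-processed minimally: drop 9
lead-in and 5 tail volumes, regress out an SPM-style discrete-cosine basis
with a 1/128 Hz cutoff, z-score every voxel over time (population SD).
Extraction samples the single nearest volume, rounding half up, with the
discard offset subtracted explicitly so onsets stay on the acquisition
timeline. Voxels are ordered by ascending linear index of the mask volume.
We deliberately use a single volume (no multi-TR averaging, no GLM betas):
the snapshot is defined at the peak, and with a 1.5-s TR the peak is
sampled exactly.

**Statistics.** For each pair, pattern similarity is the Pearson
correlation of pre-learning A with post-learning B, Fisher z-transformed
(`z = atanh r`). The *differentiation score* is the violation-minus-
nonviolation difference of condition-mean z; negative values mean the
violated pairs moved apart. Item specificity is a randomization test:
B-to-pair assignments are shuffled 1,000 times within condition (uniform
over permutations, identity allowed), the score recomputed per shuffle, and
the observed score z-scored against the null's mean and sample SD (ddof 1).
*B prediction* is the mean Fisher-z correlation of pre-learning B with the
patterns evoked by that pair's X and Y violation events; the
prediction-differentiation *coupling* is the across-pair Pearson
correlation of this score with pairmate similarity, one r per subject,
Fisher-z for group analysis. The B-X-Y integration control replaces the
prediction score with the mean Fisher-z correlation of post-B with the
post-learning X/Y snapshots.

Group inference uses planned one-way contrasts with pooled within-group
variance (REM −1, NREM 0.5, Wake 0.5; then NREM −1 vs Wake 1), df = N − k,
effect size d = 2t/√df; one-sample t tests against zero per group with
d = t/√n, one-tailed in the REM group for preregistered-direction metrics;
Bonferroni families of k = 6 ROI contrasts (α = 0.008) and k = 3 group
follow-ups (α = 0.017). Two-group sleep comparisons dispatch on
Shapiro–Wilk (α = 0.05 per group) to a Wilcoxon rank-sum test, otherwise on
median-centered Levene (α = 0.05) to Welch's or Student's t. The d
conventions are inferred from the reported (t, d) pairs, which they
reproduce to two decimals; the normality/homogeneity diagnostics are our
choices — the source analysis names only the fallback tests.

**Degenerate inputs.** Correlations of zero-variance patterns raise with
the offending item named. |r| = 1 (possible on noise-free toys) is clamped
to ±(1 − 1e-12) before `atanh` with a warning, so toy tests remain runnable
without affecting realistic data. A randomization null with zero spread
(e.g. all post-B rows identical) raises rather than returning an infinite
z; the degeneracy check is relative (sd ≤ 1e-12 × max |null|) because
bit-identical shuffle scores can differ by float-summation dust.

## The generative model

Each pair owns four latent feature blocks — shared (k_s = 24), A-unique and
B-unique (k_u = 12 each), and novel (k_n = 12) — realized as random
directions with fixed norms inside mutually orthogonal subspaces of voxel
space (stacked QR of Gaussian matrices, restricted to the voxel-mean-zero
hyperplane so Pearson correlations of noise-free patterns are exact
cosines). Patterns:

* pre-learning A = shared + A-unique; pre-learning B = shared + B-unique;
* post-learning B, violation = (1 − d_p)·shared + B-unique + d_p·novel;
* post-learning B, nonviolation = (1 + δ_int)·shared + B-unique;
* violation-event evoked = face + π_p·(shared + B-unique), the covert
  reactivation of the expected B;
* d_p = clip(δ_diff + κ·(π_p − mean π), 0, 1), with π_p drawn from a
  truncated normal on [0, 1].

Each pair's X/Y faces are drawn orthogonal to that pair's scene subspace so
the evoked pattern mixes face and reactivated B without pair-varying cross
terms. White Gaussian noise (sd 1) is added per trial and voxel. The
ground truth (every π_p, d_p, and all latent components) is returned with
the subject.

The linear π→d coupling is the simplest monotone stand-in for the
moderate-activation→weakening arm of the nonmonotonic plasticity rule:
within the regime this task probes, more covert reactivation of the
mispredicted B means more subsequent differentiation. Differentiation is
applied to post-B only, with pre-A as the fixed baseline, matching the
analysis' use of pre-A to avoid item-frequency confounds. The integration
channel (δ_int, nonviolation only) encodes the observation that the group
difference was driven by *higher* nonviolation similarity with REM sleep.

**Default study conditions.** Three groups of 23 subjects (Wake, NREM,
REM). Wake and NREM carry zero effects (reactivation π still occurs —
prediction happens in everyone; only its consequence is sleep-dependent);
REM carries δ_diff = 0.5, δ_int = 0.2, κ = 1.5, π ~ TN(0.5, 0.2). With
k_s = 24, k_u = 12 and noise sd 1 at 500 voxels, the per-voxel signal SD is
≈ 0.27 of the noise, giving pairmate similarities of r ≈ 0.03–0.08 — the
magnitude regime of real hippocampal pattern-similarity values — and a
per-subject differentiation effect of roughly 2.4 SE, i.e. detectable but
not trivial. These magnitudes were fixed once from this design calculation;
the source study does not quantify effect sizes in similarity units, so
they are package choices, not reproduced values.

**BOLD rendering.** Optionally, trial patterns are rendered into a 4D
time series: each trial contributes its pattern scaled by a canonical
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6, peak-normalized)
sampled at the volume times, summed over overlapping trials, plus optional
white noise; 9 lead-in and 5 tail volumes are prepended/appended so the
discard step of preprocessing is exercised, and the returned events carry
acquisition-timeline onsets.

**Hypnograms.** The generator emits a plausible nap course (sleep-onset
latency, N1, descent to N3, return through N2, REM last, wake-after-onset
bouts at random block boundaries) whose per-stage totals equal the
requested minutes *exactly*, in 30-s epochs. Default targets are the
observed group means rounded to the epoch grid: NREM group N1 6.5 / N2 22.5
/ N3 20 / REM 0 / WASO 9 of 65 min in bed; REM group N1 9 / N2 42 / N3 22 /
REM 16.5 / WASO 14 of 114 min. Spindles are placed uniformly within N2/N3
epochs at Poisson rates of 4.3/min (N2) and 5.15/min (N3). Sleep scoring:
TIB spans lights-off to lights-on, sleep onset is the first non-wake epoch,
WASO counts all wake from onset to lights-on (terminal wake included),
percentages are of TST. Nap classification: any REM epoch → REM group; else
a consolidated sleep bout ≥ 10 min (configurable) → NREM; else reassigned
to Wake — the experimenters' "short, fragmented bouts" rule is qualitative,
so the threshold is an exposed parameter.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analysis depends on:
item-specific pairmate geometry, condition-dependent representational
change, trial-level covert reactivation coupled to later change, realistic
similarity magnitudes, and measurement noise. It does not emulate spatial
autocorrelation, physiological or motion artifacts, scanner drift beyond
what the high-pass filter removes, inter-regional structure, or
between-subject variance in effect size (all subjects in a group share one
effect configuration). Passing tests therefore certify that the pipeline
measures what it claims to measure when the planted model holds — they do
not certify sensitivity under realistic artifact regimes.

Per-voxel z-scoring rescales every voxel by its temporal SD, which is
estimated from finitely many trials; extracted patterns therefore match
ground truth only up to a per-voxel factor common to all trials of a run.
At the task's rapid 3-s SOA, HRF overlap additionally mixes neighboring
trials into each snapshot (the overlap is verified against a direct
convolution oracle). The high-fidelity round-trip check (r > 0.99) is
accordingly run on a slow event-related variant of the 96-trial snapshot
run (60-s SOA via `design.respace_run`), where both distortions are small;
pattern *similarity* analyses are largely insensitive to the per-voxel
factor because it is shared across items.

## Problem sizes used in validation

Simulation-based checks are sized to single-CPU desk scale: null
calibration uses 500 zero-effect subjects at the full design with
128-voxel ROIs and 1,000 shuffles; contrast type-I error uses 1,000
cohorts of 3 × 6 subjects at a reduced design (2 runs × 8 pairs, 80
voxels); recovery uses 200 REM subjects at 500 voxels (per-subject sign)
and 30 cohorts of 3 × 10 subjects at 150 voxels (group-level signs).
Subfield-sized ROIs of 80–500 voxels are the realistic range for
high-resolution hippocampal masks; note that per-pair similarity SNR
*improves* as ROIs shrink (signal slope ∝ 1/n_vox, correlation noise
∝ 1/√n_vox), so the smaller ROIs are not a soft setting.

## Known limitations

* The interleaver is rejection-based; extreme parameter combinations (few
  pairs, tight spacing windows) are reported as unsatisfiable rather than
  solved exactly.
* `simulate_cohort` shares one design-generation policy and one effect
  configuration per group; subject heterogeneity must be modeled by the
  caller if needed.
* The nap generator produces one sleep cycle; multi-cycle architectures
  (full nights) would need different block logic.
* The B-X-Y integration channel is not planted by the generator; its
  coupling is expected null, which the control-analysis tests verify.
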