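# Methods

`rulemvpa` implements a complete, self-testing analysis pipeline for
time-resolved multivoxel pattern analysis (MVPA) of newly instructed
stimulus–response (S–R) rules. Because the scientific question — *is the
identity of a just-instructed rule represented in distributed prefrontal
activity from the very first implementation trial?* — hinges on subtle
statistical properties of the trial sequence and the single-trial estimator,
every stage of the pipeline is built to be validated against synthetic data
with known ground truth. This note documents the models, the defaults, and
the design choices that were genuinely open.

## Task and design model

Participants work through many short task blocks. Each block has an
instruction phase (novel written nouns paired with manual responses via
flanking cue bars) and an implementation phase in which four nouns are each
presented repeatedly (4 repetitions in the two-difficulty layout, 8 in the
learning-vs-control layout) and the memorized response must be executed.
Key timing constants: announcements of 2 s, instruction items of 2 s (4
items) or 1 s (10 items in the difficult condition), SOAs drawn from
{2.0, 2.5, 3.0, 3.5, 4.0} s (onset-to-onset, inserted *before* each trial so
the first trial is jittered against the instruction phase), inter-phase
delays of 2 or 4 s balanced exactly within condition, and 2 s feedback.
Default layouts: 3 runs × 12 blocks (18 per condition; 192 implementation
trials per run) for the 4-repetition experiment, and 3 runs × 8 blocks (12
per condition; 256 trials per run) for the 8-repetition experiment. Every
block consumes a fresh stimulus set, response maps use 2 or 3 distinct
responses in deterministic alternation within condition, and the difficult
condition implements a uniformly chosen 4-of-10 subset constrained to cover
the block's response count.

**Atomic sequences.** An implementation *stage* is a pair of consecutive
repetitions of every stimulus (stage s = repetitions 2s−1, 2s). The trial
order of each stage is an independently randomized "atomic" 8-trial
sequence: exactly two occurrences of each of the four stimuli, uniform over
admissible arrangements. With overlapping BOLD responses, single-trial
estimates cross-contaminate in a sequence-dependent way; per-stage
randomization makes the similarity statistic unbiased *in expectation over
sequences*, whereas a single fully randomized sequence split into stages
retrospectively has a systematic positive bias. Our Monte-Carlo bias suite
reproduces both facts: across ≥200 freshly randomized blocks at paradigm timing
the atomic scheme's grand-mean bias is within Monte-Carlo error of zero
while the retrospective scheme's is reliably positive (≈ +0.05–0.07
correlation units); the per-block bias *spread* is comparable between
schemes — the defect of naive randomization is its nonzero mean, not extra
variance.

The bias oracle simulates noise-free data in which every trial carries an
independent random pattern, runs the actual LSS estimator, and computes the
stage statistic (`design.estimate_sequence_bias` for a standalone block,
`design.estimate_design_bias` for all blocks of a run fitted jointly in
their real regressor environment — the variant the validation suites use).
Prewhitening is off in the oracle: the residual-based AR(1) estimate is
degenerate on noise-free data, and whitening is a fixed linear transform
applied to all regressors alike, so it does not change the bias structure.
A second, independent route through the LSS linear map (betas = A·patterns
with A computed once) cross-checks the full-refit route in the tests.

## Single-trial GLM (LSS)

Each implementation trial's amplitude is estimated by its own least-squares-
separate model: one regressor for the target trial, one for all other
implementation trials of the run, plus nuisance terms — a 20-column Fourier
basis for the instruction condition, one aggregate feedback regressor, a run
constant, and a discrete-cosine high-pass set with K = floor(2·N·TR/cutoff)
columns (cutoff 128 s for the 4-repetition layout, 256 s for the longer
blocks of the 8-repetition layout). Sticks at stimulus onset are convolved
with the canonical double-gamma HRF (peak 6 s, undershoot 16 s, unit
dispersions, ratio 6, 32 s support) at microtime resolution TR/16, sampled
at the middle microtime bin. Announcement displays are deliberately left
unmodeled (baseline). Optional AR(1) prewhitening estimates one pooled rho
per run from mean-model OLS residuals (lag-1 autocorrelation over all mask
voxels, clipped to [0, 0.95]) and applies the standard AR(1) transform;
`ar1="off"` and a fixed rho of 0 are bit-identical.

**Instruction basis.** The 20 "sine-wave" regressors are an order-10
sine+cosine Fourier set over a 44 s window time-locked to instruction onset,
built per the condition-×-basis convention: each basis function repeats at
*every* instruction onset of the run, giving one shared 20-column set. This
matters: a separate 20-column set per block would nearly saturate each 44 s
window (22 TR samples) and destroy the estimability of all trials inside
it — precisely the early stage-1 trials the analysis is about. With the
shared set, early trials keep their information and stage-1 effects are
recoverable. `GlmConfig.fourier_per_phase=True` exposes the per-block
variant for comparison.

**Efficiency.** The per-trial design [target, others, nuisance] spans the
same space as [target, sum-of-all-trials, nuisance], so one QR factorization
of the shared columns serves all trials; the target beta is the sum of the
two coefficients in the reparametrized fit. This is algebraically exact
(tests verify ≤1e−9 agreement with naive per-trial least squares) and makes
the 768 models of an 8-repetition subject cost fractions of a second.

**Exactness caveat.** Noiseless, non-overlapping trials are recovered to
machine precision only when the nuisance space is orthogonal to the trial
regressors; DCT drift columns are not, so the fidelity tests disable the
high-pass. With drifts included, isolated-trial recovery is unbiased but not
exact.

## Identity-specific pattern similarity

For one block-stage (8 trials, each stimulus twice), all pairwise Pearson
correlations over voxels are computed from the single-trial betas; the
statistic is Δ = mean(4 same-stimulus pair correlations) − mean(24
different-stimulus pair correlations). No voxel-wise normalization and no
Fisher transform by default (a flag exists). Block-stage deltas are averaged
per condition × stage per subject; in the 8-repetition layout stages can be
aggregated to early = mean(stages 1, 2) and late = mean(stages 3, 4). All
trials enter by default, errors included; a correct-only variant drops cells
whose label counts fall below two.

**White-matter bias adjustment.** Residual per-block bias is measured in a
white-matter control volume (which receives trial-locked amplitude but no
identity code) and removed by regressing, within each condition × stage
cell, the ROI block deltas on the paired white-matter block deltas; the
adjusted estimate is the regression *intercept* — the ROI delta expected at
zero measured bias. (The residual mean would equal the raw mean and remove
nothing.) Zero-variance white-matter deltas trigger a warning and fall back
to the unadjusted mean; the white-matter region itself is never adjusted
against itself. Adjustment is applied per cell before condition averaging;
the alternative order (adjust after averaging) is a documented option left
unimplemented.

The searchlight variant computes the same statistic in spheres of radius 3
voxels (123 lattice points in an open field, center included, Euclidean
distance in voxel units), assigning each delta to the center; spheres with
fewer than 2 usable voxels are missing.

## Synthetic data generator

The phantom atlas packs six disjoint compact regions (default 200 voxels
each on a 24³ grid of 3 mm voxels): a prefrontal signal region, a
dorsolateral null region, visual and motor regions, white matter, and
striatum. Each implementation trial contributes, in every region, a mean
amplitude that declines over repetitions (default 2.0 → 0.75 across 8
repetitions) plus region-specific identity codes: block-local rule-identity
patterns (s.d. 0.6) in the signal region for memorization conditions only;
stimulus-identity (s.d. 0.6) and executed-response-identity (s.d. 0.6)
patterns in visual/motor for all conditions; nothing identity-specific in
the null region, white matter, or striatum. An i.i.d. per-trial pattern
(s.d. 0.3) and a region-wide trial-amplitude jitter (s.d. 0.5) are added;
the signal-region and striatal jitters are drawn from a bivariate normal
whose correlation is the configured coupling (default 0.1 early rising to
0.6 late in the learning condition, flat 0.1 elsewhere — the connectivity
effect to be recovered). Everything is convolved with the same canonical
HRF at TR = 2 s; instruction phases add a boxcar response (amplitude 1.0,
no identity code), feedback an event response (0.5); stationary AR(1)
Gaussian noise (s.d. 1.0, rho 0.3) is added per voxel. The effect-size
defaults are arbitrary in the sense that only test statistics, not signal
amplitudes, constrain them; they were fixed once at values giving comfortable recovery for
a 20-subject cohort and are documented here rather than tuned per test.

Behavior follows a per-condition error probability declining linearly over
repetitions (easy/learning 0.15 → 0.03, difficult 0.45 → 0.12, control
0.05 → 0.03), with perseveration: an error repeats a previously executed
wrong response with probability 0.6. In memorization conditions the
reference response is the one last executed for that stimulus (so a
committed wrong rule is subjectively stable); the cued control condition
resets to the instructed response every trial. Correct-trial RTs are
Gaussian with linearly declining means. Error trials still carry the
stimulus-linked rule pattern in the signal region and the *executed*
response's pattern in motor.

What the generator does **not** emulate: physiological noise, motion,
susceptibility dropout, spatial autocorrelation of noise, HRF variability
across regions or subjects, and any nonlinearity (saturation) of the BOLD
response. Passing recovery tests therefore demonstrate the *estimator
chain* is correct and unbiased under its own assumptions — not that real
data meet those assumptions.

## Group inference

Within-subject factorial ANOVAs are built from orthonormal contrast
variables (Kronecker products of per-factor orthonormal contrasts and
averaging vectors). F is the ratio of contrast mean squares;
Greenhouse–Geisser ε = tr(Σ)²/(q·tr(Σ²)) from the contrast covariance scales
both degrees of freedom; partial η² = SS_eff/(SS_eff+SS_err); the constant
term tests the grand mean against zero and equals the squared one-sample t.
Linear-trend contrasts over numeric factors use the normalized centered
polynomial. The implementation is validated against statsmodels' AnovaRM,
pingouin, and a direct sums-of-squares oracle in the tests. Voxel-map
family-wise error uses sign-flipping max-statistic permutation (corrected
p = (1 + #{perm max ≥ t})/(n_perm + 1)), a deliberate substitution for
random-field theory: assumption-light, exact under symmetric nulls, with a
resolution floor of 1/(n_perm+1). Post-hoc cell tests are reported
uncorrected and labeled as such.

## Beta-series connectivity

The seed series is the unweighted mean single-trial beta over seed voxels.
Connectivity in a window is the Fisher-z Pearson correlation over the
selected trials, pooled across blocks within condition × window (per-block
correlation with averaging is available as an option; windows per block are
only 8 trials). The learning contrast is
(z_late − z_early)_learning − (z_late − z_early)_control with early =
repetitions {1, 2} and late = {7, 8}; error trials are excluded, and a
window with no usable trials flags the subject as missing.

## Validation-suite problem sizes

Chosen once as desk-scale stand-ins and fixed: bias suites use 17
freshly seeded full 12-block runs per scheme (204 blocks) at 100 Monte-Carlo
pattern draws per run with 40 voxels; the recovery cohort is 20 subjects at
the full 8-repetition layout and default atlas; null calibration runs 100
cohorts of 15 subjects on a reduced grid (one run of six 4-repetition
blocks, ROI-only phantom with a 48-voxel signal region) with
sigma_identity = 0, testing the ANOVA constant term at α = 0.05 against its
95% binomial band; the connectivity null runs 10 cohorts of 12 subjects on
a reduced 8-repetition grid with flat coupling.

## Known limitations

- The trial-amplitude model is linear in the HRF; nonlinear interaction of
  responses at 2 s SOAs is not modeled (the GLM makes the same assumption).
- One pooled AR(1) coefficient per run (no voxel-wise or spatially
  regularized noise model).
- The white-matter adjustment assumes the bias measured in white matter is
  the same linear bias operating in gray-matter ROIs; this holds by
  construction in the generator and only approximately in real data.
- `estimate_sequence_bias` on a standalone block places the instruction
  basis inside the block's own mini-run, which saturates the early window;
  use `estimate_design_bias` for run-context bias.
- Searchlight maps loop Python-level over centers; they are intended for
  phantom-scale grids, not whole-brain 2 mm data.
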