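# Methods

`statedyn` re-implements, as a tested pipeline, an analysis paradigm for
brain-network dynamics during naturalistic listening: a group-level hidden
Markov model (HMM) over parcellated fMRI time series, occupancy and
transition metrics per stimulus condition, and mean-centred partial least
squares (PLS) with permutation and bootstrap inference.  Because the human
data the paradigm was developed on are not publicly deposited, the package
ships a synthetic multi-subject generator that emulates the study design
with known ground truth; every claim the test suite makes is a claim about
recovering what the generator planted.

## The observation model and its estimation

Each subject contributes an ROI × volume matrix (defaults: 1,440 volumes
at TR = 0.475 s; 20 ROIs at desk scale, 220 available via config).  ROI
rows are z-scored per subject (mean 0, variance 1) to remove
between-subject amplitude differences; constant rows are zeroed and
flagged rather than rejected.

One Gaussian-observation HMM is fitted to all subjects concatenated along
time.  A state k is a multivariate Gaussian N(μ_k, Σ_k) over ROI
activity; dynamics are a row-stochastic K × K transition matrix A and
initial distribution π.  The forward–backward recursions restart at every
subject boundary, so transitions are never counted across subjects.
Estimation is maximum-likelihood EM (Baum–Welch):

- scaled (Rabiner-style) forward–backward with the per-volume max
  log-density factored out, stable for runs of 10,000+ volumes;
- k-means initialisation; `n_restarts` seeded restarts (seed + r), best
  final log-likelihood wins;
- full covariances by default (diagonal via config) with a ridge of
  `reg · trace(Σ)/R` on the diagonal (default reg = 1e-6);
- convergence at relative log-likelihood improvement < 1e-6 or
  `max_iter`; the per-iteration log-likelihood trace is retained and is
  non-decreasing up to the covariance regularisation;
- an empty state is re-seeded once from a random data point; a second
  collapse flags the fit non-converged.

The reference method used a variational (free-energy) HMM.  This package
deliberately uses maximum-likelihood EM with a penalised-likelihood model
order criterion standing in for free energy:

    criterion(K) = −log L + ½ · p(K) · log T,

a BIC-style quantity with p(K) the free-parameter count.  It is
deterministic, fully specifiable, and plays the same role (lower is
better, ties go to smaller K).  The default sweep is K = 3..20; the
analysis scripts sweep 3..8 because the planted truth at desk scale is
K = 4 and the criterion curve is steeply convex around it.

Decoding defaults to the per-volume posterior argmax (ties to the lowest
state index); Viterbi is available.  States of two estimations are
matched by the dot-product matrix of unit-normalised state means: optimal
one-to-one assignment (Hungarian algorithm), or per-row argmax for
unequal K.

## State metrics

All metrics are computed from the hard decoded path (posterior-weighted
variants are not the default, matching the convention of assigning each
volume to its single best state):

- **Fractional occupancy (FO)** — the proportion of volumes inside a set
  of windows spent in each state.
- **Transitional probability (TP)** — within-window one-step transition
  counts, row-normalised; the diagonal is persistence.  Transitions are
  never counted across window or subject boundaries (counting across
  discontiguous windows would fabricate transitions).  Rows with no
  outgoing transitions stay undefined (NaN) and propagate as missing —
  never zero-filled.
- Excerpt windows are half-open volume ranges
  `[floor(onset/TR), floor((onset+duration)/TR))`, clipped to the run;
  rating prompts are excluded.  A 20 s excerpt at TR 0.475 s spans 42 or
  43 volumes depending on onset phase.
- Condition vocabulary for the tidy tables: `all` (full run), the three
  excerpt categories, and `rest` (the leading rest block before the
  first excerpt).
- Per-excerpt FO vectors and row-major vectorised TP matrices are
  correlated (Pearson by default; Spearman available, sensible for
  4-point Likert inputs) with the subject's liking and familiarity
  ratings across excerpts, with pairwise deletion of missing entries.
- Functional connectivity is the ROI × ROI Pearson matrix across volumes.

## Mean-centred PLS

Feature rows are stacked subjects within conditions within groups.  A
centering scheme maps the (group × condition) cell means — always
unweighted, so the 44/27 group imbalance does not tilt contrasts — to a
matrix M:

- `group_main`: group means − grand mean (group effects);
- `within_group`: condition means − own group mean (group main effect
  exactly zero; task and task-by-group effects);
- `full_factorial`: all cell means − grand mean (group, task, and
  interaction together).

The SVD of M gives latent variables (design saliences u, feature
saliences v, singular values s); LV scores are the dot product of subject
feature rows with v.  Sign convention: each LV's largest-magnitude
feature salience is positive.

**Permutation test.**  The exchangeable unit follows the scheme: schemes
with group effects permute group labels across subjects; `within_group`
permutes condition labels within subject.  p uses the add-one estimator
p = (1 + #{s_perm ≥ s_obs}) / (1 + n_perm), compared per singular-value
index; defaults n_perm = 1,000 (the analysis scripts and calibration
harnesses use 200–500).

**Bootstrap.**  Subjects are resampled with replacement within group.
Each bootstrap solution is aligned to the original by orthogonal
Procrustes rotation before accumulation.  Standard errors are taken on
the singular-value-scaled saliences v·s: when the LV count equals the
feature count the unscaled v's form complete orthonormal bases and
Procrustes would align them perfectly, collapsing the SE to zero; the
scaling carries the sampling variability.  The bootstrap ratio
(original scaled weight / bootstrap SE) reads like a z-score with
|BR| ≥ 2 as the default reliability threshold.  95% percentile CIs are
reported for centered cell-mean LV scores.

## The synthetic generator

The generator defines the study conditions: 44 younger / 27 older
subjects; runs of 1,440 volumes at TR 0.475 s (11.4 min); a leading rest
block (108 s under defaults — the schedule's unused remainder, since the
protocol does not pin the rest length) followed by 24 excerpts of 20 s
(6 self-selected / 10 popular / 8 novel) in seeded random order, each
trailed by a 2 s + 2 s rating prompt that is scheduled but excluded from
excerpt windows.

Hidden dynamics are condition-switched Markov chains: the transition row
used for the step into volume t belongs to the condition volume t falls
in (rest outside excerpt windows).  The analysis fits a single HMM, but
the generator must plant condition effects for recovery tests, and
switching the matrix at window boundaries makes those effects recoverable
by construction.  Default planted structure (state convention at K = 4:
0 medial fronto-parietal, 1 temporal/perception, 2 temporal-mesolimbic/
reward, 3 fronto-parietal):

- base persistence 0.80, off-diagonal mass uniform;
- self-selected music: reward-state persistence 0.92 and doubled
  transitions into it (both groups);
- experimenter-selected (popular/novel): perception-state persistence
  0.90 (younger) / 0.85 (older);
- older group: ×1.8 (novel) and ×1.3 (popular) transitions into the
  reward state — the dedifferentiation signature;
- group main effect: +0.03 persistence on the perception state (younger)
  or fronto-parietal state (older) in every condition.

State means are N(0, separation²) per ROI (separation 2 by default —
well-separated, appropriate for recovery tests; separation 0 collapses
all states).  Covariances are `noise² (I + 0.1²·AAᵀ/R)` with A standard
normal, guaranteeing positive definiteness.

**Ratings.**  Liking and familiarity are thresholded latent bivariate
normals (cut points −1.2, 0, 1.2 → levels 1–4).  Latent means shift with
the excerpt window's reward-state occupancy (slope 2.2 younger /
1.0 older — the planted age difference in brain–behaviour coupling) and
with a self-selected boost (liking +0.8, familiarity +1.2).  The residual
latent correlation is calibrated by root-finding so the group-mean
within-subject Pearson r of the *discretised* ratings hits the per-group
target (older 0.57, younger 0.43).  Calibration is Monte-Carlo with
common random numbers (800 pseudo-subjects; window-FO pools simulated
from each category's chain started at the rest chain's stationary
distribution, matching the state distribution at real window onsets), so
the achieved correlation is a smooth monotone function of the latent
parameter and the root is stable to ~0.005.  Cut points stay fixed: they
control the marginal rating distribution, whereas the correlation is the
calibrated quantity.

**What the generator does not emulate**: hemodynamic convolution and
autocorrelation, motion and physiological artifacts, voxel-level
structure, spatial ROI covariance structure of real parcellations, and
slow drifts.  Tests passing on this generator therefore demonstrate that
the estimation and inference machinery recovers planted effects under the
model's own assumptions — not that those assumptions hold in real fMRI.

## Problem sizes in the shipped harnesses

Desk scale is 20 ROIs and K = 4 (220 ROIs available via config; the
method is dimension-agnostic).  The test suite uses: exact-inference
oracles at T ≤ 8, K ≤ 3 (exhaustive enumeration); parameter recovery at
10 ROIs, K = 4, T = 20,000 pooled over 10 subjects; model selection on 20
replicates of T = 2,000; inference calibration on 200 null and 40
effect replicates of a 16-subject reduced design with n_perm = 200; and
an end-to-end run of 16 subjects at full run length.  The analysis
scripts run the full 71-subject cohort.

## Numerical choices and degenerate inputs

- Ties in posterior argmax and Viterbi go to the lowest state index.
- Constant ROI rows: zeroed + flagged (normalisation), NaN row/column
  (connectivity).
- Zero-variance rating or metric vectors give undefined (NaN)
  correlations, excluded from group means with counts reported.
- Feature columns containing missing values are removed (and logged)
  before PLS; subjects missing a condition are dropped entirely.
- All randomness flows through `numpy.random.Generator` seeds; identical
  config + seed reproduces results bit-for-bit (the run manifest records
  the config hash and seed).

## Known limitations

- The model-order criterion is a BIC-style surrogate, not variational
  free energy; with strongly non-Gaussian or autocorrelated observations
  the two can rank models differently.
- Full-covariance states need T per state well above R; at 220 ROIs use
  the diagonal covariance option or more data.
- The permutation scheme treats subjects as exchangeable under the null;
  group-specific observation covariances would violate this.
- Percentile bootstrap CIs are first-order; no BCa correction.
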