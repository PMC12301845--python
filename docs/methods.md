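# Methods

`rctrsa` implements, as one tested pipeline, the computational chain of a
model-based RSA study of reward-modulated hierarchical action sequences:
a goal-unit recurrent network that predicts how reward reshapes the
representational geometry of a sequence task, a synthetic multivoxel fMRI
generator that plants that geometry at known ground truth, and the
searchlight/ROI/behavioral analyses that recover it.

## The task

The coffee-tea task is a 7-step hierarchical sequence task.  Step 1 cues
the drink (coffee or tea); steps 2-6 are three-alternative decisions
(first ingredient, stir, second ingredient, stir, serve); step 7 is
feedback.  The rules — cream only with coffee, sugar only with tea, water
required for both, the step-4 ingredient complementing the step-2 choice,
the spoon always selected for stirring, the prepared drink served — admit
exactly four action sequences (2 drinks x 2 ingredient orders).  One drink
is rewarded per subject, partitioning the sequences 2/2.  Six steps by
four sequences give the 24 task states that index every RDM.

Canonical state order (fixed package-wide): rewarded/water-first,
rewarded/water-second, non-rewarded/water-first, non-rewarded/water-second;
steps 1-6 within each.  Step-7 feedback is carried in event tables but has
no state index and never enters an RDM.

Session designs are 4 runs x 18 trials.  Sequence identities are balanced
exactly (18 trials each over the session, 5/5/4/4 per run on a rotating
pattern); the human instruction to pick the first ingredient "as if
flipping a coin" is idealized as exact balance.  Inter-stimulus intervals
are drawn without replacement from complete 7-level sets (2.5-4.5 s in
1/3 s steps), so every run's mean ISI is exactly 3.5 s and the session
always fits the 362-volume acquisition window (TR 1.72 s; the task starts
at the sixth volume).  Error/"too late" trials are not simulated: the
analyses exclude them, so they would be dead weight.

## The goal-unit network

An Elman network with 8 input units (six action units and the two drink
cues), 15 sigmoid hidden units with a context-layer copy of the previous
hidden state, an 8-way softmax action head, and 4 goal units (one per
sequence) that are clamped as inputs and trained as a softmax output head.
Weights are initialized i.i.d. normal(0, 0.1), biases zero.  One training
episode is one full six-step sequence drawn uniformly at random: the step-1
input is the cue, later inputs are the previous correct action (teacher
forcing), the executing sequence's goal input is held at 1, and the loss is
the sum over steps of the action and goal cross-entropies.  Gradients are
exact backpropagation through time over all six steps (verified against
central differences to <1e-4 relative error) and plain SGD updates follow
every episode.

The step-1 action target is the sequence's first-ingredient action: the
cue itself demands no response, but giving the head a target at every step
makes the trained network commit to its plan upon seeing the cue, and the
24 teacher-forced hidden states then correspond one-to-one to the task
states.

The learning rate is the one hyperparameter the study conditions leave
open; the package fixes 0.5, which brings every network in a 25-seed
ensemble to criterion within ~500 episodes — comfortably inside the
5000-episode training budget — and is recorded in `TrainConfig`.

### Reward simulation and accuracy conventions

After training the weights are frozen; reward is simulated purely by
clamping the executing sequence's goal input at 1 (rewarded) or 0
(non-rewarded).  Two accuracy conventions coexist and are both exposed:

- **Free-running** (`mode="free"`): the network's own argmax action feeds
  the next input.  Trained networks are error-free at goal level 1 under
  this, the stricter, reading.
- **State-conditional** (`mode="forced"`, decision steps 2-6): each
  decision is scored from the correct preceding state.  This is the
  convention for the goal-0 report, and the reason is structural: without
  the goal unit the water-first/water-second branch is genuinely ambiguous
  (the cue does not determine it), so a free-running network that commits
  to the other legal branch is scored wrong on the entire remainder of the
  trial and the ensemble lands near 60 %.  Scored per state, the ambiguity
  costs roughly one decision in two on the first-ingredient steps while
  stirring and serving survive, and the ensemble averages ~80 % — the
  regime the analyses assume.  At goal level 1 the two conventions agree
  (100 %).

### Model RDMs

For each reward assignment (coffee rewarded, tea rewarded) every sequence
is executed teacher-forced with its goal input at 1 or 0 according to its
drink; the 24 hidden vectors give a 24x24 Euclidean distance matrix, and
matrices are averaged element-wise over the ensemble.  Training is
reward-agnostic (the goal input is always 1), so a single ensemble serves
both assignments by relabeling.  The averaged RDMs show the core
prediction: pairwise distances among rewarded-sequence states exceed those
among non-rewarded states (with the 25-network ensemble, between-sequence
block means ≈ 2.02 vs 1.56).  Ensemble sizes are configurable; 25 is the
default for the accuracy report and RDM averaging here (50 — two seed
blocks — reproduces the larger averaging variant).

## Dissimilarity primitives

- Plain Euclidean RDMs for model geometry.
- The brain dissimilarity is the **leave-one-run-out cross-validated
  squared Euclidean distance**: per held-out run, the scalar product of the
  training-mean pattern difference with the held-out difference, averaged
  over runs.  It is unbiased (zero-centred under the null, so negative
  entries are kept) and degenerates to the exact squared distance on
  noise-free folds.  No noise whitening is applied.
- Spearman correlation = Pearson on mid-ranks (ties averaged), used for all
  model-brain RDM comparisons so any monotone transform of either geometry
  is irrelevant.
- Within-subject z-scoring uses the sample (n-1) standard deviation.
- Nonmetric MDS is Kruskal stress-1 with monotone regression
  (scikit-learn), 20 random restarts, best stress kept, seed-reproducible.
  A 24-point model geometry embeds in 2-D at stress ≈ 0.17 (rank
  correlation ≈ 0.89 with the input dissimilarities; ≈ 0.95 in 3-D) — the
  planar map is an illustration, not a lossless representation.

## First-level GLM

One GLM per run: 24 state regressors (1 s boxcars at step onsets convolved
with the canonical double-gamma HRF — response/undershoot delays 6/16 s,
unit dispersions, undershoot ratio 1:6, 32 s support, peak-normalized,
built on a 0.1 s grid and sampled at volume times), six nuisance columns
passed through unmodified, and an intercept; ordinary least squares per
voxel.  Run-separable fitting is required by the leave-one-run-out
distances; no prewhitening or high-pass filtering is applied because the
synthetic noise is white by default.  With the jittered 3.5 s mean ISI the
maximum pairwise correlation between state regressors stays below 0.8
(asserted on generated sessions).

## Synthetic subjects

A subject is four runs of 20x24x20 voxels (2.5 mm) x 362 volumes at
TR 1.72 s — the acquisition geometry at a desk-scale matrix; the full-size
grid is a config away.  BOLD = task design x true patterns + nuisance
random walks x random loadings + i.i.d. Gaussian noise.  The planted
region (default 310 voxels, the size of the medial-frontal cluster that
anchors the real analysis) carries patterns constructed by classical
scaling of the target RDM followed by a random orthonormal rotation into
voxel space — an isometry, so the target geometry is realized exactly up
to scale (truncation is reported for non-Euclidean targets).  Background
voxels carry unstructured run-stable patterns of the same amplitude;
optional decoy regions carry alternative geometries (e.g. drink-identity
dominant).  **SNR** = sd of pattern entries / noise sd (noise sd fixed at
1; `snr=inf` disables noise).

Behavioral records: per-trial Bernoulli correctness (defaults 0.95
rewarded / 0.92 non-rewarded) and log-normal step RTs.  Non-rewarded step
means (0.78, 0.60, 0.68, 0.58, 0.71 s) average 0.67 s; reward benefits
(0.05, 0, 0.025, 0, 0.025 s) land the rewarded mean at 0.65 s with the
benefit concentrated on steps 2, 4, 6 and strongest at step 2.  The
trial-level sd is 0.11 s — the residual dispersion implied by the reported
trial-level F statistics, which the marginal sd of ~0.28 s cannot
reproduce; the inferential statistics were taken as binding.

Cohorts alternate the rewarded drink across subjects (counterbalancing).
A per-subject effect magnitude g ~ N(1, 0.3) scales the behavioral reward
benefits and, through a coupling factor (default 0.5), the rewarded-block
distances of the planted geometry — giving brain-behavior contrast
correlations a planted positive ground truth.

What the generator does *not* emulate: physiological/motion noise,
autocorrelated noise (an AR(1) option exists only implicitly through the
nuisance walks), spatial smoothness of real BOLD, subject-level anatomical
variability, error-trial dynamics.  Passing recovery tests therefore show
the analysis chain is correct and calibrated under its own assumptions,
not that it is robust to everything real data do.

## Searchlight and group inference

Spheres are 6 mm radius converted to whole voxels (floor(6/2.5) = 2), i.e.
33 members on the 2.5 mm grid, truncated at mask edges with a 10-voxel
minimum.  Because the cv distance and the nearest-centroid discriminant
are sums of per-voxel contributions, sphere sums are computed by volumetric
correlation with the ball footprint — verified in the tests to be exactly
equivalent to looping over spheres.  Per subject: sphere cv-RDM → upper
triangle (276 values) → Spearman against the subject's reward-assignment
model RDM → z-score across the subject's valid voxels → 6 mm FWHM Gaussian
smoothing (in that order).

Group inference: voxel-wise one-sided Wilcoxon signed-rank across subjects
(exact null, computed by dynamic programming), primary threshold p < 0.001,
clusters by 26-connectivity, and familywise-error control of cluster
extent by sign-flipping permutation (default 1000 resamples) against the
max-cluster-extent null at alpha 0.05.  Permutation replaces random-field
theory deliberately: it is assumption-light and exactly testable.  Note
the exact test's granularity: with n subjects the smallest attainable
voxel p is 2^-n, so fewer than 10 subjects cannot pass p < 0.001.  The
signed-rank test is applied to the z-transformed (post-z) correlation
values.

Reward decoding: leave-one-run-out nearest-class-centroid classification
(rewarded vs non-rewarded states) per sphere, accuracies averaged over
folds and test states, ties counting one half.

## ROI statistics

The subject's 24x24 cv-RDM over the ROI is reduced to two 6x6 blocks of
between-sequence distances (sequence A step i vs sequence B step j) —
within the rewarded pair and within the non-rewarded pair — giving 72
distances per subject with a 36-level step-pair factor.  The ANOVA fixed
effects are condition (1 df), step pair (35), task (1), condition x step
pair (35), step pair x task (35) and the three-way interaction (35);
condition x task is excluded because a subject's rewarded block is always
their rewarded drink, making it indistinguishable from the subject
intercept.  Subjects enter as intercepts absorbed into the fixed design
(sum-to-zero coding, built explicitly), so every partial F uses the
within-subject residual — the balanced special case of the subject-random-
intercept mixed model.  Post-hoc reward contrasts are computed per
step-pair cell against the same residual, with a Sidak family adjustment
over the 36 single-contrast cells (the family to which a Tukey adjustment
of marginal-means contrasts degenerates when each cell contributes one
comparison).

Brain-behavior coupling: per subject, the distance contrast (mean rewarded
minus non-rewarded block distance; all 36 cells, and the 11 step-1 cells),
the mean-beta contrast (rewarded minus non-rewarded state betas in the
ROI), and Pearson correlations of each with the BIS contrast, with
t = r sqrt((n-2)/(1-r^2)).

## Behavior

Accuracy counts all trials; RT means use correct trials only, over
decision steps 2-6.  BIS = z(accuracy) - z(RT) with z-scores pooled over
all subject x condition cells (sample sd), so condition differences
survive standardization; the BIS contrast is rewarded minus non-rewarded.
The battery: paired t on accuracy, trial-level reward x step ANOVA on RTs,
Tukey HSD over the ten condition x step cell means (reported per step),
and a one-sample t of the BIS contrast against zero.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` seeds; same seed,
  same bytes.
- The cv estimator retains negative entries; the diagonal is defined 0.
- Degenerate inputs fail loudly: zero-variance z-scores and BIS inputs,
  empty ROIs/masks/ensembles, rank-deficient designs (collinear columns
  named), unbalanced ANOVA cells, constant RTs.
- Monte-Carlo calibration sizes used by the test suite (chosen to estimate
  rates to a few percent): 300 replicates for type-I rates, 60 for power
  runs at the study's subject counts (n=20 distances, n=50 behavior); the
  recovery cohort is 10 subjects at snr=1 on the reduced grid with
  1000/500-permutation cluster nulls.
- Ensemble-size discrepancy in the source conditions (25 trained vs 50
  averaged) is preserved as a configurable parameter rather than resolved.

## Known limitations

- The ANOVA is the balanced-design special case of the mixed model; it does
  not handle missing cells (it refuses them instead).
- Nonmetric MDS stress depends on restarts; only the best of 20 is kept.
- The searchlight assumes a regular grid and isotropic voxels.
- Reported behavioral marginal SDs and trial-level test statistics in the
  source conditions are mutually inconsistent; the generator follows the
  test statistics (see above), so its marginal RT spread is narrower than
  the printed SD.
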