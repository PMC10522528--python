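# Methods

`gbmsurv` implements a preoperative survival-classification analysis for
glioblastoma (GBM): from each patient's resting-state BOLD recordings and
structural MRI derivatives it builds a functional-connectivity fingerprint,
compresses it, classifies the patient into one of three overall-survival
classes (<1 year, 1–2 years, >2 years), attributes the classification to
brain networks, and reports survival curves for the predicted groups.
Because no patient data ship with the package, every stage is exercised on a
synthetic cohort generator that reproduces the statistical structure the
analysis assumes.

## Synthetic cohorts

A cohort is defined by `SimConfig`. Each subject belongs to one of the three
survival classes (default: balanced proportions) and receives

- **BOLD time series.** Fifteen resting-state networks (SMD, SMI, CON, AUD,
  DMN, PMN, VIS, FPN, SAL, VAN, DAN, MET, REW, THA, BGA), each with one
  latent time course; the latents at every frame are jointly Gaussian with
  covariance equal to the class's network-coupling matrix (unit diagonal,
  entries in [0, 1]). Every voxel is its network's latent plus iid N(0,
  noise_sd²) noise; defaults are 200 voxels per network and 320 frames,
  matching a two-run acquisition treated as one concatenated matrix. The
  default coupling matrices plant class-dependent coupling (0.75 / 0.45 /
  0.15 for the worst-to-best prognosis classes) in three pairs — SMD–CON,
  SMD–VIS, SMI–PMN — on a 0.15 background; matrices are projected to the
  nearest correlation matrix so sampling is well defined. This is the
  simplest model in which the downstream distance-correlation estimate is
  monotone in the planted coupling.
- **Cortical thickness.** 34 contralesional Desikan–Killiany parcels: a
  fixed plausible baseline (1.96–3.12 mm) plus a class shift (default
  −0.15 / 0 / +0.15 mm, i.e. thinner cortex in short survivors) plus
  N(0, 0.12²) parcel noise, floored at 0.5 mm.
- **Demographics.** Age ~ N(class mean, 10²) clipped to [18, 95], default
  means 65 / 61 / 57 years (short survivors older; cohort mean ≈ 61);
  sex coded 0 = female, 1 = male with default male probability 0.64 / 0.58 /
  0.50.
- **Survival.** Times drawn from class-specific lognormal distributions
  (medians 8 / 17 / 34 months, log-sd 0.45) truncated to the class interval
  — (0, 12), [12, 24], (24, 120] months — so labels are consistent with
  times by construction; exact 12- and 24-month times belong to the middle
  class. The event indicator defaults to 1 (death observed); a configurable
  censoring rate flips indicators at random for log-rank experiments while
  keeping the recorded time.

Probability maps (stand-ins for published network-membership maps, used for
ROI selection and voxel projection) give each network a contiguous
high-probability segment of at least `voxels_per_network` strictly positive
voxels plus a weak scattered tail on a shared grid.

What the generator does **not** emulate: head motion, physiological noise,
hemodynamic autocorrelation, spatial smoothness, tumor mass effects,
site/scanner effects, and any correlation between thickness and
connectivity beyond the shared class label. Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes, not that
the assumptions hold in patients.

## Connectomics

Functional connectivity between two networks is Székely's distance
correlation (the original biased V-statistic, which is bounded in [0, 1]):
pairwise Euclidean distance matrices of the two samples are double-centered
and dCor = sqrt(dCov² / sqrt(dVar²_X · dVar²_Y)). A constant sample has zero
distance variance; we return 0 with a warning rather than raising, since
degenerate synthetic configurations can produce constant series. Between-
network similarity treats each network's full voxel block as one
multivariate sample. Within-network similarity averages, over voxels, the
dCor between one voxel's time course and the remaining voxels as a single
multivariate sample (a pairwise voxel–voxel average is available via
`within_method="pairwise"` but is not the default). The implementation
exploits the decomposition of squared Euclidean distances over coordinates
so the complement-block distance matrix for each voxel is obtained by
subtraction rather than recomputation. Over 15 networks the upper-triangle
row-major traversal (self-pairs included) yields 120 labeled measures,
`SMDxSMD … BGAxBGA`. ROI selection takes each map's top-k probabilities
(k = 200 by default), ties broken by ascending voxel index.

## Autoencoder

The 120 similarities are compressed by a single-hidden-layer autoencoder:
20 sigmoid units, linear decoder, mean-squared reconstruction loss. Inputs
are standardized with training-split statistics. Training uses 80% of the
supplied subjects with 20% reserved exclusively for early stopping (the
weights returned are those of the best-validation epoch; patience 150
epochs, at most 5000). The optimizer is full-batch Adam (lr 0.01, halved
after every 30 stalled epochs). Plain gradient descent with momentum was
tried first and consistently stalled an order of magnitude above the
truncated-SVD reconstruction bound on low-rank data; Adam reaches the bound,
so it is the default. After training, code units whose activation variance
across training subjects is below 1e-4 times the largest unit variance are
pruned as "sparse"; survivors are relabeled FC1..FCm in original unit
order. The autoencoder is always fit on the classifier's training portion
only, never on held-out subjects.

## Classifier

Inputs per subject: age, sex, 34 thickness parcels, and the encoded FC
features (47 columns with an 11-feature code). The model is a feed-forward
network with three hidden layers of eight ReLU units, softmax output over
the three classes, cross-entropy loss (scikit-learn `MLPClassifier`).
Training follows nested stratified cross-validation with a global holdout:

1. a stratified holdout (default 10 subjects) is set aside untouched;
2. the remainder is split into 10 stratified outer folds;
3. within each outer training set, a 5-fold inner stratified CV selects the
   weight-decay strength from a small grid (default {1e-4, 1e-2});
4. one member model per outer fold is refit on the full outer training set.

Feature scaling uses each fold's training subjects only; sex passes through
unscaled. Epoch control is loss-based early stopping (stop when the
training loss improves by less than `tol` for 20 epochs, cap 500):
score-based stopping on a held-out split is available via
`use_validation_stopping`, but at these fold sizes the validation split is
a handful of subjects and its score saturates immediately, truncating
training (observed: perfectly separable data reached only ~54% CV accuracy
under score-based stopping).

Reported accuracies: **CV** over out-of-fold predictions; **holdout**
pooled over member × holdout-subject predictions (numerically equal to the
mean of per-member holdout accuracies, both are recorded); **combined**
counts CV and holdout subjects together; **ensemble** applies the argmax of
the member-averaged class scores to the holdout, ties broken toward the
worst prognosis (deterministic and clinically conservative). A leakage
guard verifies holdout ids never intersect the CV predictions.

## Feature importance

A feature's importance is the accuracy drop when its values are permuted
across subjects. Each ensemble member is evaluated only on its own
out-of-fold subjects; drops are averaged over members and over `repeats`
re-drawn permutations. Age, sex and thickness report importance directly.

To attribute encoded-feature importance back to the 120 raw pairs, two
routes exist. The default (**direct**) permutes each raw pair column,
re-encodes the perturbed connectome with the trained autoencoder, and
measures the out-of-fold accuracy drop; drops are floored at zero and
normalized to sum to one. The alternative (**encoder-weights**) distributes
each encoded feature's importance over pairs in proportion to the absolute
encoder weights. The direct route is the default because the encoder
standardizes its inputs, which makes weight magnitudes blind to which pairs
carry class information: on cohorts with signal planted in exactly three
pairs, the weight route ranked them anywhere from 17th to 79th of 120,
while the direct route placed them in the top handful.

Per-network weights are the mean ± sd of the 15 pair weights incident to
each network (self-pair counted once); the voxelwise map is the dot product
of the per-network means with the network probability maps.

## Survival reporting

Kaplan–Meier curves (product-limit estimator) and the k-group log-rank test
are computed with `lifelines` on the classifier's out-of-fold predicted
groups (holdout subjects excluded). Tied censoring times stay at risk
through the tied event time (the standard convention). Cohort
characteristics are compared across true survival groups with Chi-squared
tests (no continuity correction) for categorical variables and
Kruskal–Wallis for continuous ones; p-values are unadjusted, with a
Benjamini–Hochberg column emitted alongside.

## Pipeline and reproducibility

`gbmsurv run-all` executes simulate → connectome → encode → train →
importance → report. Each stage draws randomness from a named child of the
global seed (`numpy.random.SeedSequence` spawning), every artifact is
listed in a manifest with its SHA-256 checksum, and identical config + seed
reproduces identical checksums. Stage failures abort with the stage name
while keeping the artifacts already written.

## Problem sizes used in the test suite and acceptance script

Full-scale connectomics (200 voxels/network, 320 frames) costs ~8 s per
subject on one core, so the packaged experiments use reduced measurement
sizes chosen once, after verifying that the planted-coupling contrast
survives them:

- planted-effect classification: n = 150 balanced subjects, 50 voxels,
  160 frames; default group effects (coupling 0.75/0.45/0.15 in three
  pairs, 0.15 mm thickness shift per class, 4-year age shift per class);
  the permutation null re-uses the same cohort with shuffled labels and a
  single weight-decay value (a hyper-parameter search cannot bias a null);
- importance recovery: n = 120, 30 voxels, 160 frames, voxel noise sd 0.6,
  with group signal **only** in the three planted pairs (thickness and
  demographics flat) so pair recovery is attributable to FC alone;
- autoencoder adequacy: rank-3 data with noise sd 0.15 on ~unit-variance
  features, 500 training subjects — below a few hundred subjects the
  estimation variance of any 20-unit model, not its capacity, dominates the
  held-out error and the SVD bound is unapproachable.

## Known limitations

- The within-network "each voxel against the rest" reading is a documented
  interpretation; the pairwise variant is available but untuned.
- The autoencoder optimizer and the classifier's epoch control are
  practical choices exposed in config, not uniquely determined by the
  architecture.
- Holdout accuracy with 10 subjects is a coarse quantity (steps of 1%
  per member-subject pair); the ensemble accuracy on such a holdout is
  coarser still.
- Synthetic cohorts are far more homogeneous than patients; absolute
  accuracies on them say nothing about clinical performance, only that the
  pipeline recovers planted structure and behaves at chance when none
  exists.
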