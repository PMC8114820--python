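# Methods

`hybci` implements a complete two-class hybrid EEG + fNIRS classification
pipeline: synthetic recording generation, modified Beer-Lambert conversion,
signal conditioning, epoching, per-channel feature extraction, k-means
cluster-center attribute weighting, and a cross-validated classifier grid
with a confusion-matrix metric suite. This note records the models,
parameter choices, numerical conventions, and the design decisions that
were genuinely open.

## Synthetic data model

The generator emulates the *geometry* of a hybrid motor-imagery /
mental-arithmetic BCI study: 29 subjects x 3 sessions x 20 trials = 1740
observations; 36 fNIRS source-detector pairs measured at two wavelengths
(760/850 nm, 72 optical-density channels) sampled at 12.5 Hz; 32 EEG
channels at 1000 Hz; each trial is a 2 s instruction phase, a 10 s task,
and 15-17 s rest (uniform). A 5 s lead-in precedes the first trial - long
enough for the first baseline window, carrying no task information. Labels
are balanced and randomly ordered within each session.

Class structure is injected through two mechanisms:

* **Hemodynamics.** A third of the fNIRS pairs are "active": their
  ground-truth dHbO is the 10 s task boxcar convolved with a canonical
  double-gamma HRF (peak ~6 s, 1/6 undershoot), peak amplitude 0.01 mM
  modulated by a per-trial, per-channel uniform(0.8, 1.2) gain;
  dHbR = -0.4 x dHbO. For class 2 the active-channel amplitude is
  multiplied by `hemo_effect_size` (default 1.3). Concentrations are
  mapped to OD through the exact forward Beer-Lambert matrix, then
  1/f + white noise of total SD `noise_sd` (default 0.005 OD units, 70%
  pink) is added.
* **EEG.** Pink background noise of SD `noise_sd x 2000` uV (10 uV at the
  default) plus a task-window oscillation at a per-trial uniform(8, 13) Hz
  frequency and amplitude 5 uV x gain; on a quarter of the channels the
  amplitude is multiplied by `erd_effect_size` (default 0.7) for class 2
  only, mimicking event-related desynchronization.

Class membership only rescales amplitudes and never changes the order of
random draws, so setting both effect sizes to 1 produces, draw for draw,
bitwise identical class-1 and class-2 signals - the null case used by the
chance-level tests. Effect-size defaults were chosen once as plausible
single-trial effect magnitudes (a 30% hemodynamic amplitude difference, a
30% alpha-power attenuation); they put the unweighted pipeline between
chance and ceiling so that both directions of change are observable.

What the generator does **not** emulate: volume conduction and realistic
forward head models, physiological artifacts (cardiac, respiratory, Mayer
waves), motion, electrode drift, inter-subject variability structure, or
the actual statistics of any real recording. Passing tests therefore
demonstrate the correctness and internal consistency of the *pipeline*,
not expected accuracy on real data; headline accuracies from any real
study are outside what this package can or tries to reproduce.

## Beer-Lambert conversion

Concentration changes are obtained samplewise from two-wavelength OD
changes by inverting

    OD(lambda_w) = rho * sum_c eps_c(lambda_w) * DPF(lambda_w) * dC_c .

No published values were fixed for the optical constants, so configurable
defaults are used: eps (1/(mM cm)) = {HbO: 0.5958, HbR: 1.6745} at 760 nm
and {HbO: 1.0507, HbR: 0.7861} at 850 nm (standard extinction tables),
DPF = 6.0 at both wavelengths, rho = 3.0 cm. Every test of this stage is a
forward/inverse round-trip property (tolerance 1e-12), never an absolute
value, so the conclusions are independent of these defaults. Parameter
sets whose extinction/DPF matrix has condition number above 1e12 are
rejected.

## Signal conditioning

Hemoglobin series are band-passed with a 3rd-order Butterworth at
0.01-0.09 Hz, applied forward-backward (zero phase) so epoch timing is not
shifted; this doubles the effective magnitude order, and a causal
single-pass mode is available by flag. Filtering uses second-order
sections with odd-symmetric edge padding. Processing order is
MBLL -> band-pass -> downsample to 10 Hz: designing the filter at the
native 12.5 Hz keeps the (already extreme) normalized band edges as far
from Nyquist as possible.

Downsampling (12.5 -> 10 Hz, i.e. 4/5; 1000 -> 200 Hz, i.e. 1/5) is
polyphase FIR resampling with the ratio reduced to a rational number.
Each channel is demeaned before the FIR and the mean re-added afterwards,
which preserves the DC component exactly (the FIR's polyphase branch gains
alone carry ~1e-3 ripple); linear-extension padding keeps slow trends flat
at the record edges. Upsampling is rejected rather than supported.

EEG receives no band-pass, only the 1000 -> 200 Hz conversion.

## Epoching

Trials are cut with half-open sample windows
[round(onset + a fs), round(onset + b fs)), making 10 s at 10 Hz exactly
100 samples and 10 s at 200 Hz exactly 2000. Segmentation retains the
-2..0 s instruction context; baseline correction subtracts the per-trial,
per-channel mean of that window (identically for EEG and hemoglobin
epochs) and then trims to the 0-10 s task window, after which a second
baseline call errors by design.

## Features

Per channel and trial: mean, maximum, least-squares slope (amplitude/s
over the full epoch), variance (N-1), skewness and kurtosis (third and
fourth standardized moments with the population sigma; kurtosis without
the -3), and median. The "slope" had no fixed window definition, so the
full-epoch regression slope is the default and a windowed variant (mean of
per-window regression slopes) is available via `slope_window`. Constant
channels return skewness = kurtosis = 0 with a warning instead of
aborting. Tables are channel-major; hybrid tables are horizontal
concatenations with provenance-prefixed column names, stored as
476 / 504 feature columns plus one label column.

## Cluster-center weighting

The Lloyd 2-means core initializes from two distinct points sampled by
seed, assigns equidistant points to the first cluster, recomputes centers
as cluster means, stops when no center moves more than `tol` (1e-6), and
reseeds an emptied cluster with the point farthest from the survivor.
It is validated against an exhaustive minimum-SSE bipartition oracle.

The weighting pseudo-code uses a *single* per-class center z_i while the
clustering step returns two; the only coherent reading retained is the
componentwise mean of the two within-class centers, isolated in
`class_center` so alternatives can be swapped in. k-means runs on the full
class matrix by default; a per-feature (1-D) mode is available by flag.
One consequence: exact single-feature scale equivariance of the weights
(scaling feature j by a > 0 leaves w[i][j] unchanged) holds in per-feature
mode, while the full-matrix mode guarantees it only for isotropic scaling,
since anisotropic scaling can change the cluster partition itself.

Weights divide by z_i; a center entry with |z| <= 1e-12 yields w = 1 for
KMCC (identity semantics) and w = 0 for KMCCD (null semantics), with a
warning.

**The faithful mode leaks labels.** The pseudo-code weights each
observation with its own class's weight vector before any train/test
split. Applied verbatim - which `mode="faithful"` does - every row of the
data, including future test rows, is multiplied by a label-dependent
vector, so the class identity is encoded into the features before
cross-validation. On pure i.i.d. noise features this takes 1-NN from
chance to >90% CV accuracy. The faithful mode is the replication default
and is what the headline grid demonstrates; `mode="global"` (label-free
averaged weight vector, fitted inside each training fold) is provided for
honest evaluation and stays at chance on noise. The test suite asserts
both behaviors.

## Classification and metrics

Stratified 10-fold CV (1740 observations -> 174 per fold, 87 per class).
Classifiers: pooled-covariance LDA (SVD solver), soft-margin linear SVM
with C = 1 (kernel and C were unspecified; both configurable), and 1-NN
with Euclidean distance and distance ties broken by the lower training-row
index (implemented directly so the tie-break is guaranteed). Class 1 is
"positive" by convention.

Headline metrics come from the confusion matrix pooled over folds (single
values per cell, with per-fold accuracies retained); the binomial CI uses
z = 1.96 at 95% and n = the number of observations used to develop the
model (the full table size). Printed-formula variants of ACC, FPR, and p2
that appear in some write-ups are exposed behind `printed_*` flags; the
defaults are the standard definitions, which are the only ones consistent
with FPR = 1 - specificity patterns in reported tables. Zero-denominator
metrics are reported as NaN, never silently as 0.

The 10-fold protocol here uses the standard 90% train / 10% test split per
fold; a description of "174 used as training and the rest as test" is
interpreted as the fold size (174 is the test fold at n = 1740).

One numerical bound: faithfully weighted tables mix feature scales over
many orders of magnitude (KMCCD weights divide by near-zero centers), and
libsvm's active-set solver may never reach its KKT tolerance there. SVC
fits are therefore capped at 100,000 iterations (`SVM_MAX_ITER`); the
solver's ConvergenceWarning is left visible when the cap is hit, and the
affected cells are reported as what the capped solver returns.

## Problem sizes used in tests and the acceptance script

Structural counts, fold sizes, and the classification grid are computed at
the full reference geometry (1740 trials). Property tests (round trips,
feature oracles, k-means vs. exhaustive bipartition) run on small random
instances. The leakage demonstration uses n = 400 observations of d = 20
noise features over 10 seeds. Effect-size monotonicity uses a reduced
geometry (4 subjects x 1 session x 20 trials, 6 fNIRS pairs, 8 EEG
channels at 200 Hz native) averaged over 10 seeds per effect level -
monotonicity is a property of the pipeline, not of the full geometry, and
the reduced setting makes the averaging affordable.

## Known limitations

* The synthetic class mechanisms are deliberately simple; no claim is made
  about transfer to real recordings.
* The faithful weighting mode is intentionally leaky (see above); its
  accuracies must not be read as generalization estimates.
* `generate_dataset` materializes the full dataset in memory (~13 GB at
  the default geometry); use `iter_recordings` / `run_synthetic_pipeline`,
  which stream one recording at a time.
* kmeans2 is a local optimizer; single-seed runs can return a non-global
  partition (the test suite uses multi-restart where the global optimum
  matters).
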