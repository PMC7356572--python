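# Methods

## Problem setting

A snapshot VNIR hyperspectral camera images a 12×12 mm skin patch as a
50×50 pixel cube with 125 bands covering 450–950 nm (uniform sampling of
≈ 4.03 nm; the instrument's optical FWHM is 8 nm, which is a resolution
figure, not the grid step). Each pixel carries a reflectance spectrum
whose shape encodes chromophore content — melanin, oxy-/deoxy-
hemoglobin — and therefore discriminates normal skin from pigmented
lesions, and benign from malignant lesion tissue, without contact or
staining. The package turns one raw capture into a lesion-level
benign/malignant call with a per-pixel audit trail.

## Pre-processing

Radiometric calibration converts counts to reflectance voxelwise:
`CI = (RI − DI)/(WI − DI)` with white (`WI`) and dark (`DI`) reference
captures. Voxels where `WI = DI` (dead sensor elements) are set to 0
and counted rather than raising — a dead pixel should not abort a
clinical capture — and negative reflectance (raw below dark) is clamped
to 0 by default, since reflectance is physically non-negative.

The first 4 and last 5 bands are dropped (sensor roll-off), leaving 116
bands. Spectral noise is reduced with a centred moving average along
the wavelength axis (window 5, truncated at the spectral edges so
constant spectra pass through unchanged). The window type and width
were open choices; a plain moving average is the simplest smoother
consistent with the intent and both are configurable
(`PreprocessConfig`).

Finally each pixel's spectrum is min–max normalized to [0, 1]
*per signature* (not globally), deliberately discarding amplitude:
illumination non-uniformity scales amplitude but barely affects shape.
Flat spectra map to all-zeros by convention. Normalization is
idempotent and affine-invariant (`normalize(a·s + b) = normalize(s)`,
a > 0), which the property tests exercise.

Repeatability of an acquisition rig is quantified by the absolute
relative difference between two captures x, y of the same scene,
`RD(%) = |x − y| · 100 / ((mean(x) + mean(y))/2)`, applied voxelwise
with the global means in the denominator; its average (RDmean) is the
summary. This reading is the only one that makes RDmean the mean of a
per-voxel map; RD is symmetric and invariant to common rescaling.

## Segmentation

Pixel spectra are clustered with seeded K-means (k-means++, 10
restarts). Centroids are canonically ordered by mean reflectance so
cluster indices are reproducible; the indices carry no class meaning.
Cluster-to-class assignment uses the Spectral Angle Mapper
`θ(x, y) = arccos(⟨x, y⟩/(‖x‖‖y‖))` — scale-invariant, so consistent
with shape-only preprocessing — against a reference library of five
signatures: the benign and malignant class means of the labeled
training spectra plus three skin centroids from K-means over the skin
rows. Skin needs several entries because phototypes differ strongly in
melanin; a single mean would sit between modes and match nothing well.

Two assignment methods are provided. *Per-centroid* labels each cluster
by its SAM-nearest library entry. *Per-pixel* sums, per library entry,
the SAM angles of all member pixels and labels the cluster by the
entry with the smallest sum. The sum is taken per entry rather than
per class so that the 3-entry skin class is not favored merely by
count; when every pixel equals its centroid the two methods coincide
(verified numerically). Ties break toward skin — the conservative call
on an ambiguous spectrum, avoiding inflated lesion area. The default
configuration is K = 7 with the per-pixel method.

Post-processing is a morphological closing (3×3 square, the smallest
standard element) of the lesion layer followed by removal of connected
components (8-connectivity) smaller than 4 px. Closing alone cannot
remove isolated foreground specks, so the explicit component filter is
required by the stated intent of removing small isolated regions. The
composite is idempotent on the maps we generate (tested on random
grids).

The skin cluster count is selected by running K-means for K = 2…7 and
scoring each partition with silhouette and Calinski–Harabasz
(maximized) and Davies–Bouldin (minimized); each index votes and the
consensus is the most frequent vote, ties toward the smaller K. The
standard optimization direction is used for all three indices; accounts
that pick silhouette by its *smallest* value conflict with the index's
definition, and we do not follow them.

## Classification and hyperparameter search

Classifiers: SVM with linear, RBF and sigmoid kernels, random forest,
and a feed-forward network with four hidden layers (logistic
activations, 200 epochs, seeded initialization; the four tunable widths
are the hidden layers). SVMs use scikit-learn's SVC; the sigmoid
kernel `tanh(s⟨x, y⟩ + cf)` is passed as a callable because its slope
s may legitimately be negative. Every model must output a malignancy
probability: SVMs get a Platt-style logistic calibration fitted on the
training decision values, random forests use the tree-vote fraction,
and the network its output activation. No class reweighting is applied
by default.

With the default tiny widths the network collapses to predicting the
class prior — four narrow logistic layers barely propagate gradient —
which is an honest property of that architecture, not a defect; the GA
exists precisely to size such hyperparameters.

The genetic algorithm is real-coded: tournament selection (size 3),
BLX-0.5 blend crossover, per-gene Gaussian mutation (σ = 10 % of the
bound width) clipped to bounds, elitism of 2, population 50 over 30
generations by default (all configurable; the small enumerable searches
in the tests use far smaller settings). C and γ are searched in log
space, C ∈ [2⁻⁵, 2⁷] and γ ∈ [2⁻¹⁰, 2⁴]; sigmoid slope and intercept
in [−15, 15]; trees and per-layer neurons in [1, 500] as integers —
intervals wide enough to contain the tuned optima reported for
comparable pixel-classification problems. The default hyperparameters
are injected into the initial population, so with elitism the returned
AUC can never fall below the default's AUC on the same validation set.
Fitness values are cached by decoded genome, which makes small discrete
searches exhaustive in effect. Train and validation sets must be
patient-disjoint; sharing patients across sets leaks subject-specific
spectra and inflates validation AUC.

## Metrics

Overlap: Dice = 2TP/(2TP+FP+FN) and Jaccard = TP/(TP+FP+FN), linked by
Dice = 2J/(1+J). Classification: sensitivity, specificity, accuracy;
ratios with zero denominators are reported as NaN (explicitly
not-available) rather than 0 — when only one class is present, accuracy
reduces to sensitivity and specificity is undefined. AUC is computed
as the Mann–Whitney concordance probability from midranks (ties worth
½), identical to the trapezoidal ROC area; the tests verify it against
brute-force pair enumeration and scikit-learn independently.

## Lesion-level decision

The fraction of lesion pixels predicted malignant (label = score > 0.5)
is compared strictly against a 40 % risk threshold: fraction > 0.40 ⇒
malignant, else benign; exactly 0.40 is benign. The mean malignancy
score is reported alongside as a soft summary, but the decision uses
the pixel-label fraction. A capture whose segmentation finds no lesion
pixels returns status `reacquire` — the framework asks for a new
acquisition instead of guessing.

The patient-stratified split assigns whole patients to train /
validation / test (default pixel-count targets 72/12/16 %), shuffling
patients with the split seed and greedily filling the set furthest
below target; each set is first seeded with one patient carrying each
lesion class (training first) so every set holds both classes whenever
the cohort allows it.

## Synthetic scenes

The generator is phenomenological, not radiative transfer. A tissue
spectrum is a logistic rise from a visible base to a NIR plateau, minus
Gaussian hemoglobin dips at 542 and 576 nm, multiplied by a melanin
attenuation `exp(−m (500/λ)³)`, clipped to (0, 1). Three skin modes
represent light/medium/dark phototypes (melanin scales 0.10 / 0.55 /
1.25 with correspondingly shifted rise and shallower dips); benign
lesions are darker and red-shifted, malignant lesions darker and
flatter still. All mode pairs are separated by ≥ 0.05 rad SAM (the
measured minimum is ≈ 0.10), which is what makes the 3-mode consensus
and the segmentation recoverable at the default noise level.

A scene places an elliptical lesion with low-order harmonic boundary
jitter on a uniform skin background, adds i.i.d. Gaussian reflectance
noise (σ = 0.01), and synthesizes counts through the camera model:
`raw = dark + reflectance · (white − dark)` with a ±10 % planar
illumination tilt applied to the white frame and the raw capture alike,
dark ≈ 100 counts with σ = 2 read noise, white ≈ 3000 counts with a
gentle spectral roll-off. Calibration therefore inverts the forward
model exactly up to the injected reflectance noise (tested voxelwise at
3σ). Cohorts fix one phototype per patient and draw lesion classes at
a 43/57 benign/malignant patient mix; labeled spectra are sampled from
the ground-truth footprint (lesion classes) and its complement (skin),
100 pixels each per image, as *preprocessed* 116-band signatures.

What the generator does not emulate: glare, shadows, specular
artifacts, spatial texture within lesion or skin, patient motion, and
the long tail of real lesion morphologies. Passing tests therefore
demonstrate algorithmic correctness and parameter recovery under the
stated noise model — not clinical performance. Clinical overlap and
AUC figures require a real patient database and are out of scope here.

## Problem sizes and numerics

The shipped evaluation uses a 16-patient cohort (one 50×50×125 scene
each, 200 labeled pixels per image) and 40 fresh scenes for end-to-end
recovery; at these sizes the whole test suite runs in well under a
minute. SAM cosines are clipped to [−1, 1] before arccos; K-means is
always seeded with 10 restarts; all stochastic operations take explicit
seeds and the suite asserts byte-identical reruns. Degenerate inputs
have defined behaviour throughout: flat spectra normalize to zeros,
dead calibration voxels are zeroed and counted, empty clusters are
skipped, empty masks and single-class label sets raise contract errors.
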