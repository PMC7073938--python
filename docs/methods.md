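# Methods

`chromanose` implements the full data-analysis chain of a colorimetric
sensor-array electronic nose for detecting pork adulteration in minced
beef: ΔRGB feature extraction from scanned dye plates, PCA preprocessing,
three-class identification (pure beef / beef–pork mixture / pure pork) by
Fisher linear discriminant analysis and by an extreme learning machine, and
quantitative prediction of the pork mass fraction by a back-propagation
neural network. Because no raw sensor data are publicly available for this
kind of experiment, the package also contains a first-class synthetic
generator that emulates the study design, so every stage can be exercised
and tested end to end.

## Measurement model and feature extraction

A measurement is a pair of 8-bit RGB scans of the same 12-spot dye plate,
taken before and after a 5-minute exposure to the headspace of a 40 g
minced-meat sample. Each spot is summarized by the arithmetic mean color
over the disc of pixels whose integer coordinates lie within Euclidean
distance `radius_px` (default 12) of the spot center; the feature for spot
*i*, channel *c* is

    Δc_i = | mean_c(after, i) − mean_c(before, i) |,

concatenated channel-major (all ΔR, then ΔG, then ΔB, spots in row-major
grid order) into the 3N-dimensional color-change profile (N = 12 → 36
features). The absolute value makes the profile symmetric in the two scans
and non-negative by construction.

Numerical conventions, stated because image processing is where silent
mismatches hide:

* Coordinates are 0-based `(row, col)` with row increasing downward.
* Disc membership is `distance ≤ radius` on integer pixel centers. The
  pixel count of the mask is a fixed constant per radius, identical for
  every spot and image (`disc_pixel_count(12)` = 441); slightly different
  inclusive conventions give slightly different counts, which is why the
  count is documented rather than asserted and the radius is configurable.
* Spot positions come from the known plate layout (a regular lattice), not
  from image segmentation; printed arrays have fixed geometry.

## Synthetic experiment generator

The generator emulates the study design: pork fractions 0–100% in 20%
steps, 14 replicates per level, 84 samples total; fraction 0 is labelled
`pure_beef`, fraction 1 `pure_pork`, everything between `mixture`.

Mean response of dye *d*, channel *c* at fraction *x* is a scaled logistic

    μ_dc(x) = A_dc · σ( s_dc (x − m_dc) / w_dc ),

with per-dye-channel parameters drawn once from the model seed:
magnitude `A ~ U(1, 12)` intensity units (the range real difference images
span, from sub-unit responders to strong ones), midpoint `m ~ U(0.1, 0.9)`,
width `w ~ U(0.05, 0.2)`, and direction `s ∈ {−1, +1}` with equal
probability — a dye-channel is as likely to respond more strongly to beef
headspace as to pork. Every response is strictly monotone in level; the mix
of directions, midpoints and sharpnesses bends the level trajectory through
many feature-space directions, which is what keeps the variance spectrum
from collapsing onto one axis.

Measurement noise is additive Gaussian, clamped to [0, 255], with a
low-rank structure:

    ε = noise_sd · ( √ρ · L z + √(1−ρ) · w ),  z ~ N(0, I_q), w ~ N(0, I_3N),

where `L` (unit-norm rows, q = 3 latent factors) induces the strong
cross-dye collinearity real arrays show (every dye responds to many
volatiles and vice versa), and the independent part spreads the remaining
variance over all features. Per-feature noise SD is exactly `noise_sd`.

Defaults (`noise_sd = 1.5`, `ρ = 0.6`) were chosen once to land the
generator in the regime the study reports qualitatively and structurally:
a cumulative-contribution threshold of 90% is reached within at most nine
principal components; adjacent adulteration levels overlap, so linear
nearest-centroid classification is imperfect while the nonlinear ELM does
substantially better; and the level signal remains strong enough for
network regression with a high coefficient of determination. No
quantitative description of class overlap exists to calibrate against, so
these are regime choices, not fits.

What the generator does **not** emulate: dye photochemistry and reaction
kinetics, humidity/temperature drift, scanner color calibration, spatial
within-spot gradients, or non-Gaussian outliers. Passing tests therefore
demonstrate correctness of the analysis chain and reproduction of the
study's qualitative regime on data with the assumed statistical structure —
not performance on any real dye array.

The generator can also render a profile back into a before/after image
pair (uniform discs on a white background), which closes the loop for
testing: extract(render(profile)) = profile up to 8-bit quantization
(≤ 0.5 intensity units per feature).

## PCA preprocessing

PCA is fitted on the raw difference profiles (not autoscaled; an option
for correlation-matrix PCA exists but carries no fidelity claim), using the
eigendecomposition of the sample covariance with the n−1 denominator.
Components are ordered by descending eigenvalue; each component's
*contribution rate* is its eigenvalue's share of the trace, and
`select_components` returns the smallest k whose cumulative contribution
reaches the threshold (default 0.90). Component signs are not identifiable
and are fixed by making the largest-magnitude loading entry positive.

The pipeline additionally enforces a floor on k of (number of distinct
levels − 1), capped by the feature and sample counts. A six-level design
spans at most five dimensions; on noise-free data the spectrum degenerates
(PC1 can carry > 90% alone) and a pure threshold rule would starve the
downstream models of the curvature directions that make the three classes
separable. With any realistic noise the threshold already selects at least
that many components and the floor is inert.

Network inputs and targets are min–max normalized column-wise to [0, 1]
using training-set minima/maxima, y = (x − x_min)/(x_max − x_min); values
outside the training range extrapolate without clamping, and constant
columns map to 0 (with a warning) rather than erroring, so an unresponsive
sensor channel cannot crash a run. Fisher LDA consumes raw PCA scores —
its decision rule is affine-equivariant, so normalization would not change
its predictions.

## Fisher LDA with nearest-centroid assignment

The discriminant axes solve the generalized eigenproblem
`S_b v = λ S_w v` of between-class versus within-class scatter;
s = min(k−1, p) axes are retained (two for the three-class problem), each
axis reported with its share of the retained eigenvalue mass. A
near-singular within-class scatter — possible with tiny classes or
noise-free replicates — receives a ridge of `1e-6 · trace(S_w)/p` on the
diagonal, with a warning. Unknown samples are assigned to the class whose
centroid is nearest (Euclidean) in discriminant space; ties resolve to the
first class in the fixed order pure_beef < mixture < pure_pork.

## Extreme learning machine

A single-hidden-layer network whose input weights and biases are drawn
`U(−1, 1)` from the seed and never trained (the uniform law is the ELM
literature default; the study states only that they are random). With the
sigmoid activation S(x) = 1/(1+e^−x), the hidden matrix is
H = S(X Wᵀ + b) and the output weights are the minimum-norm least-squares
solution β = H⁺T against the 0/1 one-hot class coding (coding and argmax
decoding are this package's choice; the study does not state its coding).
The hidden-neuron count L is chosen to minimize validation RMSE of the
one-hot network output over a grid (tie → smallest L), mirroring how the
study tunes its classifier by RMSE; the full RMSE-versus-L trace is
returned. With L equal to the number of distinct training samples, H is
square and generically invertible, so the network interpolates its
training labels exactly — a property the tests exploit.

## BP-ANN level regression

A p–h–1 feed-forward network with tanh hidden units and a linear output
unit, trained by full-batch gradient descent with momentum on the mean
squared error of min–max-normalized inputs and targets. Hyperparameters
follow the study's fixed recipe: learning rate 0.1, momentum 0.1, stop at
training MSE ≤ 0.0002 (normalized scale) or 10,000 epochs. Design points
the study leaves open, decided here:

* The epoch budget "10.000" is read as ten thousand (European decimal
  separator); ten epochs cannot reach a 2×10⁻⁴ error.
* The tanh nonlinearity is applied to the hidden layer only; a tanh output
  could never reach the exact 0 and 1 that normalized boundary levels map
  to.
* Full-batch updates by default (an online per-sample mode is available
  via `batch_mode="online"`); weights initialize `U(−0.5, 0.5)` from the
  seed.
* Predictions pass back through the inverse output normalization and are
  not clamped, so values slightly outside [0, 1] are possible and visible.

Hidden-node count is selected by validation RMSE over a grid (default
2–12, tie → smallest); the study settled on nine inputs and five hidden
nodes (9−5−1), and the tests that probe noiseless parameter recovery use
exactly that topology. Training is deterministic given seed and data;
divergence (non-finite loss) raises an error carrying the failing epoch.

## Splitting and evaluation

Splits are stratified random partitions, reproducible under seed:
two-sevenths of each stratum forms the prediction set (84 → 60 train / 24
predict), classification stratifying by category and regression by level.
The source protocol's wording assigns two-sevenths to *training*, but its
printed misclassification counts (11 of 24 wrong at 54.17%, 14 of 60 wrong
at 76.67%) are arithmetically consistent only with two-sevenths as the
prediction share; the pipeline adopts that reading and repeats the note in
every report header.

Metrics are implemented exactly as the field prints them:
identification rate R = N₁/N₂ × 100%; RMSE = √(Σ(yᵢ−ŷᵢ)²/n); and
r = 1 − Σ(ŷᵢ−yᵢ)²/Σ(yᵢ−ȳ)². The last is algebraically a coefficient of
determination, not Pearson's correlation, but it is computed as printed
(and raises on constant reference values). Confusion tables use the fixed
class order; their trace over total equals the identification rate by
construction.

One master seed drives everything: per-stage seeds (generator, both
splits, ELM weights, BP-ANN initialization) are derived from it, so a rerun
with the same configuration reproduces `report.json` byte for byte.

## Problem sizes and reproducibility checks

The test suite and the acceptance script work at the study's own scale —
84-sample experiments, 36 features, networks with ≤ 50 hidden units —
with seed-averaged properties evaluated over 10–20 replicate experiments,
which a single CPU completes in well under a minute per batch. Oracle
checks (loop-assembled covariances, characteristic-polynomial eigenvalues,
explicit-inversion discriminant axes, double-loop pixel scans) run on
deliberately tiny instances where brute force is exact.

## Known limitations

* The study's dataset-dependent numbers (ELM 91.27%/87.5%, LDA
  76.67%/54.17%, BP-ANN r = 0.85 / RMSE = 0.147, 91.55% at nine PCs, ELM
  L = 29) are not reproducible without the original measurements; the
  package reproduces the qualitative ordering and regime, and its reports
  carry its own computed values.
* Nearest-centroid LDA ignores per-class covariance differences; no
  quadratic or regularized discriminant variants are provided.
* The ELM has no ridge (C-parameter) or kernel variant; the BP-ANN has no
  adaptive optimizers or early stopping — both deliberately match the
  study's plain formulations.
* Imaging assumes fixed plate geometry and scanner settings; there is no
  color calibration or spot detection.
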