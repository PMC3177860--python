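# Methods

## Model and assumptions

The pipeline treats the warm/cool dichotomy of color naming as a sign
readout of the L−M cone-opponent channel, and tests that reading at two
levels: psychophysical (per-chip warm/cool vote counts vs. the chip's
opponent responses) and physiological (two-way clustering of cortical
population responses vs. the stimulus opponent responses).

Colorimetry is linear throughout. A chip's reflected spectral power
distribution is the element-wise product of its reflectance with the
illuminant on a common wavelength grid; cone excitations are dot products
with the L/M/S fundamentals, with the L fundamental scaled by `l_scale`
(default 1.98) so that L+M approximates the luminous efficiency function;
computations are in energy units, consistent with that luminous-efficiency
scaling. Cone contrasts are Weber fractions against a reference gray, and
the opponent channels are the fixed linear combinations
`R_LM = 0.5 C_L − 0.5 C_M` and `R_Y = 0.25 C_L + 0.25 C_M − 0.5 C_S` (LGN
cell-population weights). Two exact consequences are tested as invariants:
rescaling the illuminant leaves every contrast unchanged, and replacing the
reference by `α·reference` scales both opponent responses by exactly `1/α`
(the constant terms cancel because 0.25 + 0.25 − 0.5 = 0), so all sign-based
conclusions are independent of which gray is chosen.

Display stimuli specified only as CIE xyY (the nine isoluminant colors at
9.5 cd/m², plus the adaptation gray) are converted to cone excitations by
reconstructing XYZ and applying the Hunt–Pointer–Estévez XYZ→LMS matrix,
stored in `data/defaults.yaml`. No phosphor spectra are modeled. Under this
route blue has the most negative R_LM and R_Y of the set (checked by test),
which is what justifies anchoring the negative response cluster at blue.

## Reference data

The packaged illuminant and cone fundamentals are **synthetic analytic
stand-ins**, named accordingly (`illuminant_daylight_synthetic.csv`: a
Planckian radiator at 6504 K, normalized to 100 at 560 nm;
`cone_fundamentals_synthetic.csv`: unit-peak Gaussians in log10 wavelength
peaking at 570/543/442 nm). They reproduce the qualitative structure the
sign analyses need — heavily overlapping L and M, short-wave-isolated S,
smooth broadband daylight — but they are not the tabulated psychophysical
fundamentals, so absolute contrast values should not be compared against
published colorimetry. Both loaders accept user-supplied tables;
`scripts/make_reference_data.py` regenerates the CSVs from the analytic
functions.

## SVM stage

Features are normalized per variable to zero mean and unit **population**
standard deviation (recorded in the classifier, so either scale can be
used; predictions on raw features equal predictions on normalized features
exactly). The soft-margin problem is solved by libsvm via scikit-learn
(`C` default 1, the libsvm default; solver tolerance 1e-6, at which the
solution matches an exact quadratic program to ~1e-5 on small problems).
Slacks are recovered as `ξᵢ = max(0, 1 − cᵢ f(xᵢ))`. Cross-validation
shuffles with a seed and splits into contiguous near-equal folds;
`n_folds = n` is leave-one-out; folds whose training part is single-class
are skipped with a warning. The information criteria are
`SVMICa = Σξ + 2S` and `SVMICb = Σξ + S·ln n` with `S` input variables and
`n` training samples; a variable is flagged non-contributing when its
exclusion lowers the criterion. A decision value of exactly 0 predicts +1.

The border angle between the fitted class boundary and a named axis is
computed in a rescaled 2-D plane (axes divided by scale factors, typically
the per-feature standard deviations, to match contrast ranges):
`atan(|w'_k| / |w'_other|)` with `w' = W/scales`. In degenerate instances
the soft-margin intercept is not unique (no support vector lies strictly on
the margin); the oracle tests accept two solutions as equivalent when their
weights and primal objectives agree.

## Imaging stage

Registration translates each trial's averaged pre-stimulation and response
frames (11 frames before; the last 5 during + 2 after stimulation) to the
first trial's pre-stimulation frame, maximizing Pearson correlation on the
overlap over integer offsets within `±max_shift` (default 3 px; ties go to
the smallest offset) and cropping the common valid margin. Activation is a
reflectance *decrease*, so maps are negative at responsive pixels. Two map
estimators are provided: the conventional `(response − pre)/pre` average,
and a classifier map — a linear SVM over pixels separating per-trial
response means from pre-stimulation means, whose unit weight image is
scaled by the projection of the mean difference onto it (sign-stable) and
divided by the mean light level. Static structure common to both frame
groups (vessels, illumination gradients) carries no class information and
is suppressed in the classifier map. The sample matrix is centered and
uniformly rescaled before the fit purely for solver conditioning; a scalar
rescaling cannot change the weight direction.

The response threshold is the most negative pixel of the control map
("exceeding" it means strictly more negative — the minimum itself is noise
by construction). Composite patches are 8-connected components (configurable)
of the OR of the per-color binary maps, kept when at least `min_colors`
(default 5) colors have suprathreshold pixels inside and no pixel touches
the outermost row/column. Per-color response vectors over a patch's pixels
are normalized to zero mean and unit population sd, which makes them
invariant to any positive-gain affine intensity change and removes the
spatially coherent component of ongoing activity — the relative, not
absolute, signal is clustered.

The two-way clustering is a faithful reimplementation of the two-phase
k-means (batch reassignment to convergence, then single-point reassignment
accepted only when the total cost drops), run from **every** pair of points
as seeds with the minimum-cost run returned; for n ≤ 12 this matches
exhaustive enumeration of all bipartitions on every tested instance. Cost is
summed squared Euclidean point-to-centroid distance by default (the default
of the reference implementation the field uses), with an unsquared option
for sensitivity checks. The cluster containing blue is "negative". The
binomial test on quadrant counts is exact and two-sided (twice the smaller
tail, capped at 1). The outlier comparison `mean N_d(R_LM) < mean N_d(R_Y)`
uses a paired one-tailed t-test by default (the same patches are scored
under both references; the sources do not state the pairing, so the
two-sample variant is kept behind a flag). A color whose reference value is
exactly 0 supports no prediction and counts as an outlier, with a log
message.

## Synthetic data

The chip generator emulates a WCS-like array: `n_hues × n_values` chips
(default 40 × 8 = 320) with baseline-plus-Gaussian-band reflectances (band
center sweeping 430–660 nm with hue; baseline and band amplitude growing
with lightness; band sd 30 nm) plus one flat-spectrum gray flagged as the
reference. Votes are `N_w ~ Binomial(T, σ(β·R_LM))` with `T = 100` votes
per chip and `β = 60` by default, chosen so that sign flips concentrate on
low-|R_LM| chips and overall concordance lands in the mid-to-high 90s — the
regime reported for the real survey; `β = 0` gives chance concordance and
large `β` makes every majority follow `sign(R_LM)` exactly.

The imaging generator emulates one session at desk scale (128×128 px, 3
patches, 10 blocks by default; frame counts 11 pre / 18 during / 2 post,
one trial per stimulus incl. a gray-screen control per block, pseudo-random
order). The scene is a baseline light level with 5% smooth spatial structure
and dark curvilinear vessel artifacts (12% absorption). Each ground-truth
patch holds two response modes displaced along a random axis: a color's
response blob sits on the `sign(R_LM)` side at distance
`offset/2 · (0.5 + 0.5·sqrt(|R_LM|/max))` plus a fixed per-(patch, color)
positional jitter (sd 1.5 px) — a hue-map-like continuous shift around two
modes, which is what makes weak-contrast colors occasionally miscluster the
way recorded patches do. Response amplitude is compressive in |R_LM| (floor
0.2, ×(1 + 0.15·|R_Y|/max) to let the S-(L+M) channel modulate amplitude
without changing the spatial mode), peak 0.4% of baseline. Ongoing activity
is a spatially coherent Gaussian field (correlation length 24 px, larger
than a patch; AR(1) in time, ρ = 0.6) at 0.1% of baseline per frame,
calibrated once so that every color's cross-patch majority still follows
`sign(R_LM)` while individual patches show a realistic spread of outliers;
per-pixel camera noise is 0.1%, and whole-frame movement jitter is up to
±2 px per trial. What the generator does **not** emulate: hemodynamic time
courses, non-rigid movement, photon (signal-dependent) noise, realistic
Munsell spectra, inter-animal variability, and palette-level naming
structure (votes are independent Bernoulli draws, not languages). Passing
tests therefore certify the pipeline's recovery of the encoded structure
under this noise model, not performance on raw recordings.

## Problem sizes and numerics

Default analyses run on the 320-chip array with leave-one-out
cross-validation, and on four pooled 128×128 sessions (12 patches) for the
imaging statistics — large enough for every statistic the pipeline reports
while keeping a full run under a minute. All stochastic steps take explicit
seeds and results are bit-reproducible given seed + config; reports contain
no timestamps. Oracle agreement in tests uses 1e-9 relative tolerance for
clustering cost, 1e-4 for SVM decision values, and exactness for integer
registration offsets. Degenerate inputs fail loudly: constant feature
columns, constant frames (undefined correlation), single-class training
data, reference excitations ≤ 0, patches with constant response (excluded
with a warning), zero-variance paired differences in the t-test.

## Known limitations

Quantitative colorimetric outputs depend on the synthetic reference data
(see above). The classifier activation map is a simplified stand-in for the
published companion method (trial-mean frames as samples, pixels as
variables); the conventional map is always available for comparison, and on
artifact-free data both select the same patches up to boundary pixels. The
intercept non-uniqueness of the soft-margin SVM means reported axis
intercepts are meaningful only when the data pin them down (dense chips near
the boundary do). Registration is integer-resolution by design; sub-pixel
motion appears as residual blur, not as an error.
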