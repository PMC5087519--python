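# Methods

## Dynamic-speckle model

The simulator draws a complex circular-Gaussian scattered field `E_0`,
spatially smoothed with a Gaussian kernel of scale `grain_sigma` (pixels) to
set the speckle grain size, and evolves it as an order-1 autoregressive
process

    E_t = rho · E_{t−1} + sqrt(1 − rho²) · W_t,

with independent smoothed innovations `W_t`. Recorded intensity is
`|E_t|²`. Modelling the *field* (not intensity) as AR(1) gives `rho` a
clean physical meaning — the frame-to-frame correlation of the underlying
scattered field — and makes both limits exact: `rho = 1` is a frozen
(static) stack and `rho = 0` gives independent frames. One-frame intensity
statistics are negative-exponential to good approximation (coefficient of
variation ≈ 1 for `grain_sigma ≤ 1`), i.e. fully developed speckle.

Intensities are linearly rescaled **once per stack** and quantized to
`bit_depth` (default 256) levels. Per-frame rescaling would manufacture
frame-to-frame gray-level transitions out of pure normalization and bias
the inertia moment, so it is deliberately avoided.

What the generator does *not* emulate: light–tissue interaction, speckle
boiling vs translation, polarization, camera read noise, or the slow
drift of real specimens. Passing tests therefore demonstrate correctness
of the analysis chain and the *direction* of activity effects, not
instrument-level realism; absolute BA values are in arbitrary units tied
to the simulation conditions.

## THSP, co-occurrence matrix, inertia moment

One spatial column (0-based index; default the middle column, which is
index 255 of a 512-wide region — the "256th" in 1-based counting) is
extracted from every frame and stacked chronologically into an `H × T`
THSP. All `H` rows contribute their `T − 1` temporal transitions to the
co-occurrence counts `N_ij`, so `Σ N_ij = H(T − 1)`. Rows of the
normalized matrix belonging to gray levels never visited are left at zero:
the row normalization is undefined there, and zeros preserve the
`Σ M_ij (i − j)²` semantics. `BA = IM` is computed vectorized and verified
against an independent triple-loop brute-force oracle to 1e-12 relative.

Gray levels default to 256 (8-bit sensor); coarser quantization is an
efficiency knob only.

### Time windows

A window of `w` seconds uses the **prefix** `floor(w · frame_rate)` frames
of the recording. At 12.5 Hz this makes the 10/20/30/40 s windows use
125/250/375/500 frames. A nominal 40 s recording of 512 frames is slightly
longer than 40 s; the window spec `"all"` addresses the full recording, so
both the 500-frame arithmetic and the 512-frame behaviour are reachable.
Window-consistency tables use Pearson correlation across samples (the
self-row is exactly 1).

## Synthetic SS/IS patches

Sound-skin patches are Gaussian noise around a potato-skin RGB mean
(default (150, 120, 90), channel SD 8). Injured-skin patches shift every
channel by `−con` so that the BT.601 luminance contrast
`Con = gray(SS) − gray(IS)` hits the target; after rendering `n_lenticels`
dark disks (darkening factor 0.45, minimal emulation of the lenticel spots
scattered over injured areas) the IS patch is re-centred so the realized
float contrast is exact, leaving 8-bit quantization as the only error.
Negative `con` reproduces the fresh-wound regime in which the wet injury
reflects more light than sound skin. Texture realism is deliberately
minimal: no quantitative texture description of injured periderm was
available to emulate.

Default contrast 30.9 corresponds to the 1-day storage regime; class rho
values (0.95 sound, 0.5 fresh injury) encode the strong activity contrast
of the first hours after wounding.

## Visible features

- **Gray conversion**: ITU-R BT.601 luminance everywhere; fixed so every
  extractor sees identical gray values.
- **Color (6)**: per-channel means and *population* SDs.
- **GLCM (8)**: quantization to 32 levels, symmetric normalized matrices
  at distance 1 and directions 0/45/90/135°; mean and SD over the four
  directions of ASM, entropy (natural log), inertia and correlation.
  Correlation of a zero-variance image is defined as 0 (a constant patch
  has no linear dependence to measure). Matrix construction is delegated
  to scikit-image; the four statistics are computed here and cross-checked
  in tests against both a pair-counting oracle and `graycoprops`.
- **Gabor (108)**: wavelengths {4, 8, 16} px — chosen to span a 65-px ROI —
  at 1-octave bandwidth, spatial aspect ratio 0.5, orientations
  0/45/90/135°; mean response magnitude over each cell of a 3×3 block grid
  (blocks as equal as integer division allows), ordered by
  (scale, orientation, block-row, block-col). Magnitude (not energy) is
  the block statistic; all bank parameters are constructor arguments.
- **DT-CWT (12)**: one decomposition level; six oriented complex subbands
  (±15°, ±45°, ±75°) built by non-decimated filtering with the LeGall 5/3
  analysis pair followed by quad-to-complex combination of the four
  polyphase components (at level 1 the dual tree is a one-sample shift of
  the primary tree). Features are mean |real| and mean |imag| per subband.
  Odd-sized patches are symmetrically padded to even dimensions. One level
  is appropriate for 65-px ROIs; deeper levels would need the longer
  quarter-shift filter pairs.

ROIs are hand-specified (CSV of image, label, row, col, size); the package
never auto-detects injury.

## Classifiers and evaluation

**LS-SVM**: binary, RBF kernel `exp(−‖x−x'‖²/2σ²)`, labels ±1. Training
solves the dense KKT system `[[0, 1ᵀ],[1, K + I/γ]]·[b; α] = [0; y]`
directly; the relative residual of that system is stored on the model and
asserted `< 1e-8`. Features are z-scored with training statistics inside
the estimator, so resampling loops cannot leak test information.
Hyperparameter search (`tune_lssvm`) is a cross-validated grid with a
deterministic tie-break toward the smallest γ, then σ.

**Binary logistic regression**: IRLS/Newton with step-halving, which makes
the recorded log-likelihood path monotone non-decreasing. Complete
separation is detected (all points correctly classified with margins
beyond 30 in absolute value — probabilities within 1e-13 of 0/1); fitting
then stops with coefficients capped at the current iterate and a
`separated_` flag, keeping training classification perfect while avoiding
divergence. Standard errors come from the inverse Fisher information; the
fit agrees with an independent maximum-likelihood implementation to 1e-6
in tests.

**Evaluation** is a stratified repeated random split, training fraction
2/3 ("2:1 distribution ratio"), 50 repeats by default, reporting mean and
SD of held-out accuracy plus summed confusion tallies. The split protocol
is also used for the scalar-BA channel, since no alternative protocol was
specified; leave-one-out can be emulated with a high repeat count and
small test fraction if needed.

### The permutation null

"Shuffled labels give chance accuracy" needs care: a *single* label
permutation bakes chance class imbalance into the two feature clusters,
and a classifier that memorizes cluster majorities scores measurably above
0.5 on held-out data (≈ 0.54–0.66 at these sample sizes). The test suite
therefore checks the null two ways: (a) i.i.d. Bernoulli(0.5) labels on a
fixed split — there the test labels are independent of everything the
model saw, expected accuracy is exactly 0.5, and the mean over 40 draws is
asserted within 3 SE; and (b) a single shuffle asserted within 3
per-repeat SDs (dispersion, not SE) of 0.5.

## Problem sizes

Monte-Carlo checks use 64×64-pixel stacks (the THSP uses one column, so
spatial extent beyond the tracked column only adds rows/averaging),
125 frames for the activity-vs-rho grid (20 seeds × 5 rho values) and
512 frames for the window-consistency grid (30 samples), 20 patch pairs
per classification task, and 40–50 split repeats. These sizes keep every
statistic stable across seeds (Spearman −1.0, window r ≈ 0.94–0.97,
accuracies ≥ 98 %) while the full suite and the acceptance script each
finish in well under a minute.

## Known limitations

- Single-column THSP only; multi-column averaging or region-wise activity
  maps are out of scope.
- 8-bit imagery only; higher bit depths are rejected at I/O.
- Alternative activity estimators (generalized differences, LASCA,
  wavelet entropy) are not implemented.
- Accuracies measured on synthetic data characterize the pipeline, not
  field performance on real tubers.
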