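# Methods

This note records the models implemented in `hsseg`, the choices made where
the underlying method descriptions are ambiguous, the parameters that
matter, what the synthetic phantom does and does not emulate, and the known
limitations.

## Data model and conventions

A hyperspectral cube is a `(rows M, cols N, bands I)` array; in memory all
cubes are `float64` and 0-based (the field's 1-based `(m, n, i)` notation
maps by subtracting one). On disk a cube is a headerless binary block plus
a sidecar text header (`<file>.hdr`, `key = value` lines plus a braced
wavelength list). BIL interleave is canonical: the byte offset of element
`(m, n, i)` is `((m·I + i)·N + n)·itemsize`, so the first `k` rows occupy
exactly the first `k·N·I` values — the property the SKE fast path relies
on. BSQ is supported for interchange only; BIP is not supported. Default
storage is little-endian `uint16` carrying a 12-bit dynamic range; the
header validates that the storage type can hold the declared range.

Whether bands or samples vary fastest within a BIL row block is a
convention of the acquiring camera; if a vendor file disagrees with this
reader, convert once via the BSQ path.

## Preprocessing

* **3D median** (default 3×3×3, replicate padding): removes isolated
  artifacts, which are assumed ≤ 4 px in-plane and confined to single
  bands. Replicate (edge) padding is used everywhere because the band
  edges — where the noise is largest — must not be contaminated with
  invented values.
* **Band-adaptive median**: sensor noise peaks at the spectrally outermost
  bands, so the in-plane mask grows from `mid_size` (default 3) at the
  central band to `edge_size` (default 7) at bands 0 and I−1, linearly in
  band index and rounded to the nearest odd integer; the spectral extent
  of the mask stays fixed (default 3). Only the in-plane size adapts.
* **Dark/white calibration**: `L_C = (L − L_DARK)/(L_WHITE − L_DARK)`,
  clipped to [0, 1]. Voxels where white equals dark are set to 0 and
  counted in a warning. The result is invariant to a common positive gain
  and offset applied to all three cubes.

## SKE — emissivity-curve screening

The chain is Eq.-by-Eq.: relative difference → per-pixel count of
tolerance exceedances → grey map `L_V = 1 − |L_R|/max|L_R|` → threshold.
Decisions:

* **Exceedance rule.** The mismatch indicator counts `|L_D| ≥ p_r`
  (two-sided): a one-sided signed rule would never flag under-emission,
  and only exceedance counting is consistent with `L_V = 0` being the
  *maximum* error. The literal one-sided variant (`L_D < p_r`) is kept
  behind `literal_rule=True` for cross-checks.
* **Degenerate normalization.** If no pixel mismatches anywhere,
  `L_V ≡ 1` (zero mismatches is minimal error).
* **Default tolerance** `p_r = 0.1` (10 % relative deviation) — of the
  order of the calibrated noise floor at the band edges; always report the
  value used.
* **Partial-row caveat.** `max|L_R|` is taken over the rows analysed, so a
  partial-row mask equals the corresponding rows of the full-image mask
  exactly when the maximal mismatch count (typically fully mismatching
  background) is represented among those rows.
* The reference curve must be in the same radiometric space as the cube
  (raw counts vs. raw, calibrated reflectance vs. calibrated).

## S3D — whole-sequence segmentation

`L_PAT` is the per-band ROI mean; the signed difference volume is filtered
with the full 3×3×3 median (the in-plane 8-neighbourhood extended to the
two adjacent bands). The percent error scale is defined here as

    L_S(m,n) = 100 · mean_i |L_V(m,n,i)| / mean_i L_PAT(i),

i.e. mean absolute deviation as a percentage of the mean reference level —
one defensible reading that makes thresholds like 30/20/10 % dimensionally
meaningful; users comparing against other implementations should check
their percent convention. `L_S` is then smoothed with an in-plane median
window and thresholded from above (a pixel is accepted where its error is
*below* the bound), giving nested levels rendered as a multi-level label
map (label k = accepted down to the k-th threshold).

The in-plane smoothing window defaults to 29×29 (the nearest odd size to a
30×30 plane filter, which has no well-defined centre) and is meant for
~700×520 frames; scale it roughly with the frame (15×15 at 96×96;
`plane_window=1` disables it). Since every stage uses square windows and
replicate padding, the method commutes exactly with 90° rotations.

## SH — hierarchical segmentation

* **Pooling**: block means over 8×8 (noise-suppressing, unlike
  decimation); trailing partial blocks average over their actual extent.
* **Features**: `w(k) = |L_C(m,n,i_k) − L_PAT(i_k)|` at the `F = 3`
  strongest interior local maxima of the reference curve (plateaus take
  the leftmost band; a monotone curve is rejected with a pointer to manual
  band selection). Features share units (reflectance difference) and are
  deliberately not rescaled.
* **Clustering**: multi-restart k-means (10 restarts, fixed seed) for
  K = 2…5. The "nearest-neighbour analysis" of the original description
  has no training labels, so it is read as unsupervised centroid
  clustering.
* **Class-count criterion**: for each K the dispersion is the mean over
  classes of the *standard error of the class mean* — per-class RMS spread
  about the centroid divided by √n_k. The raw within-class spread would
  decrease every time k-means splits a coherent cluster (splitting a
  Gaussian blob shrinks its per-class RMS by ~0.6–0.9×) and would always
  drive K to the maximum; dividing by √n_k makes a needless split *raise*
  the criterion (~1.26× per split), so it bottoms out at the natural class
  count. Raw spread ("std") and within-class MSE ("mse") are available via
  `criterion=`. Ties break toward smaller K.
* **Object class** = the cluster whose centroid is nearest the feature
  origin (best match to the reference curve). Clustering happens once, at
  reduced resolution; labels are upsampled blockwise.
* **Per-band re-binarization**: full-resolution band masks are
  `|L_C(:,:,i) − L_PAT(i)| ≤ τ_i` with `τ_i` the midpoint between the
  object class's mean absolute deviation and that of all other pixels
  (one-vs-rest), estimated at reduced resolution.
* **Final mask** = per-pixel majority vote across the (stabilized) band
  masks.

On a noiseless two-class scene the unstabilized chain recovers the ground
truth exactly; the spatial filters (3D median, plane median, conditional
morphology) each trade ≤ 1–3 boundary pixels at corners and
high-curvature tips for noise robustness.

## Conditional morphology

Per band `i`, the gate is the windowed mean `p_c` of the *normalized*
brightness (values in [0, 1]; the stabilizer refuses unnormalized input).
With structuring element `M_S × N_S` (default 17×17) and gates
`p_ec = p_dc = 0.5`:

* erosion: copy where `p_c < p_dc`, otherwise minimum over the SE;
* dilation: copy where `p_c > p_ec`, otherwise maximum over the SE;
* order: erosion then dilation, each band processed independently
  (`order=` is configurable; no propagation from band to band).

Consequences of these gate polarities: specks are eroded where the
surroundings are *bright* and holes are filled where they are *dark*, so
the stabilizer expects a **dark object on a bright background** in the
normalized cube — invert the band first for the opposite polarity.
`p_dc = 1, p_ec = 0` reduce both gates to the copy branch (identity);
`p_dc = 0` / `p_ec = 1` reduce to plain erosion/dilation. The gates act on
a brightness *mean*, so a dark object's convex corners (whose windows are
bright-majority) are unavoidably shaved by a few pixels; the majority vote
across bands absorbs this in the composed SH pipeline. The 17×17 element
suits ~700×520 frames — scale it with the frame (9×9 at 96×96), keeping
it at least twice the expected noise-component size. The gate thresholds
are camera constants to be set once per acquisition setup.

## Evaluation

Binary masks are scored with TPR = TP/(TP+FN), SPC = TN/(TN+FP) and
balanced accuracy ACC = (TPR+SPC)/2, in percent (balanced, because the
object typically covers a small fraction of the frame). An empty positive
or negative class raises an error naming the class rather than returning a
silent NaN. Multi-level S3D outputs are binarized per level; multi-class
SH labelings are evaluated one-vs-rest on the object class. `rounded()`
applies half-up integer rounding for comparison against integer-printed
tables.

## Synthetic phantom

The generator emulates the target acquisition regime: 12-bit linear camera
(`counts = dark + R·(white − dark)`, quantized and clipped), 0.4–1.0 µm
wavelength axis, per-band Gaussian noise rising linearly from `σ_mid` (1 %
of full scale by default) at the central band to `σ_mid·edge_gain` (×3) at
the outermost bands, and single-band salt/pepper artifacts of at most 4 px
a side. Scene spectra are Gaussian-peaks-over-baseline models, which give
controllable local maxima for SH's feature bands. Geometry defaults to
96×96×32 so the full study runs in seconds; `rows=696, cols=520,
bands=128` reproduces the full camera geometry.

Two deliberate design choices:

* the default object (baseline 0.25, three peaks to ≈ 0.45) and background
  are exact spectral complements (sum = 1 per band), which pins the 50 %
  object/background mixing level to reflectance 0.5 — precisely where the
  default morphology gates expect the boundary — and keeps a ≥ 0.1
  reflectance gap at every band, so all three methods separate the classes
  with margin by construction;
* noise is independent across pixels and bands.

What the phantom does **not** emulate: realistic tissue optics
(melanin/haemoglobin absorption), camera PSF and smile/keystone,
illumination non-uniformity beyond the dark/white model, spatially or
spectrally correlated noise, and partial-volume mixing at object borders
(edges are hard). Passing the phantom study therefore demonstrates the
correctness and composability of the algorithms under their stated
assumptions, not clinical-grade performance on real tissue.

## Numerical choices and degenerate inputs

* Replicate padding for every window (medians, means, morphology).
* Odd-size windows everywhere; even sizes are rejected, and the adaptive
  median schedule rounds to the nearest odd.
* Threshold lists for S3D must be strictly decreasing within (0, 100).
* k-means degeneracy (< K distinct feature vectors) raises rather than
  fabricating empty classes; `select_class_count` caps K at the number of
  distinct vectors.
* Calibration guards division by zero (white = dark → 0, counted);
  SKE refuses reference curves with zero entries, naming the band; S3D
  refuses a zero-mean reference level.
* Fixed seeds thread through every stochastic component (phantom rendering
  and k-means restarts); identical configuration + seed reproduces outputs
  bit-for-bit.

## Known limitations

* The percent error scale of S3D and the dispersion criterion of SH are
  documented interpretations of ambiguous prose; both are isolated behind
  single functions (`aggregate_error`, `cluster_pixels`) with alternatives
  where applicable.
* Window sizes (plane median, SE) are frame-scale-dependent and must be
  chosen by the user; defaults target ~700×520 frames.
* Conditional morphology assumes the dark-object/bright-background
  polarity described above.
* The partial-row fast path requires BIL interleave by design.
* No automatic ROI discovery: the ROI is an input.
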