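# Methods

This note documents the models, numerical choices and limitations behind
`rgbrsfc`. It is written for users who need to judge what a result computed
with this package does — and does not — mean.

## Problem setting

During brain tumor resection, the neurosurgeon needs to know which patches of
the exposed cortex are functional. An RGB camera filming the craniotomy
window sees slow intensity fluctuations caused by changes in oxy- and
deoxyhemoglobin concentration (ΔC_HbO2, ΔC_Hb), the same hemodynamic signals
that fMRI and fNIRS exploit. The package turns such a video into functional
maps three ways: correlating each pixel with a theoretical task response,
correlating each pixel with a seed region, and decomposing the pixel × time
matrix with spatial ICA — then binarizes the maps and quantifies their
agreement.

## The chromophore model

The modified Beer–Lambert law links per-channel intensity ratios to
concentration changes. With channels c ∈ {R, G, B} and chromophores
n ∈ {HbO2, Hb}:

    ΔA_c(p, t) = log10( I_c(p, 0) / I_c(p, t) )
               = Σ_n ε_n(c) · L_c(class(p)) · ΔC_n(p, t)

* **Absorbance base.** Base-10 logarithms, the convention of the modified
  Beer–Lambert literature; ε is in cm⁻¹·(mol/L)⁻¹ and L in cm.
* **Reference intensity.** The first post-preprocessing frame per pixel. All
  concentrations are changes relative to that frame, which is also the frame
  the tissue segmentation uses.
* **Effective wavelengths.** A real camera channel integrates over a broad
  spectral band. We reduce each channel to a single effective wavelength
  (610, 530, 470 nm for R, G, B) because camera sensitivity curves are
  device-specific; the extinction table is a plain CSV that users should
  replace for quantitative work on their own hardware.
* **Path lengths.** The mean photon path length depends on wavelength and on
  tissue type (gray matter, surface vessel, buried vessel). Accurate values
  require photon-transport simulation of the actual imaging geometry; the
  packaged table holds synthetic order-of-magnitude placeholders, clearly
  labeled as such. Map topology — which drives every comparison metric — is
  insensitive to the absolute scale; reported mol/L values are not.
* **Inversion.** Three channels and two chromophores give an overdetermined
  3 × 2 linear system per pixel and frame, solved by ordinary least squares
  (precomputed pseudo-inverse per tissue class, applied vectorized). Pixels
  with any nonpositive intensity are flagged invalid and carry zeros.

## Preprocessing

Fixed order: motion compensation → drift correction → low-pass → inversion.

* **Motion.** Brain motion under the craniotomy is dominated by periodic
  cardiac/respiratory displacement. Each frame is registered to frame 0 by
  subpixel phase correlation (upsampling factor 10 ≈ 0.1 px resolution) on
  the grayscale channel mean, then resampled bilinearly with edge
  replication. Rigid translation only; an estimated shift above 25 % of the
  frame is treated as a registration failure.
* **Drift.** Tissue desiccation causes a slow multiplicative intensity
  drift. A per-pixel, per-channel least-squares polynomial (degree 1 by
  default) is removed, and the temporal mean is then restored — the
  Beer–Lambert ratios need a meaningful baseline, so detrending must not
  recenter the series at zero.
* **Low-pass.** 4th-order Butterworth with 0.08 Hz cut-off, applied
  forward–backward (zero phase, so hemodynamic timing is preserved for the
  correlation maps; the effective magnitude response is the square of the
  single-pass response). Resting-state fluctuations live below 0.1 Hz; the
  0.08 Hz cut-off also passes the 0.025 Hz fundamental of the standard
  20 s / 20 s task block design, so one shared preprocessing branch serves
  both analyses. Filtering is applied to RGB intensities, before inversion.

## Functional maps

* **Task maps.** The theoretical response H is the stimulus boxcar
  (0 = rest, 1 = stimulation) convolved with a canonical double-gamma HRF
  (peak 6 s, undershoot 16 s, undershoot ratio 1/6, unit dispersions —
  configurable, since the true HRF is patient- and tissue-dependent). HbO2
  theory is +H, Hb theory −H. The map is the Pearson correlation of each
  pixel's full filtered series with its theory; no epoch windowing.
* **Seed maps.** The seed is a 20-pixel-diameter disk; its spatial-mean time
  course is correlated against every pixel. Constant or invalid pixels get
  r = 0.
* **ICA maps.** Each chromophore's pixels × time matrix is standardized per
  pixel (zero mean, unit variance; zero-variance pixels excluded and
  reported), then decomposed with FastICA into K = 5 independent temporal
  sources; the spatial maps are the columns of the pseudo-inverse of the
  unmixing matrix. The 5 images are sorted by spatial variance, ascending.
  Because ICA sign is arbitrary, each component is flipped so its
  largest-magnitude spatial weight is positive, which makes the positive
  branch of the thresholding rule select the component's dominant lobe and
  makes runs reproducible. FastICA runs with tol = 1e-3 and max_iter = 1000;
  a tighter tolerance makes the minor, noise-chasing components oscillate
  indefinitely without changing map topology, so non-convergence at 1e-3 is
  treated as an error rather than silently accepted.

## Binarization and comparison

A map I with valid-pixel statistics μ_I, σ_I is thresholded at
T = μ_I + α·σ_I if μ_I ≥ 0 (keeping values ≥ T), else at T = μ_I − α·σ_I
(keeping values ≤ T); the severity criterion α defaults to 0.75. Both
branches keep the extreme tail on the side of the mean's sign, so the rule
is symmetric under negating the map. The binary map is cleaned with a
morphological opening followed by a closing using a 20-px-wide disk
(specks smaller than the element vanish, comparable holes close), and pairs
of maps are compared with

    DICE(X, Y) = 2|X∩Y| / (|X| + |Y|)      Overlap(X, Y) = |X∩Y| / |X|

DICE is symmetric; Overlap is the fraction of the reference map X (the
task-based map, in the standard comparison) contained in Y. Marked
stimulation-response points are tested for plain pixel membership in the
binary maps. Degenerate cases are defined, not fatal: two empty masks give
DICE 0 with a warning, a flat map thresholds to an empty mask with a
warning. Cardinalities are computed after morphological cleanup.

## The digital-cortex phantom

No intraoperative videos are publicly available, so the package ships a
generator whose output has known ground truth and the statistical structure
the pipeline assumes:

* **Networks.** Binary masks (two 18-px-radius disks by default in a
  128 × 128 field) each carry one shared source signal: Gaussian noise
  band-limited to 0.01–0.08 Hz, synthesized in the frequency domain (random
  Gaussian Fourier coefficients strictly inside the open band, zero
  outside), scaled to 1 µmol/L peak ΔC_HbO2. Keeping modes strictly inside
  the band keeps planted sources clear of the analysis filter's cut-off and
  of the record-length mode that a linear detrend would eat. Sources of
  distinct networks are drawn independently and then decorrelated in-sample
  (Gram–Schmidt on the centered traces): over a 100 s record the empirical
  correlation of two independent band-limited signals has a standard
  deviation near 0.3, so without this step the planted "uncorrelated
  networks" ground truth would carry large sampling noise. ΔC_Hb is coupled
  as −γ·ΔC_HbO2 with γ = 0.4, a typical optical-imaging amplitude ratio.
* **Task.** Optionally, the HRF-convolved 20 s / 20 s block response is
  planted in a task region at ±1 µmol/L (positive HbO2, negative Hb, equal
  magnitude). The task region can coincide with network 1 to emulate a task
  run over a resting-state network.
* **Rendering.** The true concentration video passes through the same
  Beer–Lambert forward model the inversion assumes, with per-class baseline
  intensities (gray matter brighter, vessels redder and darker). Then, in
  order: per-channel linear multiplicative drift (−2 to −3 × 10⁻⁴/s,
  a few percent over 100 s), sinusoidal rigid translation (2 px amplitude,
  1.1 s period — cardiac-like), and i.i.d. Gaussian sensor noise with
  sd = 0.5 % of the local baseline. All randomness flows from one seed;
  identical configs render byte-identical videos.
* **What the phantom does not emulate.** Nonrigid motion, spatially
  correlated noise, Mayer waves and respiration harmonics, specular
  reflections, realistic vessel geometry, and nonlinear desiccation.
  Passing recovery tests on the phantom therefore demonstrates the
  pipeline's correctness under its own model assumptions, not clinical
  performance on patient videos.

## Problem sizes and tolerances

Recovery checks run on the default phantom (128 × 128, 100 s at 10 Hz,
1000 frames), the scale at which a full analysis takes well under a minute;
the exactness check for the Beer–Lambert round trip uses a quiet 64 × 64,
200-frame phantom and demands relative error below 1e-9 (the inversion is
algebraically exact there, so only floating-point error remains). Metric
implementations are checked against explicit pixel-set enumeration to 1e-12
on a thousand random mask pairs. End-to-end determinism is asserted at the
byte level on the comparison tables of two identically seeded runs.

## Known limitations

* Concentration scales inherit the placeholder path-length table; treat
  mol/L outputs as relative until the table is replaced with values from a
  photon-transport simulation of the actual optics.
* The tissue segmentation is a deterministic channel-ratio heuristic
  intended for phantoms and quick looks; supply a curated label map for
  real data.
* Rigid translation cannot compensate pulsatile deformation of the cortex
  surface.
* K = 5 ICA components is a fixed default; no automatic model-order
  selection is attempted.
* The double-gamma HRF is a population default; task maps degrade when the
  patient's response deviates from it, which resting-state analyses do not
  suffer from.
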