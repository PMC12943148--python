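# Methods

This note records the models behind `ringbeam`, the parameters that matter,
and the numerical and design choices made where more than one reasonable
option existed.

## Acquisition model

The ring array is modeled as N point elements uniformly spaced on a circle
of radius R (element 0 on the +x axis, counter-clockwise indexing). All
lengths are millimetres internally, times seconds, frequencies hertz;
sound speeds enter and leave the API in m/s and are converted once at the
boundary — mixing mm and m/s is the classic source of silent c-scaling
bugs in beamforming code.

Acquisition is full synthetic aperture ("one-to-all"): element n transmits
a spherical wave, all N elements receive, yielding an (N, N, T) RF cube
per slice. Echoes are single-scattering:

    r_nm(t) = sum_k a_k g(d_nk) g(d_mk) w_elev(z_k) p(t - (d_nk + d_mk)/c) + noise

* **Spreading** g(d) = 1/max(d, d_floor) with d_floor = 1 mm. The floor is
  purely numerical: a scatterer grazing an element would otherwise produce
  an unbounded amplitude.
* **Elevation.** The physical elevation aperture (10 mm) is treated as the
  FWHM of a Gaussian slice-sensitivity profile, sigma_elev = 10/2.3548 ≈
  4.25 mm. Scatterers off the slice plane are attenuated accordingly and
  their out-of-plane offset also enters the 3D propagation distance.
* **Pulse.** Default excitation is a 5-cycle bipolar square wave at the
  3 MHz center frequency, sampled at 40 MHz. Sample count is
  round(n_cycles/f0 · fs); the waveform is evaluated at midpoint times
  (j+1/2)/fs, which keeps the +1/-1 half-periods balanced, and residual DC
  is removed with the peak renormalized to 1. The pulse is **centered** on
  the geometric arrival index, so the echo envelope peaks exactly where a
  delay-and-sum beamformer samples. (With onset-at-arrival the beamformer
  samples the rising edge; mismatched speeds can then look *brighter* than
  the true speed — we observed exactly that before adopting the centered
  convention.) An optional zero-phase Butterworth band-pass (fractional
  bandwidth 0.6, matching a ">= 60% at -6 dB" transducer) models the
  device's band-limiting; it is off by default so the stated drive waveform
  is what propagates.
* **Noise** is white Gaussian, with SNR defined against the RMS of the
  noise-free frame. Seeded per frame; a scan derives slice k's seed as
  seed + k so a one-slice scan is bit-identical to a single-frame call.
* **Record length** T covers the round trip across the ring diameter,
  T >= ceil(2·(2R)/c · fs), padded by the pulse length and rounded up to an
  FFT-friendly size (the raw ceiling is prime for the 110 mm / 40 MHz
  configuration, which would make every Hilbert transform a Bluestein FFT).

What the simulator does **not** model: attenuation with depth (an
exponential hook exists but defaults off), multiple scattering and
reverberation, element directivity and finite element size, transducer
impulse response identification, and electronic crosstalk. Passing tests
therefore demonstrate correctness of the reconstruction chain under the
stated forward model, not robustness to every artifact of real hardware.

## Digital phantoms

**Resolution phantom.** Five "axial" wires at cumulative 4/3/2/1 mm gaps,
five "lateral" wires at 3/2/1/0.5 mm gaps, one isolated wire; nominal
0.3 mm wire diameter. By default each wire is a *single* scatterer at its
nominal axis position: a sub-wavelength solid wire reflects coherently, so
its phase center is the axis. Modeling a wire instead as a sparse random
cloud inside the 0.3 mm disk (available via `scatterers_per_line > 1`)
superimposes random phases spread over ~0.6 wavelength; we measured that
this speckle systematically drags the coherence-sweep argmax to a
carrier-period ambiguity ±7 m/s from the truth. Nominal wire coordinates
are round 0.1 mm values, as on a phantom datasheet. Optional lesion disks
(7 mm cyst-like, two 10 mm tumor-like, 10 mm stone-like) can be added.

**Breast phantom.** A 10 mm hyperechoic cylinder (tumor-like), a 6 mm
anechoic cylinder rendered visible by rim scatterers (cyst-like), a 5 mm
strongly reflective focus (calcification), and a uniform Rayleigh-amplitude
speckle background, all extruded 30 mm along the scan axis.

## Beamforming

Channel signals are converted to analytic form by the Hilbert transform
(complex64; per-transmit-row FFTs to bound workspace) so that the envelope
and channel coherence are well defined. Delays use the fractional index
t_idx = (d_Tx + d_Rx)/c · fs with **linear interpolation** between the two
neighboring samples — at ~13 samples per carrier period, nearest-neighbor
rounding visibly degrades resolution. Indices outside [0, T−1] contribute
nothing.

Apodization defaults to an acceptance-angle gate with half angle pi/2
(an element only contributes to points its face can see; for points inside
the ring this equals uniform weighting, but it excludes impossible paths
for exterior points and tighter gates are available). There is no per-pixel
weight normalization by default — the beamforming sum is a plain weighted
sum — but the per-pixel weight sum is carried in the output for audits and
an opt-in normalization flag exists for display comparability.

The inner gather loop (pairs x pixels) is a numba kernel; the test suite
pins it against a naive pure-Python triple-loop reference to 1e-9 relative.

## Sound-speed autofocus

The L1 coherence factor of the delay-compensated samples s_i is

    L1CF = |sum_i s_i| / (sum_i |s_i| + eps).

This normalized form is bounded in [0, 1] and equals ~1 for perfectly
aligned channels; the "printed" unnormalized ratio |Σs|²/(Σ|s|²+ε) that
sometimes appears in the CF literature evaluates to N for N identical
samples and cannot serve as a bounded focus criterion. The conventional L2
factor |Σs|²/(N·Σ|s|²+ε) is provided as a selectable variant, and every
report records which variant was used. eps defaults to 1e-12 x the maximum
channel amplitude (a relative guard is unit-safe).

The speed estimate sweeps strictly increasing candidates (default
1400–1600 m/s in 1 m/s steps), beamforms at each, and maximizes the mean
coherence over an ROI; ties break to the lowest candidate, and an optional
three-point parabolic refinement of the objective is reported separately
from the grid argmax.

**ROI rule.** The default ROI is "pixels within 10 dB of that candidate's
amplitude maximum". The obvious alternative — a top-quantile rule (kept as
an option) — fails in a specific, instructive way: at far-off candidates
the beamformed image contains no focused energy at all, and its brightest
pixels sample the slowly decaying 1/t tails of the analytic signals. Those
tails are tiny but *phase-coherent across channels*, so their L1CF is high
and the sweep rewards arbitrarily wrong speeds. An amplitude threshold
anchored to the slice maximum keeps only genuine target mainlobes.

Two structural hazards of coherence autofocus on a ring are worth naming.
First, targets near the ring center are degenerate: every pair delay is
equal there, so *any* candidate speed keeps the channels aligned — the
discriminating signal comes from targets well off-center (the phantom's
groups sit ~10 mm out). Second, with a narrowband pulse the objective has
"teeth": common delay shifts of integer carrier periods re-align the
channels, spaced ~c²/(2R·f0) ≈ 3.5 m/s apart at full aperture. Aperture
dispersion suppresses the teeth, but only if the aperture is densely
sampled; rings much sparser than ~128 elements at R = 110 mm alias the
ambiguity onto wrong candidates, which is why the recovery studies run at
full scale.

## Volume and rendering

Slices stack along +z (the scan direction). Trilinear interpolation is
implemented directly from the 8-neighbor weight product (the weights form a
partition of unity, hence affine fields are reproduced exactly — both are
asserted, and the sampler is cross-checked against
`scipy.ndimage.map_coordinates(order=1)`). Size-1 axes fold the upper
neighbor back so degenerate single-slice volumes remain valid. Resampling
to isotropic voxels and ray sampling both go through this one sampler.

Ray casting is discrete front-to-back emission-absorption compositing
along axis-aligned rays, step defaulting to half the smallest voxel
spacing. Intensities are normalized to [0, 1] by the volume maximum before
the piecewise-linear opacity lookup, and the value term is the normalized
intensity itself (identity value map). Out-of-volume samples contribute
nothing. Projections: `coronal` collapses the slice axis (cylinder
cross-sections), `sagittal` the column axis, `axial` the row axis, with
max or mean reduction.

## Image-quality metrics

* **FWHM**: half-maximum crossings with linear interpolation, or a
  least-squares Gaussian fit returning 2·sigma·sqrt(2 ln 2).
* **CR** = E{|s_in|²}/E{|s_out|²}, evaluated on the envelope amplitude
  image (squared internally). **gCNR** = 1 − Σ_bins min(p_i, p_o) over 256
  shared bins spanning the pooled range; the pipeline evaluates it on
  log-compressed display values, common practice because gCNR is invariant
  to monotone maps only in the continuum limit. Both domains are logged
  and overridable.
* **Dice** 2|A∩B|/(|A|+|B|); two empty masks score 1 (identical-emptiness
  convention, so the metric is total).
* **Rayleigh judgment**: the two highest local maxima (peaks under 2% of
  the global maximum ignored as ripple); dip ratio = minimum between them
  over the lower peak; resolved iff dip ratio <= 0.735, the classical
  two-point criterion; peak positions are parabolically refined.
* **Linear accuracy**: per target, SD, CV = SD/mean·100, bias =
  mean |measured − actual|, %bias = bias/actual·100, plus unweighted
  averages. CV is *defined* as SD/mean·100; published phantom tables
  sometimes carry %SD columns that are not reproducible from the printed
  mean ± SD, and no attempt is made to mimic those.

## Problem sizes in the shipped studies

The acceptance studies and the slowest tests emulate the 512-element,
110 mm ring with a 128-element ring (same radius, frequency, and sampling).
128 elements is the sparsest configuration at which the coherence sweep's
carrier-period ambiguity stays suppressed (see above) while a full
81-candidate sweep over a 101 x 101 ROI runs in ~1.5 minutes. The speed
recovery study uses one noisy slice (SNR 20 dB) of the wire phantom and a
10 x 10 mm ROI at 0.1 mm pixels over the lateral group; the two-point
study uses noise-free pairs on a 0.025 mm line grid. Unit tests use 4–16
element rings where only arithmetic, not aperture physics, is under test.

## Known limitations

* The estimated speed is a single bulk value per slice; layered or
  per-pixel speed maps are out of scope.
* The forward model is linear and attenuation-free by default; contrast
  metrics on the breast phantom reflect that idealization.
* The coherence objective needs bright, off-center point-like structure in
  the ROI; on pure diffuse speckle its maximum is flat and seed-dependent.
* Apodization offers uniform and acceptance-angle gates only; adaptive
  (minimum-variance) weighting is out of scope.
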