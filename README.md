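# ringbeam

Synthetic-aperture reflection imaging for **ring transducer arrays** —
the acquisition geometry used by 3D breast ultrasound scanners in which a
circle of elements surrounds the immersed breast and a vertical stage steps
it through the tissue slice by slice. `ringbeam` implements the full
software chain of such a system: a point-scatterer echo simulator standing
in for the hardware front end, delay-and-sum (DAS) beamforming, sound-speed
autofocus by coherence-factor maximization, volume assembly with ray-cast
rendering, and the image-quality metrics used to assess it (FWHM, CR, gCNR,
Dice, Rayleigh two-point resolvability, linear measurement accuracy).

The package is aimed at people developing or evaluating ring-array
reconstruction algorithms who need a controlled, fully synthetic test bed
with known ground truth.

## The method

**Acquisition.** The ring (N elements, radius R, center = origin) fires one
element at a time while all N receive ("one-to-all"), giving an N x N x T
RF dataset r_{n,m}(t) per slice. The simulator models each scatterer k as

r_{n,m}(t) = Σ_k a_k · g(d_{n,k}) · g(d_{m,k}) · w_elev(z_k) · p(t − (d_{n,k}+d_{m,k})/c) + noise,

with spherical spreading g(d) = 1/max(d, d_floor), a Gaussian elevation
(slice-thickness) weight, and a five-cycle bipolar-square excitation p.

**Beamforming.** For pixel P and channel pair (n, m) the round-trip delay
maps to the fractional sample index t_idx = (d_Tx(P)+d_Rx(P))/c · fs; the
analytic (Hilbert) channel signals ŝ are linearly interpolated there and
summed, focData(P) = Σ_m Σ_n w_{m,n}(P) · ŝ_{n,m}(t_idx), and the image is
|focData|.

**Sound-speed autofocus.** Beamforming with the wrong speed c misaligns
the channel phases. The L1 coherence factor of the delay-compensated
samples s_i,

L1CF = |Σ_i s_i| / (Σ_i |s_i| + ε) ∈ [0, 1],

is ≈1 at a well-focused target and drops under phase dispersion. The bulk
speed estimate ĉ maximizes the mean L1CF over the bright-target ROI across
a 1 m/s candidate sweep (1400–1600 m/s by default).

**Volume and rendering.** Beamformed slices stack along the scan axis
(voxel (i,j,k) at X = IPP_k + i·Δr·**r** + j·Δc·**c**), are resampled to
isotropic voxels by trilinear interpolation, and rendered by front-to-back
alpha compositing (I = Σ_t T_t · α(v_t) · v_t with transmittance
T_t = Π_{s<t}(1−α(v_s))) or by axis-aligned max/mean projections.

## Worked example

Two wire targets 0.5 mm apart in a 128-element, 110 mm ring at 3 MHz
(fs = 40 MHz), beamformed at the true speed, judged by the Rayleigh dip
criterion:

```python
import numpy as np
from ringbeam import (RingArray, ScattererSet, make_grid, make_pulse,
                      simulate_rf_frame, das_beamform, rayleigh_resolved, fwhm)

array = RingArray(n_elements=128, radius=110.0,
                  center_frequency=3e6, sampling_frequency=40e6)
pulse = make_pulse(3e6, n_cycles=5, sampling_frequency=40e6)

pair = ScattererSet(np.array([[-0.25, 0.0, 0.0], [0.25, 0.0, 0.0]]), np.ones(2))
frame = simulate_rf_frame(array, pair, true_speed=1513.0, pulse=pulse)

grid = make_grid(-0.85, 0.85, 0.0, 0.0, 0.025, ring_radius=array.radius)
profile = das_beamform(frame, array, grid, speed=1513.0).amplitude[0]
resolved, distance, dip = rayleigh_resolved(profile, grid.xs)
print(f"0.5 mm pair: resolved={resolved}, peak distance={distance:.3f} mm, dip ratio={dip:.2f}")
```

prints

```
0.5 mm pair: resolved=True, peak distance=0.502 mm, dip ratio=0.18
```

i.e. the two wires produce distinct peaks 0.502 mm apart whose valley falls
to 18% of the lower peak — far below the classical Rayleigh dip of 73.5%,
so the pair is resolved. The same chain on a single wire gives a lateral
point-spread FWHM of 0.152 mm, the full-ring aperture limit at this
frequency.

A complete simulate → autofocus → beamform → volume → render → metrics run
is available from the shell:

```sh
ringbeam pipeline --out run/                 # defaults: resolution phantom, speed="auto"
ringbeam simulate --phantom breast --out scan.h5 --seed 0
ringbeam autofocus scan.h5 --candidates 1480:1560:1 --out speed.json
```

## Layout

| module | contents |
| --- | --- |
| `ringbeam.arraygeom` | ring geometry, imaging grids |
| `ringbeam.echosim` | pulses, digital phantoms, one-to-all RF simulation |
| `ringbeam.dasbeam` | DAS beamformer, apodization, log compression |
| `ringbeam.speedfocus` | L1/L2 coherence factor, candidate-sweep speed estimation |
| `ringbeam.volrender` | slice stacking, trilinear resampling, ray casting, projections |
| `ringbeam.imquality` | FWHM, CR, gCNR, Dice, Rayleigh judgment, linear accuracy |
| `ringbeam.cli_io` | config, RF container I/O (HDF5 + JSON sidecar), pipeline |
| `ringbeam.cli` | `ringbeam` console entry point |

See `docs/methods.md` for the modeling assumptions and numerical choices.
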