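"""Synthetic RF channel data for the one-to-all ring acquisition.

The simulator replaces the hardware front end: each element in turn emits a
spherical wave (single-element transmit), all N elements receive, and every
point scatterer contributes a delayed, spreading-attenuated copy of the
excitation pulse to every (tx, rx) channel pair:

    r_{n,m}(t) = sum_k  a_k * g(d_{n,k}) * g(d_{m,k}) * w_elev(z_k)
                        * p(t - (d_{n,k} + d_{m,k}) / c)  + noise

with g(d) = 1/max(d, d_floor) spherical spreading and a Gaussian elevation
(slice-thickness) weight w_elev(z) = exp(-z^2 / (2 sigma_elev^2)). The model
is single-scattering and, by default, attenuation-free.

Two digital phantoms mirror commercial test objects: a resolution phantom
with axial/lateral line groups at 4/3/2/1 mm and 3/2/1/0.5 mm spacings
(0.3 mm line diameter) plus lesion disks, and a breast-mimicking phantom with
10 mm and 6 mm cylindrical lesions and a 5 mm calcified focus in a speckle
background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.fft
import scipy.signal

from . import _kernels
from .arraygeom import RingArray

__all__ = [
    "Pulse",
    "ScattererSet",
    "RFFrame",
    "make_pulse",
    "bandlimit_pulse",
    "make_resolution_phantom",
    "make_breast_phantom",
    "simulate_rf_frame",
    "simulate_scan",
    "record_length",
]

#: Physical elevation aperture of the array, treated as the FWHM of the
#: Gaussian slice-sensitivity profile.
ELEVATION_FWHM_MM = 10.0
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
DEFAULT_SIGMA_ELEV_MM = ELEVATION_FWHM_MM / _FWHM_TO_SIGMA

#: Spherical-spreading floor: distances below this (mm) are clamped so that
#: scatterers grazing an element cannot produce unbounded amplitudes.
DEFAULT_SPREADING_FLOOR_MM = 1.0

#: Sanity window on propagation speed for soft tissue / water, m/s.
SPEED_WINDOW_M_S = (1300.0, 1700.0)

MM_PER_M = 1000.0


@dataclass(frozen=True)
class Pulse:
    """Sampled excitation pulse with unit peak amplitude."""

    center_frequency: float
    n_cycles: int
    sampling_frequency: float
    shape: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        dur = len(self.samples) / self.sampling_frequency
        nominal = self.n_cycles / self.center_frequency
        if abs(dur - nominal) > 1.0 / self.sampling_frequency + 1e-15:
            raise ValueError(
                f"pulse duration {dur:.3e} s deviates from n_cycles/f0 = "
                f"{nominal:.3e} s by more than one sample period"
            )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_frequency


def make_pulse(
    center_frequency: float,
    n_cycles: int,
    sampling_frequency: float,
    shape: str = "bipolar_square",
) -> Pulse:
    """Sample an excitation pulse of ``n_cycles`` periods at ``f0``.

    ``bipolar_square`` alternates +1/-1 every half period (the square-wave
    drive of the acquisition electronics); ``gated_sine`` is sin(2*pi*f0*t)
    over the same support. The number of samples is round(n_cycles/f0 * fs)
    and the waveform is evaluated at midpoint times (j + 1/2)/fs, which keeps
    the bipolar pulse balanced; any residual DC is removed and the peak
    renormalized to 1.
    """
    f0, fs = float(center_frequency), float(sampling_frequency)
    if fs < 2.0 * f0:
        raise ValueError(f"fs = {fs:g} Hz aliases a {f0:g} Hz pulse (fs < 2*f0)")
    if fs < 4.0 * f0:
        warnings.warn(f"fs = {fs:g} Hz is marginal for f0 = {f0:g} Hz (fs < 4*f0)")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    n = int(round(n_cycles / f0 * fs))
    t = (np.arange(n) + 0.5) / fs
    phase = t * f0  # cycles
    if shape == "bipolar_square":
        samples = np.where((phase % 1.0) < 0.5, 1.0, -1.0)
    elif shape == "gated_sine":
        samples = np.sin(2.0 * np.pi * phase)
    else:
        raise ValueError(f"unknown pulse shape {shape!r}")
    samples = samples - samples.mean()
    peak = np.abs(samples).max()
    if peak > 0:
        samples = samples / peak
    return Pulse(f0, int(n_cycles), fs, shape, samples)


def bandlimit_pulse(pulse: Pulse, fractional_bandwidth: float = 0.6, order: int = 2) -> Pulse:
    """Band-pass the pulse around f0 (zero-phase Butterworth, unit peak).

    Models the transducer's finite bandwidth acting on the square-wave drive;
    the default fractional bandwidth matches a -6 dB bandwidth >= 60% device.
    """
    if not 0 < fractional_bandwidth < 2:
        raise ValueError("fractional_bandwidth must be in (0, 2)")
    f0, fs = pulse.center_frequency, pulse.sampling_frequency
    lo = f0 * (1.0 - fractional_bandwidth / 2.0)
    hi = min(f0 * (1.0 + fractional_bandwidth / 2.0), 0.49 * fs)
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, pulse.samples)
    peak = np.abs(filtered).max()
    if peak > 0:
        filtered = filtered / peak
    return replace(pulse, samples=filtered)


@dataclass(frozen=True)
class ScattererSet:
    """3D point scatterers with non-negative reflectivities.

    ``positions`` is (S, 3) in mm; ``labels`` optionally names the phantom
    feature each scatterer belongs to.
    """

    positions: np.ndarray
    reflectivities: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        refl = np.atleast_1d(np.asarray(self.reflectivities, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, 3)
        if pos.shape[1] != 3:
            raise ValueError("positions must be (S, 3)")
        if len(refl) != len(pos):
            raise ValueError("positions and reflectivities must have equal length")
        if np.any(refl < 0):
            raise ValueError("reflectivities must be >= 0")
        if self.labels is not None and len(self.labels) != len(pos):
            raise ValueError("labels must match the number of scatterers")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "reflectivities", refl)
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.positions)

    def select(self, label: str) -> "ScattererSet":
        """Subset of scatterers carrying the given feature label."""
        if self.labels is None:
            raise ValueError("ScattererSet has no labels")
        keep = np.array([l == label for l in self.labels])
        return ScattererSet(
            self.positions[keep],
            self.reflectivities[keep],
            tuple(np.array(self.labels)[keep]),
        )

    @staticmethod
    def merge(*sets: "ScattererSet") -> "ScattererSet":
        pos = np.concatenate([s.positions for s in sets], axis=0)
        refl = np.concatenate([s.reflectivities for s in sets])
        if all(s.labels is not None for s in sets):
            labels: tuple[str, ...] | None = tuple(
                l for s in sets for l in s.labels  # type: ignore[union-attr]
            )
        else:
            labels = None
        return ScattererSet(pos, refl, labels)


@dataclass(frozen=True)
class RFFrame:
    """One slice of raw channel data r_{n,m}(t) plus acquisition metadata."""

    data: np.ndarray  # (n_tx, n_rx, n_samples) float32
    sampling_frequency: float
    array: RingArray
    true_speed: float | None = None  # m/s, known only for simulated frames
    slice_z: float = 0.0  # mm
    seed: int | None = None

    def __post_init__(self) -> None:
        d = self.data
        if d.ndim != 3 or d.shape[0] != d.shape[1]:
            raise ValueError(f"data must be (N, N, T), got {d.shape}")
        if d.shape[0] != self.array.n_elements:
            raise ValueError(
                f"data has {d.shape[0]} channels but array has "
                f"{self.array.n_elements} elements"
            )
        if not np.isfinite(d).all():
            raise ValueError("RF data contains non-finite values")
        if self.true_speed is not None:
            t_min = int(
                np.ceil(
                    2.0 * (2.0 * self.array.radius)
                    / (self.true_speed * MM_PER_M)
                    * self.sampling_frequency
                )
            )
            if d.shape[2] < t_min:
                raise ValueError(
                    f"record length {d.shape[2]} shorter than round-trip across "
                    f"the ring diameter ({t_min} samples)"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def record_length(array: RingArray, speed: float, pulse: Pulse) -> int:
    """Number of samples covering a round trip across the ring diameter.

    Padded by the pulse length and rounded up to an FFT-friendly size so the
    Hilbert transform never lands on an awkward (e.g. prime) length.
    """
    c_mm = speed * MM_PER_M
    t_min = int(np.ceil(2.0 * (2.0 * array.radius) / c_mm * array.sampling_frequency))
    return scipy.fft.next_fast_len(t_min + len(pulse.samples) + 1)


def _line_disk(rng: np.random.Generator, center_xy, n: int, diameter: float, length_z: float):
    """Scatterers jittered within a disk of the given diameter around a line center."""
    r = 0.5 * diameter * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0.0, 2.0 * np.pi, size=n)
    z = rng.uniform(-0.5 * length_z, 0.5 * length_z, size=n) if length_z > 0 else np.zeros(n)
    return np.column_stack([center_xy[0] + r * np.cos(th), center_xy[1] + r * np.sin(th), z])


def _filled_disk(rng: np.random.Generator, center_xy, n: int, diameter: float, length_z: float):
    return _line_disk(rng, center_xy, n, diameter, length_z)


# Nominal line-center layout of the resolution phantom, mm: round 0.1 mm
# coordinates. The lateral group (gaps 3, 2, 1, 0.5) sits around (0, +10);
# the axial group (gaps 4, 3, 2, 1) runs along y at x = -10; one isolated
# line sits at (10, -10).
_LATERAL_GAPS = (3.0, 2.0, 1.0, 0.5)
_AXIAL_GAPS = (4.0, 3.0, 2.0, 1.0)
LATERAL_GROUP_CENTER = (0.0, 10.0)
_LATERAL_X0 = -3.3  # first lateral wire, keeps all wires on a 0.1 mm lattice
AXIAL_GROUP_X = -10.0
_AXIAL_Y0 = -5.0
SINGLE_LINE_POS = (10.0, -10.0)


def resolution_phantom_line_centers() -> dict[str, np.ndarray]:
    """Nominal (x, y) centers of every target line, keyed by label."""
    out: dict[str, np.ndarray] = {}
    lat = _LATERAL_X0 + np.concatenate([[0.0], np.cumsum(_LATERAL_GAPS)])
    for i, x in enumerate(lat):
        out[f"lateral_{i + 1}"] = np.array([LATERAL_GROUP_CENTER[0] + x, LATERAL_GROUP_CENTER[1]])
    ax = _AXIAL_Y0 + np.concatenate([[0.0], np.cumsum(_AXIAL_GAPS)])
    for i, y in enumerate(ax):
        out[f"axial_{i + 1}"] = np.array([AXIAL_GROUP_X, y])
    out["single"] = np.array(SINGLE_LINE_POS)
    return out


def make_resolution_phantom(
    line_diameter: float = 0.3,
    scatterers_per_line: int = 1,
    seed: int | None = None,
    line_length: float = 0.0,
    include_lesions: bool = False,
    lesion_scatterers: int = 150,
) -> ScattererSet:
    """Digital twin of a wire/line resolution phantom.

    Five axial lines at cumulative 4/3/2/1 mm gaps, five lateral lines at
    3/2/1/0.5 mm gaps, and one isolated line. With the default
    ``scatterers_per_line=1`` each wire is modeled as a single specular
    reflector at its nominal axis position: a sub-wavelength solid wire
    scatters coherently, so its phase center is the axis, not a random
    point in its cross-section. With ``scatterers_per_line > 1`` the wire's
    physical extent is modeled by points uniformly jittered within a disk of
    ``line_diameter`` (0.3 mm nominal); note that a sparse random cloud adds
    speckle-like phase noise a solid wire does not have. ``line_length``
    spreads scatterers along z (0 keeps them in the slice plane). Optional
    lesion disks: one 7 mm cyst-like (hypoechoic), two 10 mm tumor-like
    (hyperechoic) and one 10 mm stone-like (strongly reflective) target.
    """
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    refls: list[np.ndarray] = []
    labels: list[str] = []
    for label, center in resolution_phantom_line_centers().items():
        if scatterers_per_line == 1:
            pts = np.array([[center[0], center[1], 0.0]])
        else:
            pts = _line_disk(rng, center, scatterers_per_line, line_diameter, line_length)
        chunks.append(pts)
        refls.append(np.full(len(pts), 1.0))
        labels.extend([label] * len(pts))
    if include_lesions:
        lesions = [
            ("cyst_7mm", (15.0, 15.0), 7.0, 0.15),
            ("tumor_10mm_a", (-15.0, 15.0), 10.0, 2.0),
            ("tumor_10mm_b", (-15.0, -15.0), 10.0, 2.0),
            ("stone_10mm", (15.0, -15.0), 10.0, 4.0),
        ]
        for label, center, diam, refl in lesions:
            pts = _filled_disk(rng, center, lesion_scatterers, diam, line_length)
            chunks.append(pts)
            refls.append(np.full(len(pts), refl))
            labels.extend([label] * len(pts))
    return ScattererSet(np.concatenate(chunks), np.concatenate(refls), tuple(labels))


def make_breast_phantom(
    seed: int | None = None,
    n_background: int = 2000,
    background_radius: float = 40.0,
    height: float = 30.0,
    background_reflectivity: float = 0.3,
) -> ScattererSet:
    """Digital twin of a breast-tissue-mimicking phantom.

    A 10 mm hyperechoic tumor-like cylinder, a 6 mm anechoic cyst-like
    cylinder (visible through its rim), and a 5 mm strongly reflective
    calcified focus, embedded in a uniform speckle background; all cylinder
    axes run along z over ``height`` mm.
    """
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    refls: list[np.ndarray] = []
    labels: list[str] = []

    tumor_c, tumor_d = (-18.0, 0.0), 10.0
    cyst_c, cyst_d = (15.0, 8.0), 6.0
    calc_c, calc_d = (0.0, -18.0), 5.0

    if n_background > 0:
        r = background_radius * np.sqrt(rng.uniform(size=n_background))
        th = rng.uniform(0, 2 * np.pi, size=n_background)
        z = rng.uniform(0.0, height, size=n_background)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), z])
        # carve out the anechoic cyst interior
        keep = np.hypot(pts[:, 0] - cyst_c[0], pts[:, 1] - cyst_c[1]) > cyst_d / 2.0
        pts = pts[keep]
        chunks.append(pts)
        refls.append(background_reflectivity * rng.rayleigh(1.0, size=len(pts)))
        labels.extend(["background"] * len(pts))

    n_tumor = 300
    pts = _filled_disk(rng, tumor_c, n_tumor, tumor_d, height)
    pts[:, 2] += height / 2.0
    chunks.append(pts)
    refls.append(np.full(n_tumor, 2.5))
    labels.extend(["tumor_10mm"] * n_tumor)

    n_rim = 150
    th = rng.uniform(0, 2 * np.pi, size=n_rim)
    z = rng.uniform(0.0, height, size=n_rim)
    pts = np.column_stack(
        [cyst_c[0] + cyst_d / 2.0 * np.cos(th), cyst_c[1] + cyst_d / 2.0 * np.sin(th), z]
    )
    chunks.append(pts)
    refls.append(np.full(n_rim, 1.5))
    labels.extend(["cyst_6mm"] * n_rim)

    n_calc = 80
    pts = _filled_disk(rng, calc_c, n_calc, calc_d, height)
    pts[:, 2] += height / 2.0
    chunks.append(pts)
    refls.append(np.full(n_calc, 6.0))
    labels.extend(["calcification_5mm"] * n_calc)

    return ScattererSet(np.concatenate(chunks), np.concatenate(refls), tuple(labels))


def simulate_rf_frame(
    array: RingArray,
    scatterers: ScattererSet,
    true_speed: float,
    pulse: Pulse,
    noise_snr_db: float | None = None,
    seed: int | None = None,
    slice_z: float = 0.0,
    sigma_elev: float = DEFAULT_SIGMA_ELEV_MM,
    d_floor: float = DEFAULT_SPREADING_FLOOR_MM,
    attenuation_db_per_mm: float = 0.0,
    n_samples: int | None = None,
) -> RFFrame:
    """Simulate one one-to-all frame: every element transmits, all receive.

    ``slice_z`` is the z-position of the imaging plane; scatterer depths enter
    both the 3D propagation distance and the Gaussian elevation weight through
    z' = z - slice_z. Additive white Gaussian noise at ``noise_snr_db``
    (relative to the RMS of the noise-free frame) is applied when requested.
    """
    if not SPEED_WINDOW_M_S[0] < true_speed < SPEED_WINDOW_M_S[1]:
        raise ValueError(
            f"true_speed {true_speed} m/s outside sanity window {SPEED_WINDOW_M_S}"
        )
    if pulse.sampling_frequency != array.sampling_frequency:
        raise ValueError("pulse and array sampling frequencies disagree")
    pos = scatterers.positions
    if len(pos):
        in_plane = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(in_plane >= array.radius):
            bad = int(np.argmax(in_plane))
            raise ValueError(
                f"scatterer {bad} at in-plane radius {in_plane[bad]:.2f} mm lies "
                f"outside the ring (radius {array.radius} mm)"
            )

    fs = array.sampling_frequency
    c_mm = true_speed * MM_PER_M
    T = int(n_samples) if n_samples is not None else record_length(array, true_speed, pulse)
    out = np.zeros((array.n_elements, array.n_elements, T), dtype=np.float32)

    if len(pos):
        elem = array.element_positions  # (N, 2)
        dz = pos[:, 2] - slice_z
        dx = pos[:, 0][:, None] - elem[:, 0][None, :]
        dy = pos[:, 1][:, None] - elem[:, 1][None, :]
        dist = np.sqrt(dx * dx + dy * dy + dz[:, None] ** 2)  # (S, N) mm
        gain = 1.0 / np.maximum(dist, d_floor)
        if attenuation_db_per_mm > 0:
            gain = gain * 10.0 ** (-attenuation_db_per_mm * dist / 20.0)
        amp = scatterers.reflectivities * np.exp(-(dz**2) / (2.0 * sigma_elev**2))
        pulse_padded = np.concatenate([pulse.samples, [0.0]]).astype(np.float32)
        _kernels.add_echoes(
            out,
            dist.astype(np.float32),
            gain.astype(np.float32),
            amp.astype(np.float32),
            np.float64(fs / c_mm),
            pulse_padded,
        )

    if noise_snr_db is not None:
        rng = np.random.default_rng(seed)
        rms = float(np.sqrt(np.mean(out.astype(np.float64) ** 2)))
        sigma = np.float32(rms / 10.0 ** (noise_snr_db / 20.0)) if rms > 0 else np.float32(0.0)
        if sigma > 0:
            for n in range(out.shape[0]):  # per-tx to bound temporary memory
                out[n] += sigma * rng.standard_normal(out.shape[1:], dtype=np.float32)

    return RFFrame(out, fs, array, float(true_speed), float(slice_z), seed)


def simulate_scan(
    array: RingArray,
    scatterers: ScattererSet,
    z_start: float,
    dz: float,
    n_slices: int,
    true_speed: float,
    pulse: Pulse,
    noise_snr_db: float | None = None,
    seed: int | None = None,
    **kwargs,
) -> list[RFFrame]:
    """Step the imaging plane along z: slice k is acquired at z_start + k*dz.

    Per-slice noise seeds are seed + k so a one-slice scan is bit-identical to
    :func:`simulate_rf_frame` at z_start.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if dz <= 0:
        raise ValueError(f"dz must be positive, got {dz}")
    frames = []
    for k in range(n_slices):
        frames.append(
            simulate_rf_frame(
                array,
                scatterers,
                true_speed,
                pulse,
                noise_snr_db=noise_snr_db,
                seed=None if seed is None else seed + k,
                slice_z=z_start + k * dz,
                **kwargs,
            )
        )
    return frames
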