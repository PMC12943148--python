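"""Synthetic-aperture delay-and-sum beamforming on the ring geometry.

For every pixel P of the imaging grid and every (tx n, rx m) channel pair the
round-trip propagation delay is converted to a fractional sample index

    t_idx = (d_Tx(P) + d_Rx(P)) / c * fs,

the analytic (Hilbert-transformed) channel signal is linearly interpolated at
that index, weighted by the apodization scheme, and summed:

    focData(x, y) = sum_m sum_n w_{m,n}(x, y) * s_{n,m}(t_idx).

The amplitude image is |focData|. Complex (analytic-signal) beamforming is
used so that the envelope is well defined and channel coherence (see
``speedfocus``) is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from . import _kernels
from .arraygeom import ImagingGrid, RingArray
from .echosim import MM_PER_M, RFFrame

__all__ = [
    "ApodizationScheme",
    "BeamformedImage",
    "propagation_distances",
    "delay_sample_index",
    "apodization_weight",
    "das_beamform",
    "log_compress",
    "analytic_signal",
    "element_pixel_distances",
    "element_pixel_weights",
]


@dataclass(frozen=True)
class ApodizationScheme:
    """Per-channel weighting of the beamforming sum.

    ``uniform`` weights every channel 1. ``acceptance_angle`` keeps a channel
    only if the angle between each element's inward normal and the
    element-to-pixel direction stays within ``acceptance_half_angle`` for both
    the transmitter and the receiver; with the default half angle of pi/2 this
    excludes geometrically impossible paths for points outside the ring while
    keeping every interior point fully weighted.
    """

    kind: str = "acceptance_angle"
    acceptance_half_angle: float = np.pi / 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "acceptance_angle"):
            raise ValueError(f"unknown apodization kind {self.kind!r}")
        if not 0.0 < self.acceptance_half_angle <= np.pi:
            raise ValueError("acceptance_half_angle must be in (0, pi]")


@dataclass(frozen=True)
class BeamformedImage:
    """Complex beamformed slice plus bookkeeping for normalization audits."""

    complex_image: np.ndarray  # (rows, cols) complex
    grid: ImagingGrid
    speed: float  # m/s used for the delays
    weight_sum: np.ndarray  # (rows, cols) sum of channel weights per pixel

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.complex_image)


def propagation_distances(point, tx_pos, rx_pos) -> tuple[float, float]:
    """Distances (mm) from imaging point (x, y[, z]) to the tx and rx elements."""
    p = np.asarray(point, dtype=float)
    z = p[2] if p.shape[-1] == 3 else 0.0
    tx = np.asarray(tx_pos, dtype=float)
    rx = np.asarray(rx_pos, dtype=float)
    d_tx = float(np.sqrt((p[0] - tx[0]) ** 2 + (p[1] - tx[1]) ** 2 + z**2))
    d_rx = float(np.sqrt((p[0] - rx[0]) ** 2 + (p[1] - rx[1]) ** 2 + z**2))
    return d_tx, d_rx


def delay_sample_index(d_tx: float, d_rx: float, speed: float, fs: float) -> float:
    """Fractional sample index of the round-trip delay (no rounding).

    Distances in mm, speed in m/s, fs in Hz.
    """
    if speed <= 0:
        raise ValueError(f"speed must be positive, got {speed}")
    return (d_tx + d_rx) / (speed * MM_PER_M) * fs


def apodization_weight(point, tx_pos, rx_pos, scheme: ApodizationScheme) -> float:
    """Weight of a single (tx, rx) channel at one imaging point, in [0, 1]."""
    if scheme.kind == "uniform":
        return 1.0
    w_tx = _element_sees(point, tx_pos, scheme.acceptance_half_angle)
    w_rx = _element_sees(point, rx_pos, scheme.acceptance_half_angle)
    return float(w_tx * w_rx)


def _element_sees(point, elem_pos, half_angle: float) -> float:
    p = np.asarray(point, dtype=float)
    e = np.asarray(elem_pos, dtype=float)
    z = p[2] if p.shape[-1] == 3 else 0.0
    d = np.array([p[0] - e[0], p[1] - e[1], z])
    norm = np.linalg.norm(d)
    if norm == 0:
        return 1.0
    inward = np.array([-e[0], -e[1], 0.0])
    inward /= np.linalg.norm(inward)
    cos = float(np.dot(d / norm, inward))
    return 1.0 if cos >= np.cos(half_angle) - 1e-12 else 0.0


def element_pixel_distances(array: RingArray, grid: ImagingGrid) -> np.ndarray:
    """Element-to-pixel distances (N, P) in mm, P row-major over the grid."""
    elem = array.element_positions
    px = grid.pixel_centers()
    dx = elem[:, 0][:, None] - px[:, 0][None, :]
    dy = elem[:, 1][:, None] - px[:, 1][None, :]
    return np.sqrt(dx * dx + dy * dy + grid.depth_z**2)


def element_pixel_weights(
    array: RingArray, grid: ImagingGrid, scheme: ApodizationScheme
) -> np.ndarray:
    """Per-element apodization weight at every pixel, (N, P) float32.

    The channel weight w_{m,n} used by the beamformer is the product of the
    tx and rx element weights.
    """
    px = grid.pixel_centers()
    P = len(px)
    N = array.n_elements
    if scheme.kind == "uniform":
        return np.ones((N, P))
    elem = array.element_positions
    dx = px[:, 0][None, :] - elem[:, 0][:, None]
    dy = px[:, 1][None, :] - elem[:, 1][:, None]
    dz = grid.depth_z
    norm = np.sqrt(dx * dx + dy * dy + dz**2)
    inward = -elem / np.linalg.norm(elem, axis=1, keepdims=True)  # (N, 2)
    cos = inward[:, 0][:, None] * dx + inward[:, 1][:, None] * dy
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(norm > 0, cos / norm, 1.0)
    return (cos >= np.cos(scheme.acceptance_half_angle) - 1e-12).astype(float)


def analytic_signal(frame: RFFrame) -> np.ndarray:
    """Complex analytic channel signals via the Hilbert transform, complex64.

    Computed per transmit row to keep the FFT workspace small.
    """
    data = frame.data
    N, _, T = data.shape
    out = np.empty((N, N, T), dtype=np.complex64)
    for n in range(N):
        out[n] = scipy.signal.hilbert(data[n].astype(np.float64), axis=-1)
    return out


def das_beamform(
    rf: RFFrame,
    array: RingArray,
    grid: ImagingGrid,
    speed: float,
    apod: ApodizationScheme | None = None,
    normalize: bool = False,
    analytic: np.ndarray | None = None,
) -> BeamformedImage:
    """Delay-and-sum beamform one frame onto the grid at the given speed (m/s).

    ``analytic`` may carry a precomputed analytic-signal cube (as returned by
    :func:`analytic_signal`) to amortize the Hilbert transform across repeated
    calls, e.g. during a sound-speed sweep. ``normalize`` divides each pixel
    by its channel-weight sum (off by default: the beamforming sum is a plain
    weighted sum).
    """
    if apod is None:
        apod = ApodizationScheme()
    if rf.array.n_elements != array.n_elements:
        raise ValueError(
            f"RF frame has {rf.array.n_elements} elements, array has {array.n_elements}"
        )
    if speed <= 0:
        raise ValueError(f"speed must be positive, got {speed}")
    if analytic is None:
        analytic = analytic_signal(rf)
    dist = element_pixel_distances(array, grid)
    weights = element_pixel_weights(array, grid, apod)
    scale = rf.sampling_frequency / (speed * MM_PER_M)
    sum_re, sum_im, _, _, w_sum = _kernels.das_accumulate(
        analytic, dist, weights, np.float64(scale), False
    )
    img = (sum_re + 1j * sum_im).reshape(grid.shape)
    wsum = w_sum.reshape(grid.shape)
    if normalize:
        with np.errstate(invalid="ignore", divide="ignore"):
            img = np.where(wsum > 0, img / wsum, 0.0)
    return BeamformedImage(img, grid, float(speed), wsum)


def log_compress(amplitude: np.ndarray, dynamic_range_db: float = 60.0) -> np.ndarray:
    """Map an amplitude image to display values in [0, 1].

    20*log10(A / max A), clipped to [-DR, 0] and affinely mapped to [0, 1];
    an all-zero image maps to all zeros.
    """
    if dynamic_range_db <= 0:
        raise ValueError("dynamic_range_db must be positive")
    amp = np.asarray(amplitude, dtype=float)
    peak = amp.max() if amp.size else 0.0
    if peak == 0:
        return np.zeros_like(amp)
    floor = peak * 10.0 ** (-(dynamic_range_db + 20.0) / 20.0)  # below the clip already
    db = 20.0 * np.log10(np.maximum(amp, floor) / peak)
    db = np.clip(db, -dynamic_range_db, 0.0)
    return (db + dynamic_range_db) / dynamic_range_db
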