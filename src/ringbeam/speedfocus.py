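"""Coherence-factor sound-speed autofocus.

Biological tissue rarely propagates sound at the conventional 1540 m/s
assumption; beamforming with a mismatched speed misaligns the channel delays
and defocuses the image. The coherence factor measures how well the
delay-compensated channel samples s_i agree in phase at a point. The L1 form

    L1CF = |sum_i s_i| / (sum_i |s_i| + eps)

is 1 when all channels align perfectly and falls toward 0 under phase
dispersion; the conventional L2 form |sum s|^2 / (N * sum |s|^2 + eps) is
available as a variant. The bulk speed is estimated by sweeping candidate
speeds, beamforming at each, and selecting the candidate that maximizes the
mean coherence over a region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .arraygeom import ImagingGrid, RingArray
from .dasbeam import (
    ApodizationScheme,
    analytic_signal,
    element_pixel_distances,
    element_pixel_weights,
)
from .echosim import MM_PER_M, RFFrame

__all__ = ["SpeedEstimate", "l1cf", "coherence_map", "estimate_optimal_speed"]

#: Relative epsilon guarding the coherence denominator, scaled by the maximum
#: channel amplitude of the frame (unit-safe).
DEFAULT_EPSILON_REL = 1e-12


@dataclass(frozen=True)
class SpeedEstimate:
    """Result of a candidate-speed coherence sweep."""

    candidates: np.ndarray  # m/s, strictly increasing
    objectives: np.ndarray  # mean ROI coherence per candidate, in [0, 1]
    speed: float  # selected candidate (argmax; ties -> lowest)
    roi_description: str
    epsilon: float
    variant: str = "l1"
    refined_speed: float | None = None  # parabolic refinement, if requested

    def __post_init__(self) -> None:
        c = np.asarray(self.candidates, dtype=float)
        obj = np.asarray(self.objectives, dtype=float)
        if len(c) != len(obj):
            raise ValueError("candidates and objectives must have equal length")
        if self.speed not in c:
            raise ValueError("selected speed must be one of the candidates")
        if np.any(obj < 0) or np.any(obj > 1):
            raise ValueError("objective values must lie in [0, 1]")
        object.__setattr__(self, "candidates", c)
        object.__setattr__(self, "objectives", obj)


def l1cf(samples, epsilon: float) -> float:
    """L1 coherence factor |sum s| / (sum |s| + eps) of delay-compensated samples."""
    s = np.asarray(samples)
    if s.size == 0:
        raise ValueError("l1cf requires at least one sample")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return float(np.abs(s.sum()) / (np.abs(s).sum() + epsilon))


def _cf_from_sums(sum_re, sum_im, abs_sum, sq_sum, w_sum, epsilon, variant):
    mag = np.hypot(sum_re, sum_im)
    if variant == "l1":
        return mag / (abs_sum + epsilon)
    if variant == "l2":
        return mag**2 / (np.maximum(w_sum, 1.0) * sq_sum + epsilon)
    raise ValueError(f"unknown coherence variant {variant!r}")


def _sweep_one(analytic, dist, weights, fs, speed, epsilon, variant, shape):
    scale = fs / (speed * MM_PER_M)
    sum_re, sum_im, abs_sum, sq_sum, w_sum = _kernels.das_accumulate(
        analytic, dist, weights, np.float64(scale), True
    )
    amp = np.hypot(sum_re, sum_im).reshape(shape)
    cf = _cf_from_sums(sum_re, sum_im, abs_sum, sq_sum, w_sum, epsilon, variant).reshape(shape)
    return amp, np.clip(cf, 0.0, 1.0)


def _default_epsilon(analytic) -> float:
    peak = float(np.abs(analytic).max()) if analytic.size else 0.0
    return DEFAULT_EPSILON_REL * peak if peak > 0 else 1e-30


def coherence_map(
    rf: RFFrame,
    array: RingArray,
    grid: ImagingGrid,
    speed: float,
    apod: ApodizationScheme | None = None,
    epsilon: float | None = None,
    variant: str = "l1",
    analytic: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel coherence of the delay-compensated channels, in [0, 1].

    The sample set at each pixel is every (tx, rx) channel with nonzero
    apodization weight, interpolated at its round-trip delay index.
    """
    if apod is None:
        apod = ApodizationScheme()
    if rf.array.n_elements != array.n_elements:
        raise ValueError("RF frame and array element counts disagree")
    if analytic is None:
        analytic = analytic_signal(rf)
    if epsilon is None:
        epsilon = _default_epsilon(analytic)
    dist = element_pixel_distances(array, grid)
    weights = element_pixel_weights(array, grid, apod)
    _, cf = _sweep_one(
        analytic, dist, weights, rf.sampling_frequency, speed, epsilon, variant, grid.shape
    )
    return cf


def estimate_optimal_speed(
    rf: RFFrame,
    array: RingArray,
    grid: ImagingGrid,
    candidates,
    roi_mask: np.ndarray | None = None,
    roi_rule: str = "threshold_db",
    roi_db: float = 10.0,
    roi_fraction: float = 0.01,
    apod: ApodizationScheme | None = None,
    epsilon: float | None = None,
    variant: str = "l1",
    aggregate: str = "mean",
    refine: bool = False,
) -> SpeedEstimate:
    """Sweep candidate speeds and pick the one maximizing ROI coherence.

    The objective at each candidate is the mean coherence over the ROI. With
    no explicit ``roi_mask`` the ROI is re-derived per candidate from that
    candidate's beamformed amplitude: rule ``threshold_db`` (default) keeps
    pixels within ``roi_db`` of the slice maximum — i.e. the bright targets —
    while ``top_fraction`` keeps the top ``roi_fraction`` quantile. The
    amplitude restriction matters: dim pixels sample the slowly decaying
    tails of the analytic signals, which are phase-coherent across channels
    and would otherwise reward arbitrarily wrong speeds.
    ``aggregate='amplitude_weighted'`` weights the ROI mean by pixel
    amplitude. ``refine`` adds a three-point parabolic interpolation around
    the grid argmax, reported separately.
    """
    cand = np.asarray(candidates, dtype=float)
    if cand.ndim != 1 or len(cand) < 1:
        raise ValueError("candidates must be a non-empty 1D sequence")
    if np.any(np.diff(cand) <= 0):
        raise ValueError("candidates must be strictly increasing")
    if apod is None:
        apod = ApodizationScheme()
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != grid.shape:
            raise ValueError("roi_mask shape must match the grid")
        if not roi_mask.any():
            raise ValueError(
                "empty ROI mask; supply a non-empty mask or use the amplitude rule"
            )

    analytic = analytic_signal(rf)
    if epsilon is None:
        epsilon = _default_epsilon(analytic)
    dist = element_pixel_distances(array, grid)
    weights = element_pixel_weights(array, grid, apod)
    fs = rf.sampling_frequency

    objectives = np.empty(len(cand))
    for i, c in enumerate(cand):
        amp, cf = _sweep_one(analytic, dist, weights, fs, c, epsilon, variant, grid.shape)
        if roi_mask is not None:
            mask = roi_mask
        else:
            if roi_rule == "threshold_db":
                mask = amp >= amp.max() * 10.0 ** (-roi_db / 20.0)
            elif roi_rule == "top_fraction":
                mask = amp >= np.quantile(amp, 1.0 - roi_fraction)
            else:
                raise ValueError(f"unknown roi_rule {roi_rule!r}")
            if not mask.any():  # pathological flat slice
                raise ValueError(
                    "amplitude ROI rule selected no pixels; loosen the rule "
                    "or pass an explicit roi_mask"
                )
        if aggregate == "mean":
            objectives[i] = float(cf[mask].mean())
        elif aggregate == "amplitude_weighted":
            w = amp[mask]
            objectives[i] = float((cf[mask] * w).sum() / (w.sum() + epsilon))
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")

    best = int(np.argmax(objectives))  # first max -> lowest speed on ties
    refined = None
    if refine and 0 < best < len(cand) - 1:
        y0, y1, y2 = objectives[best - 1 : best + 2]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            refined = float(cand[best] + delta * (cand[best + 1] - cand[best]))

    if roi_mask is not None:
        roi_desc = "explicit mask"
    elif roi_rule == "threshold_db":
        roi_desc = f"pixels within {roi_db:g} dB of the slice maximum, per candidate"
    else:
        roi_desc = f"top {roi_fraction * 100:g}% amplitude pixels per candidate"
    return SpeedEstimate(
        candidates=cand,
        objectives=objectives,
        speed=float(cand[best]),
        roi_description=roi_desc,
        epsilon=float(epsilon),
        variant=variant,
        refined_speed=refined,
    )
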