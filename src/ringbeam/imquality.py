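"""Image-quality assessment: PSF width, contrast, distribution overlap,
segmentation agreement, two-point resolvability, and linear measurement
accuracy.

Conventions
-----------
* FWHM of a Gaussian point-spread profile is 2*sigma*sqrt(2 ln 2).
* Contrast ratio CR = E{|s_in|^2} / E{|s_out|^2} is computed on the envelope
  amplitude image (squared internally).
* gCNR = 1 - OVL, where OVL is the overlap of the target/background intensity
  histograms over shared bin edges; commonly evaluated on log-compressed
  display values.
* Two points are called resolved (Rayleigh sense) when the intensity dip
  between their peaks falls to at most ``dip_threshold`` of the lower peak;
  the default 0.735 is the classical two-point criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.signal

__all__ = [
    "RegionMask",
    "ResolutionReport",
    "LinearAccuracyReport",
    "fwhm",
    "contrast_ratio",
    "gcnr",
    "dice",
    "rayleigh_resolved",
    "two_point_resolution",
    "linear_accuracy",
]

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))
DEFAULT_DIP_THRESHOLD = 0.735


@dataclass(frozen=True)
class RegionMask:
    """Boolean mask congruent with the image it annotates."""

    mask: np.ndarray
    role: str = "target"  # "target" | "background"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.role not in ("target", "background"):
            raise ValueError(f"role must be 'target' or 'background', got {self.role!r}")


def _as_mask(m) -> np.ndarray:
    if isinstance(m, RegionMask):
        return m.mask
    return np.asarray(m, dtype=bool)


def fwhm(profile, coords, method: str = "halfmax") -> float:
    """Full width at half maximum of a single-peaked 1D profile, in coord units.

    ``halfmax`` linearly interpolates the two half-maximum crossings around
    the global peak; ``gaussian`` least-squares fits a Gaussian and returns
    2*sigma*sqrt(2 ln 2).
    """
    y = np.asarray(profile, dtype=float)
    x = np.asarray(coords, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("profile and coords must be equal-length 1D arrays")
    ipk = int(np.argmax(y))
    if ipk == 0 or ipk == len(y) - 1:
        raise ValueError("profile maximum lies at an endpoint")
    if method == "gaussian":
        a0 = y[ipk] - y.min()
        sigma0 = max((x.max() - x.min()) / 10.0, np.finfo(float).eps)

        def model(xx, a, mu, sigma, off):
            return a * np.exp(-((xx - mu) ** 2) / (2.0 * sigma**2)) + off

        popt, _ = scipy.optimize.curve_fit(
            model, x, y, p0=[a0, x[ipk], sigma0, y.min()], maxfev=20000
        )
        return float(abs(popt[2]) * GAUSSIAN_FWHM_FACTOR)
    if method != "halfmax":
        raise ValueError(f"method must be 'halfmax' or 'gaussian', got {method!r}")

    half = y[ipk] / 2.0

    def crossing(idx_range, direction):
        prev = ipk
        for i in idx_range:
            if y[i] <= half:
                # linear interpolation between i and the sample nearer the peak
                x0, x1 = x[i], x[prev]
                y0, y1 = y[i], y[prev]
                if y1 == y0:
                    return x0
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = i
        raise ValueError(f"no half-maximum crossing on the {direction} side of the peak")

    left = crossing(range(ipk - 1, -1, -1), "left")
    right = crossing(range(ipk + 1, len(y)), "right")
    return float(abs(right - left))


def contrast_ratio(image, target, background) -> float:
    """CR = mean |s|^2 over the target / mean |s|^2 over the background."""
    img = np.asarray(image, dtype=float)
    t, b = _as_mask(target), _as_mask(background)
    if t.shape != img.shape or b.shape != img.shape:
        raise ValueError("masks must match the image shape")
    if not t.any() or not b.any():
        raise ValueError("target and background masks must be non-empty")
    mu_o = float(np.mean(img[b] ** 2))
    if mu_o == 0:
        raise ValueError("background mean intensity is zero")
    return float(np.mean(img[t] ** 2) / mu_o)


def gcnr(image, target, background, n_bins: int = 256) -> float:
    """Generalized contrast-to-noise ratio: 1 minus the histogram overlap.

    Normalized histograms of the two regions share bin edges spanning the
    pooled intensity range; OVL = sum_bins min(p_i, p_o) and gCNR = 1 - OVL.
    """
    img = np.asarray(image, dtype=float)
    t, b = _as_mask(target), _as_mask(background)
    if not t.any() or not b.any():
        raise ValueError("target and background masks must be non-empty")
    vals_t, vals_b = img[t], img[b]
    lo = min(vals_t.min(), vals_b.min())
    hi = max(vals_t.max(), vals_b.max())
    if lo == hi:  # degenerate: both regions a single shared value
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p_t, _ = np.histogram(vals_t, bins=edges)
    p_b, _ = np.histogram(vals_b, bins=edges)
    ovl = np.minimum(p_t / p_t.sum(), p_b / p_b.sum()).sum()
    return float(1.0 - ovl)


def dice(mask_a, mask_b) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|); two empty masks count as 1."""
    a, b = _as_mask(mask_a), _as_mask(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes disagree: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0  # identical-emptiness convention
    return float(2.0 * np.logical_and(a, b).sum() / (na + nb))


def _parabolic_peak(y, i):
    """Sub-sample peak location by a 3-point parabola around index i."""
    if i == 0 or i == len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (y[i - 1] - y[i + 1]) / denom)


def rayleigh_resolved(
    profile,
    coords,
    dip_threshold: float = DEFAULT_DIP_THRESHOLD,
    min_prominence_frac: float = 0.02,
) -> tuple[bool, float | None, float | None]:
    """Two-point resolvability of a 1D intensity profile.

    Locates the two highest local maxima (peaks below
    ``min_prominence_frac`` of the global maximum are ignored as ripple);
    the dip ratio is the minimum between them divided by the lower peak.
    Returns (resolved, peak_distance, dip_ratio); distance uses sub-sample
    parabolic refinement and is None when fewer than two peaks exist.
    """
    y = np.asarray(profile, dtype=float)
    x = np.asarray(coords, dtype=float)
    if y.ndim != 1 or y.shape != x.shape:
        raise ValueError("profile and coords must be equal-length 1D arrays")
    if y.size < 3 or y.max() <= 0 or np.ptp(y) == 0:
        return False, None, None
    peaks, props = scipy.signal.find_peaks(y, prominence=min_prominence_frac * y.max())
    if len(peaks) < 2:
        return False, None, None
    top2 = peaks[np.argsort(y[peaks])[-2:]]
    i_lo, i_hi = int(top2.min()), int(top2.max())
    dip = float(y[i_lo : i_hi + 1].min())
    lower_peak = float(min(y[i_lo], y[i_hi]))
    dip_ratio = dip / lower_peak if lower_peak > 0 else 1.0
    pos_lo = np.interp(_parabolic_peak(y, i_lo), np.arange(len(x)), x)
    pos_hi = np.interp(_parabolic_peak(y, i_hi), np.arange(len(x)), x)
    distance = float(abs(pos_hi - pos_lo))
    return bool(dip_ratio <= dip_threshold), distance, float(dip_ratio)


@dataclass(frozen=True)
class ResolutionReport:
    """Per-separation two-point resolvability summary."""

    separations: tuple[float, ...]  # mm, as tested
    resolved: tuple[bool, ...]
    peak_distances: tuple[float | None, ...]  # mm
    dip_ratios: tuple[float | None, ...]
    smallest_resolved: float | None  # mm

    def __post_init__(self) -> None:
        order = np.argsort(self.separations)
        res = np.asarray(self.resolved)[order]
        # once a separation resolves, every larger one should too
        if np.any(np.diff(res.astype(int)) < 0):
            warnings.warn("resolved flags are not monotone in separation")


def two_point_resolution(
    separations,
    profiles,
    coords_list,
    dip_threshold: float = DEFAULT_DIP_THRESHOLD,
) -> ResolutionReport:
    """Apply the Rayleigh dip criterion to one profile per tested separation."""
    seps = tuple(float(s) for s in separations)
    if not (len(seps) == len(profiles) == len(coords_list)):
        raise ValueError("separations, profiles and coords_list must align")
    flags, dists, dips = [], [], []
    for prof, coords in zip(profiles, coords_list):
        ok, d, dip = rayleigh_resolved(prof, coords, dip_threshold)
        flags.append(ok)
        dists.append(d)
        dips.append(dip)
    resolved_seps = [s for s, ok in zip(seps, flags) if ok]
    return ResolutionReport(
        separations=seps,
        resolved=tuple(flags),
        peak_distances=tuple(dists),
        dip_ratios=tuple(dips),
        smallest_resolved=min(resolved_seps) if resolved_seps else None,
    )


@dataclass(frozen=True)
class TargetAccuracy:
    actual: float  # mm
    measurements: tuple[float, ...]  # mm
    mean: float
    sd: float
    cv_percent: float  # SD / mean * 100
    bias: float  # mean |measured - actual|, mm
    bias_percent: float  # bias / actual * 100


@dataclass(frozen=True)
class LinearAccuracyReport:
    """Distance-measurement accuracy across calibration targets."""

    targets: tuple[TargetAccuracy, ...]
    mean_cv_percent: float
    mean_bias: float
    mean_bias_percent: float


def linear_accuracy(measurements_per_target, actuals) -> LinearAccuracyReport:
    """Per-target SD, CV, bias and %bias, plus unweighted averages.

    Bias is the mean absolute deviation of the measurements from the known
    target length; %bias expresses it as a percentage of that length.
    """
    if len(measurements_per_target) != len(actuals):
        raise ValueError("one measurement list per actual value required")
    rows = []
    for meas, actual in zip(measurements_per_target, actuals):
        if actual <= 0:
            raise ValueError(f"actual length must be positive, got {actual}")
        m = np.asarray(meas, dtype=float)
        if m.size < 1:
            raise ValueError("each target needs at least one measurement")
        mean = float(m.mean())
        sd = float(m.std(ddof=1)) if m.size > 1 else 0.0
        bias = float(np.abs(m - actual).mean())
        rows.append(
            TargetAccuracy(
                actual=float(actual),
                measurements=tuple(m),
                mean=mean,
                sd=sd,
                cv_percent=sd / mean * 100.0 if mean != 0 else np.inf,
                bias=bias,
                bias_percent=bias / actual * 100.0,
            )
        )
    return LinearAccuracyReport(
        targets=tuple(rows),
        mean_cv_percent=float(np.mean([r.cv_percent for r in rows])),
        mean_bias=float(np.mean([r.bias for r in rows])),
        mean_bias_percent=float(np.mean([r.bias_percent for r in rows])),
    )
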