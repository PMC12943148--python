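"""Numba inner loops for echo synthesis and delay-and-sum gathering.

These kernels are the only performance-critical code paths: a 128-element
frame holds 128*128 channel pairs, and an 81-candidate sound-speed sweep over
a 101x101 grid touches ~1e10 pair-pixel delay evaluations. Everything here is
plain loops so the arithmetic matches the naive reference implementations used
as oracles in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["add_echoes", "das_accumulate"]


@njit(cache=True, fastmath=True)
def add_echoes(out, dist, gain, amp, scale, pulse_padded):
    """Accumulate point-scatterer echoes into an RF frame, in place.

    out          : (N, N, T) float32 -- RF data indexed (tx, rx, sample)
    dist         : (S, N) float32 -- scatterer-to-element distance, mm
    gain         : (S, N) float32 -- one-way spreading gain per element
    amp          : (S,) float32 -- reflectivity x elevation weight
    scale        : float -- samples per mm of round-trip path (fs / c_mm)
    pulse_padded : (L+1,) float32 -- pulse samples with one trailing zero

    Each (tx n, rx m) channel receives the pulse linearly interpolated and
    centered at the fractional arrival index (d_n + d_m) * scale, so the echo
    envelope peaks at the index a delay-and-sum beamformer computes.
    """
    S, N = dist.shape
    T = out.shape[2]
    L = pulse_padded.shape[0] - 1  # true pulse length
    half = (L - 1) / 2.0
    for s in range(S):
        a_s = amp[s]
        if a_s == 0.0:
            continue
        for n in range(N):
            dn = dist[s, n]
            gn = gain[s, n]
            for m in range(N):
                idx = (dn + dist[s, m]) * scale - half
                a = a_s * gn * gain[s, m]
                j0 = int(np.ceil(idx))
                if j0 < 0:
                    j0 = 0
                j1 = int(np.floor(idx)) + L - 1
                if j1 > T - 1:
                    j1 = T - 1
                for j in range(j0, j1 + 1):
                    u = j - idx
                    pu = int(u)
                    f = u - pu
                    out[n, m, j] += a * (
                        pulse_padded[pu] * (1.0 - f) + pulse_padded[pu + 1] * f
                    )


@njit(cache=True, fastmath=True)
def das_accumulate(analytic, dist, weights, scale, want_abs):
    """Delay-compensated channel gather for every pixel of a grid.

    analytic : (N, N, T) complex64 -- analytic (Hilbert) channel signals
    dist     : (N, P) float64 -- element-to-pixel distance, mm
    weights  : (N, P) float64 -- per-element apodization weight at each pixel
    scale    : float -- samples per mm of round-trip path (fs / c_mm)
    want_abs : bool -- also accumulate |s| and |s|^2 (needed for coherence)

    Returns (sum_re, sum_im, abs_sum, sq_sum, w_sum), each (P,) float64.
    The per-channel weight is w_tx * w_rx; samples at fractional delay indices
    are linearly interpolated, indices outside [0, T-1] contribute nothing.
    """
    N = analytic.shape[0]
    T = analytic.shape[2]
    P = dist.shape[1]
    sum_re = np.zeros(P)
    sum_im = np.zeros(P)
    abs_sum = np.zeros(P)
    sq_sum = np.zeros(P)
    w_sum = np.zeros(P)
    for n in range(N):
        for m in range(N):
            ch = analytic[n, m]
            for p in range(P):
                w = weights[n, p] * weights[m, p]
                if w == 0.0:
                    continue
                idx = (dist[n, p] + dist[m, p]) * scale
                if idx < 0.0 or idx > T - 1:
                    continue
                i0 = int(idx)
                if i0 > T - 2:
                    i0 = T - 2
                f = idx - i0
                c0 = ch[i0]
                c1 = ch[i0 + 1]
                vr = (c0.real * (1.0 - f) + c1.real * f) * w
                vi = (c0.imag * (1.0 - f) + c1.imag * f) * w
                sum_re[p] += vr
                sum_im[p] += vi
                w_sum[p] += w
                if want_abs:
                    m2 = vr * vr + vi * vi
                    sq_sum[p] += m2
                    abs_sum[p] += np.sqrt(m2)
    return sum_re, sum_im, abs_sum, sq_sum, w_sum
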