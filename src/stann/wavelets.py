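"""Minimal periodized orthogonal discrete wavelet transform.

Only what the ECG denoiser needs: a db4 filter bank, multi-level
analysis/synthesis with periodic boundary handling, and universal soft
thresholding. Signals are padded to a multiple of 2**levels and the pad
is stripped after reconstruction.
"""

from __future__ import annotations

import numpy as np

# Daubechies-4 (8-tap) reconstruction low-pass filter.
_REC_LO_DB4 = np.array(
    [
        0.23037781330885523,
        0.7148465705525415,
        0.6308807679295904,
        -0.02798376941698385,
        -0.18703481171888114,
        0.030841381835986965,
        0.032883011666982945,
        -0.010597401784997278,
    ]
)

# Orthonormal QMF pair used for analysis; synthesis is the adjoint.
DEC_LO = _REC_LO_DB4[::-1].copy()
DEC_HI = (_REC_LO_DB4 * np.power(-1.0, np.arange(8))).copy()


def _analysis_indices(n: int, taps: int) -> np.ndarray:
    return (2 * np.arange(n // 2)[:, None] + np.arange(taps)[None, :]) % n


def dwt_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One periodized analysis step -> (approximation, detail). len(x) must be even."""
    x = np.asarray(x, dtype=float)
    if len(x) % 2:
        raise ValueError("dwt_step requires even length")
    idx = _analysis_indices(len(x), len(DEC_LO))
    win = x[idx]
    return win @ DEC_LO, win @ DEC_HI


def idwt_step(approx: np.ndarray, detail: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`dwt_step`; exact inverse for the orthonormal bank."""
    n = 2 * len(approx)
    idx = _analysis_indices(n, len(DEC_LO))
    x = np.zeros(n)
    np.add.at(x, idx, approx[:, None] * DEC_LO[None, :])
    np.add.at(x, idx, detail[:, None] * DEC_HI[None, :])
    return x


def wavedec(x: np.ndarray, levels: int) -> list[np.ndarray]:
    """Return [a_L, d_L, d_{L-1}, ..., d_1]; len(x) must divide by 2**levels."""
    coeffs: list[np.ndarray] = []
    a = np.asarray(x, dtype=float)
    for _ in range(levels):
        a, d = dwt_step(a)
        coeffs.append(d)
    coeffs.append(a)
    return coeffs[::-1]

def waverec(coeffs: list[np.ndarray]) -> np.ndarray:
    a = coeffs[0]
    for d in coeffs[1:]:
        a = idwt_step(a, d)
    return a


def denoise_soft(x: np.ndarray, levels: int = 4, shrink_levels: int = 1) -> np.ndarray:
    """Universal-threshold soft wavelet shrinkage (noise scale from MAD of d1).

    Only the `shrink_levels` finest detail levels are thresholded: white
    noise is spread evenly over levels while sharp waveform features
    (QRS) concentrate at coarser scales, so shrinking everything trades
    waveform distortion for noise removal at a loss.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2**levels:
        return x.copy()
    block = 2**levels
    padded_len = int(np.ceil(n / block)) * block
    pad = padded_len - n
    xp = np.concatenate([x, x[-pad:][::-1]]) if pad else x
    coeffs = wavedec(xp, levels)  # [a_L, d_L, ..., d_1]
    d1 = coeffs[-1]
    sigma = np.median(np.abs(d1)) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(len(xp)))
    out = list(coeffs)
    for j in range(1, min(shrink_levels, levels) + 1):
        d = out[-j]
        out[-j] = np.sign(d) * np.maximum(np.abs(d) - thr, 0.0)
    return waverec(out)[:n]
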