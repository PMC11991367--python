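"""Fidelity and detection metrics: MSE, DTW distance, SNR (dB), BER (%).

DTW uses the classic unconstrained dynamic-programming recurrence with
absolute-difference local cost and anchored endpoints:

    D(i, j) = |a_i - b_j| + min(D(i-1, j), D(i, j-1), D(i-1, j-1)).

SNR follows the steganographic convention

    SNR = -10 log10( sum (s_hat - s)^2 / sum s^2 )   [dB],

returning +inf for a perfect reconstruction.  BER is the percentage of
mismatched bits between two equal-length bit vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["MetricsReport", "mse", "dtw_distance", "snr_db", "ber_percent", "evaluate_pair"]


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    dtw: float
    snr_db: float
    ber_percent: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return a, b


def mse(a, b) -> float:
    """Mean squared error (1/N) * sum (a_i - b_i)^2."""
    a, b = _pair(a, b)
    return float(np.mean((a - b) ** 2))


def dtw_distance(a, b, window: int | None = None) -> float:
    """Dynamic time warping distance with |.| local cost.

    Lengths may differ.  ``window`` optionally restricts the warping path to
    |i - j| <= window (Sakoe-Chiba band); the default is unconstrained.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw_distance requires nonempty inputs")
    n, m = a.size, b.size
    if window is not None:
        window = max(window, abs(n - m))
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        j_lo = 1 if window is None else max(1, i - window)
        j_hi = m if window is None else min(m, i + window)
        cost_row = np.abs(a[i - 1] - b[j_lo - 1 : j_hi])
        for j, c in zip(range(j_lo, j_hi + 1), cost_row):
            D[i, j] = c + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return float(D[n, m])


def snr_db(s, s_hat) -> float:
    """Signal-to-noise ratio of an embedding, in dB; +inf when s_hat == s."""
    s, s_hat = _pair(s, s_hat)
    signal_energy = float(np.sum(s**2))
    if signal_energy == 0.0:
        raise ValueError("reference signal is all-zero; SNR undefined")
    residual = float(np.sum((s_hat - s) ** 2))
    if residual == 0.0:
        return float("inf")
    return -10.0 * np.log10(residual / signal_energy)


def ber_percent(w, w_hat) -> float:
    """Bit error rate: 100 * (# mismatched bits) / (total bits)."""
    w = np.asarray(getattr(w, "bits", w)).ravel()
    w_hat = np.asarray(getattr(w_hat, "bits", w_hat)).ravel()
    if w.size != w_hat.size:
        raise ValueError(f"bit-vector length mismatch: {w.size} vs {w_hat.size}")
    if w.size == 0:
        raise ValueError("empty bit vectors")
    return float(100.0 * np.count_nonzero(w != w_hat) / w.size)


def evaluate_pair(reference, test, bits_ref=None, bits_test=None) -> MetricsReport:
    """Full report for a signal pair and (optionally) a bit-vector pair."""
    return MetricsReport(
        mse=mse(reference, test),
        dtw=dtw_distance(reference, test),
        snr_db=snr_db(reference, test),
        ber_percent=None if bits_ref is None else ber_percent(bits_ref, bits_test),
    )
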