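"""Sensor signal-conditioning chain: Butterworth stages and Bode analysis.

The modelled front-end cascades a high-pass stage at 1 Hz, a low-pass stage at
10 Hz and a band-pass stage at 5-20 Hz (order 2 each, Butterworth, bilinear
transform at the dataset sample rate).  Application is causal by default, as
in a physical analog chain; zero-phase filtering is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "FrequencyResponse",
    "DEFAULT_CHAIN",
    "design_filter",
    "apply_chain",
    "bode_response",
]


@dataclass(frozen=True)
class FilterSpec:
    kind: str  # "lowpass" | "highpass" | "bandpass"
    cutoff_hz: float | tuple[float, float]
    order: int = 2
    sample_rate: float = 250.0

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ValueError(f"unknown filter kind: {self.kind!r}")
        nyq = self.sample_rate / 2.0
        cut = np.atleast_1d(np.asarray(self.cutoff_hz, dtype=float))
        if self.kind == "bandpass":
            if cut.size != 2 or not cut[0] < cut[1]:
                raise ValueError("bandpass needs a (low, high) cutoff pair with low < high")
        elif cut.size != 1:
            raise ValueError(f"{self.kind} needs a single cutoff")
        if np.any(cut <= 0) or np.any(cut >= nyq):
            raise ValueError("cutoffs must lie strictly between 0 and Nyquist")
        if self.order < 1:
            raise ValueError("order must be positive")


def default_chain(sample_rate: float = 250.0) -> tuple[FilterSpec, ...]:
    """High-pass 1 Hz -> band-pass 5-20 Hz -> low-pass 10 Hz, order 2 each."""
    return (
        FilterSpec("highpass", 1.0, 2, sample_rate),
        FilterSpec("bandpass", (5.0, 20.0), 2, sample_rate),
        FilterSpec("lowpass", 10.0, 2, sample_rate),
    )


DEFAULT_CHAIN = default_chain()


@dataclass(frozen=True)
class FrequencyResponse:
    frequencies: np.ndarray  # Hz, log-spaced
    magnitude_db: np.ndarray
    phase_deg: np.ndarray  # unwrapped


def design_filter(spec: FilterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Digital Butterworth coefficients (b, a) via the bilinear transform."""
    nyq = spec.sample_rate / 2.0
    wn = np.atleast_1d(np.asarray(spec.cutoff_hz, dtype=float)) / nyq
    b, a = sps.butter(spec.order, wn if wn.size > 1 else wn[0], btype=spec.kind)
    poles = np.roots(a)
    if np.any(np.abs(poles) >= 1.0):
        raise RuntimeError("designed filter is unstable")
    return b, a


def apply_chain(samples: np.ndarray, specs, sample_rate: float | None = None, zero_phase: bool = False) -> np.ndarray:
    """Apply the filter stages in order; output length equals input length."""
    samples = np.asarray(samples, dtype=float)
    out = samples.copy()
    for spec in specs:
        if sample_rate is not None and spec.sample_rate != sample_rate:
            raise ValueError(
                f"signal sample rate {sample_rate} Hz does not match filter spec {spec.sample_rate} Hz"
            )
        b, a = design_filter(spec)
        out = sps.filtfilt(b, a, out) if zero_phase else sps.lfilter(b, a, out)
    return out


def bode_response(
    specs,
    f_min_hz: float = 0.1,
    f_max_hz: float = 100.0,
    n_points: int = 256,
) -> FrequencyResponse:
    """Combined Bode response of the cascade: |H| in dB, unwrapped phase in deg.

    The cascade response is the product of the stage responses evaluated on a
    log-spaced frequency grid below Nyquist.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one filter stage")
    sample_rate = specs[0].sample_rate
    nyq = sample_rate / 2.0
    if not (0 < f_min_hz < f_max_hz < nyq):
        raise ValueError("need 0 < f_min < f_max < Nyquist")
    freqs = np.logspace(np.log10(f_min_hz), np.log10(f_max_hz), n_points)
    h_total = np.ones(n_points, dtype=complex)
    for spec in specs:
        b, a = design_filter(spec)
        _, h = sps.freqz(b, a, worN=freqs, fs=spec.sample_rate)
        h_total *= h
    mag_db = 20.0 * np.log10(np.maximum(np.abs(h_total), 1e-300))
    phase_deg = np.degrees(np.unwrap(np.angle(h_total)))
    return FrequencyResponse(frequencies=freqs, magnitude_db=mag_db, phase_deg=phase_deg)
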