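"""Fourier-simulated single-beat ECG generation.

A beat is modelled as six localized wave components (P, Q, R, S, T, U) on a
flat isoelectric baseline.  Each wave is a Gaussian bump
``a * exp(-(t - c)^2 / (2 w^2))`` with amplitude ``a`` (mV), center ``c`` and
width ``w`` expressed as fractions of the beat duration.  Because the beat is
periodic, the same waveform can be reconstructed from the first ``K`` Fourier
harmonics of its periodic extension; both views are exposed.

Datasets are built by adding zero-mean Gaussian noise (standard deviation =
``noise_factor``, in normalized amplitude units) to independent copies of the
clean beat, normalizing, and splitting into train/validation/test partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

__all__ = [
    "WaveParams",
    "BeatTemplate",
    "ECGSignal",
    "DatasetSpec",
    "NormalizationRecord",
    "ECGDataset",
    "DEFAULT_TEMPLATE",
    "synthesize_beat",
    "add_noise",
    "normalize",
    "denormalize",
    "generate_dataset",
    "save_signals_csv",
    "load_signals_csv",
]

WAVE_ORDER = ("P", "Q", "R", "S", "T", "U")

NormalizationMode = Literal["minus-one-to-one", "zscore", "none"]


@dataclass(frozen=True)
class WaveParams:
    """One ECG wave: amplitude (mV, signed), center and width as beat fractions."""

    amplitude: float
    center: float
    width: float


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology parameters for a single ECG beat.

    The default template places the six waves so that the R wave carries the
    largest positive deflection, the U wave stays below 0.05 mV, and centers
    strictly increase P < Q < R < S < T < U.
    """

    waves: dict[str, WaveParams]
    beat_duration: float = 0.36  # seconds; 90 samples at 250 Hz
    baseline_level: float = 0.0

    def __post_init__(self) -> None:
        missing = set(WAVE_ORDER) - set(self.waves)
        if missing:
            raise ValueError(f"template missing waves: {sorted(missing)}")
        centers = [self.waves[w].center for w in WAVE_ORDER]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError("wave centers must strictly increase in P<Q<R<S<T<U order")
        for name, wp in self.waves.items():
            if wp.width <= 0:
                raise ValueError(f"{name} wave width must be positive")
        r_amp = self.waves["R"].amplitude
        others = [self.waves[w].amplitude for w in WAVE_ORDER if w != "R"]
        if not (r_amp > 0 and all(r_amp >= a for a in others)):
            raise ValueError("R amplitude must be the largest positive amplitude")


DEFAULT_TEMPLATE = BeatTemplate(
    waves={
        "P": WaveParams(0.10, 0.20, 0.025),
        "Q": WaveParams(-0.12, 0.36, 0.010),
        "R": WaveParams(1.00, 0.40, 0.012),
        "S": WaveParams(-0.20, 0.44, 0.010),
        "T": WaveParams(0.25, 0.62, 0.040),
        "U": WaveParams(0.04, 0.78, 0.030),
    }
)


@dataclass(frozen=True)
class ECGSignal:
    """Fixed-length real-valued sample vector (mV) with its sampling rate."""

    samples: np.ndarray
    sampling_rate: float = 250.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be a 1-D vector")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class DatasetSpec:
    """How many noisy beats to draw and how to normalize/split them."""

    n_signals: int = 100
    noise_factor: float = 0.0
    seed: int = 0
    normalization_mode: NormalizationMode = "minus-one-to-one"
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self) -> None:
        if self.n_signals < 10:
            raise ValueError("n_signals must be at least 10")
        if self.noise_factor < 0:
            raise ValueError("noise_factor must be nonnegative")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class NormalizationRecord:
    """Affine parameters needed to invert a normalization: x = scale*y + offset."""

    mode: str
    scale: float
    offset: float


@dataclass
class ECGDataset:
    """Train/val/test partitions of noisy beats plus the provenance to rebuild them."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    sampling_rate: float
    norm_record: NormalizationRecord
    template: BeatTemplate
    spec: DatasetSpec
    clean_beat: np.ndarray  # normalized clean beat, for reference comparisons

    @property
    def all_signals(self) -> np.ndarray:
        return np.concatenate([self.train, self.val, self.test], axis=0)


def _wave_times(n_samples: int, n_beats: int = 1) -> np.ndarray:
    # sample i sits at phase (i + 0.5)/n of its beat; phases beyond [0,1) wrap
    return (np.arange(n_samples * n_beats) + 0.5) / n_samples


def synthesize_beat(
    template: BeatTemplate = DEFAULT_TEMPLATE,
    n_samples: int = 90,
    sampling_rate: float = 250.0,
    fourier_terms: int | None = None,
    n_beats: int = 1,
) -> ECGSignal:
    """Synthesize one clean (noiseless) ECG beat.

    Parameters
    ----------
    template
        Wave morphology (amplitudes, centers, widths) and baseline.
    n_samples
        Number of samples in the beat (>= 16).
    sampling_rate
        Sampling rate in Hz; carried on the output signal.
    fourier_terms
        If given, reconstruct the beat from its first ``fourier_terms``
        harmonics of the periodic extension instead of returning the sum of
        Gaussian bumps directly.  ``K >= n_samples // 2`` reproduces the bump
        sum exactly.
    n_beats
        Number of identical beats to concatenate (periodic extension).

    Returns
    -------
    ECGSignal
        One (or more) beat(s); the global maximum of a single beat falls at
        the R-wave center sample.
    """
    if n_samples < 16:
        raise ValueError("n_samples must be at least 16")
    if n_beats < 1:
        raise ValueError("n_beats must be positive")
    phase = _wave_times(n_samples, n_beats)
    samples = np.full(n_samples * n_beats, template.baseline_level, dtype=float)
    for name in WAVE_ORDER:
        wp = template.waves[name]
        # wrap-around distance keeps the bump periodic across the beat boundary
        d = phase - wp.center
        d = d - np.round(d)
        samples += wp.amplitude * np.exp(-(d**2) / (2.0 * wp.width**2))
    if fourier_terms is not None:
        if fourier_terms < 1:
            raise ValueError("fourier_terms must be positive")
        spectrum = np.fft.rfft(samples)
        spectrum[n_beats * fourier_terms + 1 :] = 0.0
        samples = np.fft.irfft(spectrum, n=n_samples * n_beats)
    return ECGSignal(samples=samples, sampling_rate=sampling_rate)


def add_noise(signal: ECGSignal, noise_factor: float, seed: int | np.random.SeedSequence) -> ECGSignal:
    """Add i.i.d. zero-mean Gaussian noise with standard deviation ``noise_factor``."""
    if noise_factor < 0:
        raise ValueError("noise_factor must be nonnegative")
    if noise_factor == 0:
        return ECGSignal(samples=signal.samples.copy(), sampling_rate=signal.sampling_rate)
    rng = np.random.default_rng(seed)
    noisy = signal.samples + noise_factor * rng.standard_normal(len(signal))
    return ECGSignal(samples=noisy, sampling_rate=signal.sampling_rate)


def normalize(signals: np.ndarray, mode: NormalizationMode) -> tuple[np.ndarray, NormalizationRecord]:
    """Normalize a (n_signals, n_samples) array; returns data + inversion record.

    ``minus-one-to-one`` maps the global min/max of the batch onto [-1, 1];
    ``zscore`` centers to zero mean, unit standard deviation.  Degenerate
    (constant) batches pass through with scale 1 so the inverse is exact.
    """
    signals = np.asarray(signals, dtype=float)
    if mode == "none":
        return signals.copy(), NormalizationRecord("none", 1.0, 0.0)
    if mode == "minus-one-to-one":
        lo, hi = float(signals.min()), float(signals.max())
        if hi == lo:
            return signals.copy(), NormalizationRecord(mode, 1.0, 0.0)
        scale = (hi - lo) / 2.0
        offset = (hi + lo) / 2.0
        return (signals - offset) / scale, NormalizationRecord(mode, scale, offset)
    if mode == "zscore":
        mu, sd = float(signals.mean()), float(signals.std())
        if sd == 0.0:
            return signals - mu, NormalizationRecord(mode, 1.0, mu)
        return (signals - mu) / sd, NormalizationRecord(mode, sd, mu)
    raise ValueError(f"unknown normalization mode: {mode!r}")


def denormalize(signals: np.ndarray, record: NormalizationRecord) -> np.ndarray:
    """Invert :func:`normalize`: x = scale * y + offset."""
    return np.asarray(signals, dtype=float) * record.scale + record.offset


def _split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    # val/test round to nearest; train absorbs the remainder
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    n_train = n - n_val - n_test
    if n_train <= 0:
        raise ValueError("split leaves no training signals")
    return n_train, n_val, n_test


def generate_dataset(
    template: BeatTemplate = DEFAULT_TEMPLATE,
    spec: DatasetSpec = DatasetSpec(),
    n_samples: int = 90,
    sampling_rate: float = 250.0,
) -> ECGDataset:
    """Generate a normalized, partitioned dataset of noisy copies of one beat.

    Each signal is an independent Gaussian-noise realization of the same clean
    beat.  A master seed fans out one child seed per signal (counter-based via
    ``SeedSequence.spawn``), so the dataset is reproducible and each signal is
    independent of how many others are drawn before it.
    """
    clean = synthesize_beat(template, n_samples=n_samples, sampling_rate=sampling_rate)
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(spec.n_signals)
    raw = np.empty((spec.n_signals, n_samples))
    for i, child in enumerate(children):
        raw[i] = add_noise(clean, spec.noise_factor, child).samples
    normed, record = normalize(raw, spec.normalization_mode)
    # the clean beat on the same normalized scale, for reference comparisons
    clean_normed = (clean.samples - record.offset) / record.scale
    n_train, n_val, n_test = _split_sizes(spec.n_signals, spec.split_fractions)
    return ECGDataset(
        train=normed[:n_train],
        val=normed[n_train : n_train + n_val],
        test=normed[n_train + n_val :],
        sampling_rate=sampling_rate,
        norm_record=record,
        template=template,
        spec=spec,
        clean_beat=clean_normed,
    )


def save_signals_csv(path: str, signals: np.ndarray, header: bool = False) -> None:
    """Write signals as delimited text, one signal per row."""
    import pandas as pd

    df = pd.DataFrame(np.atleast_2d(np.asarray(signals, dtype=float)))
    df.to_csv(path, index=False, header=header)


def load_signals_csv(path: str, header: bool | None = None) -> np.ndarray:
    """Read signals from delimited text (one per row); header row auto-detected."""
    import pandas as pd

    if header is None:
        # a header row is non-numeric; sniff the first line
        with open(path) as fh:
            first = fh.readline()
        try:
            [float(tok) for tok in first.strip().split(",")]
            header_arg = None
        except ValueError:
            header_arg = 0
    else:
        header_arg = 0 if header else None
    df = pd.read_csv(path, header=header_arg)
    return df.to_numpy(dtype=float)


def template_to_dict(template: BeatTemplate) -> dict:
    """Plain-dict form of a template for manifests/config files."""
    return asdict(template)
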