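"""Binary watermark embedding and extraction for VAE-reconstructed signals.

Three non-blind strategies:

* ``mu`` — add ``alpha * w`` to the first L coordinates of the encoder's
  latent mean before reparameterization and decoding.
* ``z`` — add ``alpha * w`` to the sampled latent vector itself.
* ``freq`` — after reconstruction, raise (bit 1) or lower (bit 0) the DFT
  magnitude of selected frequency bins by ``alpha``, phase preserved, and
  invert the transform.

Each embedding returns an :class:`EmbedRecord` carrying the reference payload
(original mean, original z, or original spectral magnitudes) that extraction
needs.  Stored-reference extraction is the exact algebraic inverse of
embedding; a ``reencode`` mode re-encodes the suspect signal instead, which is
only approximate because encode(decode(.)) is not idempotent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .vae_core import VAE, LatentStats, reparameterize

__all__ = [
    "WatermarkBits",
    "EmbedRecord",
    "default_watermark",
    "default_freq_indices",
    "embed_mu",
    "extract_mu",
    "embed_z",
    "extract_z",
    "embed_freq",
    "extract_freq",
    "save_record",
    "load_record",
]

BIT_THRESHOLD = 0.5  # midpoint rule on the continuous estimate
MAGNITUDE_FLOOR = 1e-9  # bit-0 embedding may not drive a magnitude negative


def _as_bits(bits: np.ndarray) -> np.ndarray:
    bits = np.asarray(bits)
    if bits.ndim != 1 or bits.size < 1:
        raise ValueError("watermark must be a nonempty 1-D bit vector")
    if not np.all(np.isin(bits, (0, 1))):
        raise ValueError("watermark bits must be 0 or 1")
    return bits.astype(int)


@dataclass(frozen=True)
class WatermarkBits:
    """Binary payload of length L."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", _as_bits(self.bits))

    def __len__(self) -> int:
        return self.bits.size


def default_watermark(length: int = 10) -> WatermarkBits:
    """The all-ones payload used throughout the reference experiments."""
    return WatermarkBits(np.ones(length, dtype=int))


@dataclass
class EmbedRecord:
    """Everything extraction needs: strategy, strength, carrier and reference.

    ``reference`` is the original (pre-embedding) quantity: the latent mean,
    the sampled latent vector, or the spectral magnitudes at the chosen bins.
    ``carrier`` is the corresponding watermarked quantity (mu_w or z_w) for
    the latent strategies; stored-reference extraction differences the two.
    """

    strategy: str  # "mu" | "z" | "freq"
    alpha: float
    watermarked_signal: np.ndarray
    reference: np.ndarray  # original mu | original z | original |X[k]| at indices
    n_bits: int
    carrier: np.ndarray | None = None  # mu_w | z_w (latent strategies)
    coeff_indices: np.ndarray | None = None  # freq strategy only
    log_var: np.ndarray | None = None  # latent strategies: sigma at embed time
    epsilon: np.ndarray | None = None  # reparameterization draw used at embed time


# ----------------------------------------------------------- latent strategies


def _check_latent_capacity(model: VAE, w: WatermarkBits) -> None:
    if len(w) > model.config.latent_dim:
        raise ValueError(
            f"watermark length {len(w)} exceeds latent dimension {model.config.latent_dim}"
        )


def _padded(w: WatermarkBits, dim: int) -> np.ndarray:
    tilde = np.zeros(dim)
    tilde[: len(w)] = w.bits
    return tilde


def embed_mu(
    model: VAE,
    x: np.ndarray,
    w: WatermarkBits,
    alpha: float,
    epsilon: np.ndarray | float = 0.0,
) -> EmbedRecord:
    """Embed into the latent mean: mu_w = mu + alpha * w on coordinates 0..L-1.

    The watermarked signal is ``decode(mu_w + epsilon * sigma)``; the record
    stores the original mean as the extraction reference.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    _check_latent_capacity(model, w)
    stats = model.encode(np.asarray(x, dtype=float))
    mu_w = stats.mu + alpha * _padded(w, model.config.latent_dim)
    eps = np.broadcast_to(np.asarray(epsilon, dtype=float), mu_w.shape).copy()
    z = reparameterize(LatentStats(mu=mu_w, log_var=stats.log_var), epsilon=eps)
    return EmbedRecord(
        strategy="mu",
        alpha=alpha,
        watermarked_signal=model.decode(z),
        reference=stats.mu.copy(),
        n_bits=len(w),
        carrier=mu_w,
        log_var=stats.log_var.copy(),
        epsilon=eps,
    )


def extract_mu(
    record: EmbedRecord,
    model: VAE | None = None,
    mode: str = "stored",
) -> WatermarkBits:
    """Recover bits as threshold((mu_w - mu_ref) / alpha) on the embedded coords.

    ``stored`` uses the watermarked mean implied by the record (exact inverse);
    ``reencode`` re-encodes the watermarked signal through the model, per the
    verification narrative, and is approximate.
    """
    if record.strategy != "mu":
        raise ValueError(f"record strategy is {record.strategy!r}, expected 'mu'")
    if record.alpha == 0:
        raise ZeroDivisionError("alpha is zero; embedding is not invertible")
    if mode == "stored":
        mu_w = record.carrier
    elif mode == "reencode":
        if model is None:
            raise ValueError("reencode mode requires the model")
        mu_w = model.encode(record.watermarked_signal).mu
    else:
        raise ValueError(f"unknown extraction mode: {mode!r}")
    w_cont = (mu_w - record.reference)[: record.n_bits] / record.alpha
    return WatermarkBits((w_cont >= BIT_THRESHOLD).astype(int))


def embed_z(
    model: VAE,
    x: np.ndarray,
    w: WatermarkBits,
    alpha: float,
    epsilon: np.ndarray | float = 0.0,
) -> EmbedRecord:
    """Embed into the sampled latent vector: z_w = z_original + alpha * w."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    _check_latent_capacity(model, w)
    stats = model.encode(np.asarray(x, dtype=float))
    eps = np.broadcast_to(np.asarray(epsilon, dtype=float), stats.mu.shape).copy()
    z_orig = reparameterize(stats, epsilon=eps)
    z_w = z_orig + alpha * _padded(w, model.config.latent_dim)
    return EmbedRecord(
        strategy="z",
        alpha=alpha,
        watermarked_signal=model.decode(z_w),
        reference=z_orig.copy(),
        n_bits=len(w),
        carrier=z_w,
        log_var=stats.log_var.copy(),
        epsilon=eps,
    )


def extract_z(record: EmbedRecord, model: VAE | None = None, mode: str = "stored") -> WatermarkBits:
    """Recover bits as threshold((z_w - z_original) / alpha)."""
    if record.strategy != "z":
        raise ValueError(f"record strategy is {record.strategy!r}, expected 'z'")
    if record.alpha == 0:
        raise ZeroDivisionError("alpha is zero; embedding is not invertible")
    if mode == "stored":
        z_w = record.carrier
    elif mode == "reencode":
        if model is None:
            raise ValueError("reencode mode requires the model")
        stats = model.encode(record.watermarked_signal)
        z_w = reparameterize(stats, epsilon=record.epsilon)
    else:
        raise ValueError(f"unknown extraction mode: {mode!r}")
    w_cont = (z_w - record.reference)[: record.n_bits] / record.alpha
    return WatermarkBits((w_cont >= BIT_THRESHOLD).astype(int))


# -------------------------------------------------------- frequency strategy


def default_freq_indices(n_bits: int = 10) -> np.ndarray:
    """Half-spectrum bins 2..n_bits+1: skip the DC bin and the fundamental."""
    return np.arange(2, n_bits + 2)


def embed_freq(
    x_hat: np.ndarray,
    w: WatermarkBits,
    alpha: float,
    coeff_indices: np.ndarray | None = None,
) -> EmbedRecord:
    """Embed by shifting DFT magnitudes at selected bins by +/- alpha.

    A bit shifts the *total* spectral magnitude of its conjugate bin pair by
    ``alpha``: bin k and bin n-k each move by ``alpha/2`` (up for bit 1, down
    for bit 0, floored so magnitudes stay positive).  This equals modifying
    the single positive-frequency coefficient by ``alpha`` and keeping the
    real part of the inverse transform.  Phase is preserved and conjugate
    symmetry maintained, so the output is real to numerical precision.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    x_hat = np.asarray(x_hat, dtype=float)
    n = x_hat.size
    if coeff_indices is None:
        coeff_indices = default_freq_indices(len(w))
    coeff_indices = np.asarray(coeff_indices, dtype=int)
    if coeff_indices.size != len(w):
        raise ValueError("need exactly one frequency bin per watermark bit")
    if np.unique(coeff_indices).size != coeff_indices.size:
        raise ValueError("coeff_indices must be distinct")
    nyquist = n // 2 if n % 2 == 0 else None
    if np.any(coeff_indices <= 0) or (nyquist is not None and np.any(coeff_indices >= nyquist)) or np.any(
        coeff_indices > (n - 1) // 2
    ):
        raise ValueError("coeff_indices must lie strictly between DC and Nyquist")

    X = np.fft.fft(x_hat)
    ref_mags = np.abs(X[coeff_indices]).copy()
    half = alpha / 2.0  # split across the conjugate pair: total shift is alpha
    for k, bit in zip(coeff_indices, _as_bits(np.asarray(w.bits))):
        mag = np.abs(X[k])
        new_mag = mag + half if bit == 1 else max(mag - half, MAGNITUDE_FLOOR)
        phase = X[k] / mag if mag > 0 else 1.0
        X[k] = new_mag * phase
        X[n - k] = np.conj(X[k])  # conjugate symmetry keeps the signal real
    watermarked = np.fft.ifft(X)
    if np.max(np.abs(watermarked.imag)) > 1e-9:
        raise AssertionError("inverse transform left a nontrivial imaginary residue")
    return EmbedRecord(
        strategy="freq",
        alpha=alpha,
        watermarked_signal=watermarked.real,
        reference=ref_mags,
        n_bits=len(w),
        coeff_indices=coeff_indices,
    )


def extract_freq(record: EmbedRecord, suspect: np.ndarray | None = None) -> WatermarkBits:
    """Bit k = 1 iff the suspect's magnitude at bin k exceeds the reference."""
    if record.strategy != "freq":
        raise ValueError(f"record strategy is {record.strategy!r}, expected 'freq'")
    if suspect is None:
        suspect = record.watermarked_signal
    suspect = np.asarray(suspect, dtype=float)
    if suspect.size != record.watermarked_signal.size:
        raise ValueError("suspect length does not match the record's signal length")
    mags = np.abs(np.fft.fft(suspect)[record.coeff_indices])
    return WatermarkBits((mags > record.reference).astype(int))


# ----------------------------------------------------------------- sidecar IO


def save_record(record: EmbedRecord, path: str) -> None:
    """Write an EmbedRecord as a JSON sidecar file."""
    def opt(arr):
        return None if arr is None else np.asarray(arr).tolist()

    payload = {
        "strategy": record.strategy,
        "alpha": record.alpha,
        "n_bits": record.n_bits,
        "watermarked_signal": record.watermarked_signal.tolist(),
        "reference": record.reference.tolist(),
        "carrier": opt(record.carrier),
        "coeff_indices": opt(record.coeff_indices),
        "log_var": opt(record.log_var),
        "epsilon": opt(record.epsilon),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_record(path: str) -> EmbedRecord:
    """Read an EmbedRecord from its JSON sidecar."""
    with open(path) as fh:
        payload = json.load(fh)

    def opt(key, dtype=float):
        return None if payload[key] is None else np.asarray(payload[key], dtype=dtype)

    return EmbedRecord(
        strategy=payload["strategy"],
        alpha=payload["alpha"],
        watermarked_signal=np.asarray(payload["watermarked_signal"], dtype=float),
        reference=np.asarray(payload["reference"], dtype=float),
        n_bits=payload["n_bits"],
        carrier=opt("carrier"),
        coeff_indices=opt("coeff_indices", int),
        log_var=opt("log_var"),
        epsilon=opt("epsilon"),
    )
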