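"""Rate coding: spike frequency <-> per-sample firing probability.

The simulator advances in discrete samples.  A neuron firing at ``f`` Hz in a
model sampled at ``F`` Hz is represented as a Bernoulli event with per-sample
probability ``f / F``; the inverse map converts efferent firing probabilities
back to frequencies.  Afferent Boolean states are drawn by thresholding a
uniform variate: ``afferent = X >= 1 - p`` with ``X ~ U[0, 1)``, which is exact
at both endpoints ``p = 0`` and ``p = 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateCodingConfig",
    "freq_to_prob",
    "prob_to_freq",
    "sampling_step_ms",
    "sample_afferent",
    "encode_position",
    "NON_TEMPORAL_MAX_SAMPLING_HZ",
]

log = logging.getLogger(__name__)

#: Highest sampling rate of the memoryless (non-temporal) engine.  Above this
#: the assumption that every neuron returns to rest between samples breaks.
NON_TEMPORAL_MAX_SAMPLING_HZ = 250.0


@dataclass(frozen=True)
class RateCodingConfig:
    """Sampling rate and the position -> afferent-probability encoder.

    Parameters
    ----------
    sampling_frequency : float
        Model samples per simulated second (Hz).
    encoder_low, encoder_high : float
        Afferent firing probability at joint position 0 (full extension) and
        1 (full flexion).  The encoder is linear between them.
    temporal : bool
        If False the non-temporal sampling cap of 250 Hz is enforced.
    """

    sampling_frequency: float = 250.0
    encoder_low: float = 0.0
    encoder_high: float = 1.0
    temporal: bool = False

    def __post_init__(self) -> None:
        if self.sampling_frequency <= 0:
            raise ValueError("sampling_frequency must be > 0")
        if not (0.0 <= self.encoder_low < self.encoder_high <= 1.0):
            raise ValueError(
                "require 0 <= encoder_low < encoder_high <= 1, got "
                f"({self.encoder_low}, {self.encoder_high})"
            )
        if not self.temporal and self.sampling_frequency > NON_TEMPORAL_MAX_SAMPLING_HZ:
            raise ValueError(
                "non-temporal model is capped at "
                f"{NON_TEMPORAL_MAX_SAMPLING_HZ:g} Hz sampling "
                f"(got {self.sampling_frequency:g} Hz)"
            )

    @property
    def step_ms(self) -> float:
        return sampling_step_ms(self.sampling_frequency)


def freq_to_prob(freq: float, sampling: float) -> float:
    """Convert a spike frequency (Hz) to a per-sample firing probability."""
    if sampling <= 0:
        raise ValueError("sampling frequency must be > 0")
    if not (0.0 <= freq <= sampling):
        raise ValueError(
            f"spike frequency {freq} Hz outside [0, {sampling}] Hz: a rate above "
            "the sampling frequency cannot be represented as a probability"
        )
    return freq / sampling


def prob_to_freq(prob: float, sampling: float) -> float:
    """Convert a per-sample firing probability back to a frequency (Hz)."""
    prob = np.asarray(prob, dtype=float)
    if np.any(prob < 0.0) or np.any(prob > 1.0):
        raise ValueError("firing probability must lie in [0, 1]")
    if sampling <= 0:
        raise ValueError("sampling frequency must be > 0")
    out = prob * sampling
    return float(out) if out.ndim == 0 else out


def sampling_step_ms(sampling: float) -> float:
    """Duration of one model sample in milliseconds (1000 / sampling)."""
    if sampling <= 0:
        raise ValueError("sampling frequency must be > 0")
    return 1000.0 / sampling


def sample_afferent(prob: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` independent Boolean afferent states.

    Each element is 1 with probability ``prob`` via the threshold rule
    ``X >= 1 - prob`` with ``X ~ U[0, 1)``.
    """
    if not (0.0 <= prob <= 1.0):
        raise ValueError("firing probability must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    x = rng.random(n)
    return (x >= 1.0 - prob).astype(np.uint8)


def encode_position(position: float, cfg: RateCodingConfig) -> float:
    """Map a joint position in [0, 1] to an afferent firing probability.

    Linear: ``encoder_low + position * (encoder_high - encoder_low)``.
    Out-of-range positions are clamped with a warning.
    """
    if position < 0.0 or position > 1.0:
        log.warning("joint position %.4g outside [0, 1]; clamping", position)
        position = min(max(position, 0.0), 1.0)
    return cfg.encoder_low + position * (cfg.encoder_high - cfg.encoder_low)
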