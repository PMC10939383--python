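"""Sequence generation from probability matrices.

Given a row-stochastic (n, 20) matrix, a final sequence can be read off by
argmax, or an ensemble of sequences can be drawn position-by-position from
temperature-rescaled rows:

    p_i(T) = exp(z_i / T) / sum_j exp(z_j / T),   z_i = log p_i

Feeding log-probabilities into the softmax makes the stated limits hold
exactly: T=1 returns the original distribution, T=0 degenerates to argmax,
and T -> infinity tends to uniform over the row's support.  Positions are
sampled independently (each frame was predicted independently of its
neighbours, so there is no positional coupling to exploit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AA_ORDER

__all__ = [
    "SamplingConfig",
    "apply_temperature",
    "decode_argmax",
    "sample_sequences",
]


@dataclass
class SamplingConfig:
    temperature: float = 1.0
    n_sequences: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")


def _check_row(row: np.ndarray) -> np.ndarray:
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or np.any(row < 0) or abs(row.sum() - 1.0) > 1e-6:
        raise ValueError("row must be a valid probability distribution")
    return row


def apply_temperature(row: np.ndarray, temperature: float) -> np.ndarray:
    """Rescale one probability row by sampling temperature.

    Zero-probability classes stay at exactly zero for every temperature.
    At T=0 the argmax class (lowest index on ties) takes all the mass.
    """
    row = _check_row(row)
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    if temperature == 0:
        out = np.zeros_like(row)
        out[int(np.argmax(row))] = 1.0
        return out
    support = row > 0
    z = np.log(row[support]) / temperature
    z -= z.max()
    e = np.exp(z)
    out = np.zeros_like(row)
    out[support] = e / e.sum()
    return out


def decode_argmax(matrix) -> str:
    """One letter per row, the most probable class; ties break to the
    lowest class index in ``AA_ORDER``."""
    probs = np.asarray(matrix)
    return "".join(AA_ORDER[i] for i in probs.argmax(axis=1))


def sample_sequences(matrix, config: SamplingConfig) -> list[str]:
    """Draw ``n_sequences`` sequences, each position independently.

    Reproducible: the generator is numpy's PCG64 seeded with
    ``config.seed``, and positions are consumed row-major
    (sequence-by-sequence, position-by-position).
    """
    probs = np.asarray(matrix)
    tempered = np.stack([apply_temperature(r, config.temperature)
                         for r in probs])
    cdf = np.cumsum(tempered, axis=1)
    cdf[:, -1] = 1.0
    rng = np.random.default_rng(config.seed)
    sequences = []
    for _ in range(config.n_sequences):
        u = rng.random(probs.shape[0])
        choices = (cdf < u[:, None]).sum(axis=1)
        sequences.append("".join(AA_ORDER[c] for c in choices))
    return sequences
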