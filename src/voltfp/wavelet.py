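"""Haar Simple Wavelet decomposition and step-mean derived attributes.

A 518-sample curve is truncated to 512 = 2^9 samples by dropping the six
samples nearest -0.7 V (the first six in acquisition order, whose values
are essentially identical across curves).  The forward transform at level
k produces 2^k coefficients in a mean-based convention: c0 is the global
mean and each refinement coefficient is the difference between a
half-interval's mean and its parent interval's mean.  Inverting the
truncated decomposition yields the level-k derived attributes
coef0 ... coef(2^k - 1): the stepwise approximation of the curve with 2^k
equal-width steps, each attribute being exactly the curve's mean over its
block, indexed in acquisition order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io import Voltammogram

TRUNCATED_LENGTH = 512
_DROP = 6


def truncate_to_pow2(curve: Voltammogram | np.ndarray) -> np.ndarray:
    """Drop the six samples nearest -0.7 V, leaving 512 = 2^9 samples.

    Inputs whose length is already a power of two pass through unchanged;
    any other length is an error.
    """
    y = curve.currents if isinstance(curve, Voltammogram) else np.asarray(curve, float)
    n = len(y)
    if n == _DROP + TRUNCATED_LENGTH:
        return y[_DROP:]
    if n >= 2 and (n & (n - 1)) == 0:
        return y
    raise ParameterError(f"cannot truncate length {n} to a power of 2")


def _check_pow2(n: int) -> int:
    if n < 2 or (n & (n - 1)) != 0:
        raise ParameterError(f"signal length {n} is not a power of 2")
    return int(np.log2(n))


def haar_forward(x: np.ndarray, level: int) -> np.ndarray:
    """Truncated mean-based Haar decomposition: 2^level coefficients.

    Coefficient 0 is the global mean; the following 2^level - 1
    coefficients are, level by level and left to right, the difference
    between each interval's left-half mean and the interval's own mean.
    """
    x = np.asarray(x, dtype=float)
    m = _check_pow2(len(x))
    if not 1 <= level <= m:
        raise ParameterError(f"level must be in 1..{m}")
    coeffs = [float(x.mean())]
    means = x.reshape(1, -1).mean(axis=1)     # interval means at current depth
    for _ in range(level):
        halves = x.reshape(2 * len(means), -1).mean(axis=1)
        coeffs.extend(halves[0::2] - means)   # left-half mean minus parent mean
        means = halves
    return np.asarray(coeffs[: 2 ** level])


@dataclass
class WaveletAttributes:
    """Level-k derived attributes: 2^k step means in acquisition order."""

    level: int
    coefs: np.ndarray

    def __post_init__(self):
        if len(self.coefs) != 2 ** self.level:
            raise ParameterError(
                f"level {self.level} requires {2 ** self.level} attributes")

    def names(self) -> list[str]:
        return [f"w{self.level}coef{j}" for j in range(len(self.coefs))]


def haar_inverse_attributes(coeffs: np.ndarray, level: int) -> WaveletAttributes:
    """Invert the truncated decomposition into 2^level step attributes."""
    coeffs = np.asarray(coeffs, dtype=float)
    if len(coeffs) != 2 ** level:
        raise ParameterError(
            f"level {level} requires {2 ** level} coefficients, got {len(coeffs)}")
    means = np.array([coeffs[0]])
    pos = 1
    for _ in range(level):
        d = coeffs[pos:pos + len(means)]
        pos += len(means)
        left = means + d
        right = 2.0 * means - left            # parent mean = (left + right)/2
        means = np.column_stack([left, right]).ravel()
    return WaveletAttributes(level, means)


def wavelet_attributes(curve: Voltammogram | np.ndarray, level: int = 5
                       ) -> WaveletAttributes:
    """Truncate, transform and invert in one step (the usual entry point)."""
    y = truncate_to_pow2(curve)
    return haar_inverse_attributes(haar_forward(y, level), level)


def block_means(x: np.ndarray, level: int) -> np.ndarray:
    """Direct block-mean computation (the attributes' defining property)."""
    x = np.asarray(x, dtype=float)
    _check_pow2(len(x))
    return x.reshape(2 ** level, -1).mean(axis=1)
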