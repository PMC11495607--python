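"""Exact Polya-Gamma PG(1, z) sampling (Devroye's alternating-series method).

Used for the data augmentation that makes the categorical-logit multilevel
model conditionally conjugate: with omega_i ~ PG(1, psi_i), the logistic
likelihood becomes Gaussian in the linear predictor.  A PG(1, c) variate is
J*(1, c/2) / 4 where J* is the tilted Jacobi-type distribution; J* is drawn
by rejection from a mixture of a truncated inverse-Gaussian body and an
exponential tail, with the alternating-series acceptance test.  Compiled
with numba; the generator is seeded explicitly per call for reproducibility.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # body/tail split point of the J* proposal


@njit(cache=True)
def _ndtr(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _a_coef(n: int, x: float) -> float:
    # n-th coefficient of the alternating series for the J* density
    if x > _TRUNC:
        return (
            math.pi
            * (n + 0.5)
            * math.exp(-((n + 0.5) ** 2) * math.pi * math.pi * x / 2.0)
        )
    return (
        math.pi
        * (n + 0.5)
        * (2.0 / (math.pi * x)) ** 1.5
        * math.exp(-2.0 * (n + 0.5) ** 2 / x)
    )


@njit(cache=True)
def _trunc_inv_gauss(z: float) -> float:
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC)."""
    t = _TRUNC
    if z < 1.0 / t:
        # mean above the truncation point: rejection via scaled chi-square
        while True:
            while True:
                e1 = -math.log(np.random.random())
                e2 = -math.log(np.random.random())
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) ** 2)
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while True:
            y = np.random.standard_normal()
            y = y * y
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) ** 2)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True)
def _sample_jstar(z: float) -> float:
    t = _TRUNC
    z = abs(z)
    k = math.pi * math.pi / 8.0 + z * z / 2.0
    p = math.pi / (2.0 * k) * math.exp(-k * t)
    # mass of the tilted inverse-Gaussian body below t, written so the
    # exp(2z) factor inside the IG cdf never overflows
    a1 = math.sqrt(1.0 / t) * (t * z - 1.0)
    b1 = math.sqrt(1.0 / t) * (t * z + 1.0)
    q = 2.0 * (math.exp(-z) * _ndtr(a1) + math.exp(z) * _ndtr(-b1))
    ratio = p / (p + q)
    while True:
        if np.random.random() < ratio:
            x = t - math.log(np.random.random()) / k  # exponential tail
        else:
            x = _trunc_inv_gauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def _pg_fill(z: np.ndarray, out: np.ndarray, seed: int) -> None:
    np.random.seed(seed)
    for i in range(z.shape[0]):
        out[i] = 0.25 * _sample_jstar(0.5 * abs(z[i]))


def pg_draws(z: np.ndarray, seed: int) -> np.ndarray:
    """Draw PG(1, z_i) for each element of z, reproducibly for a given seed."""
    z = np.ascontiguousarray(z, dtype=np.float64)
    out = np.empty_like(z)
    _pg_fill(z, out, int(seed) % (2**32 - 1))
    return out
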