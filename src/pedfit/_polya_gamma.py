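"""Polya-Gamma PG(1, z) sampling (Devroye's alternating-series method).

Used for exact conjugate updates of logit-linked latent values: with
``w ~ PG(1, eta)`` the Bernoulli-logit likelihood becomes Gaussian in
``eta``, so the latent can be Gibbs-sampled without Metropolis steps.

The implementation follows the standard accept-reject construction for the
Jacobi J*(1, z) density: a proposal from a truncated inverse-Gaussian body
or exponential tail (split at t = 0.64), thinned by the alternating
partial sums of the series expansion.  Draws use numba's internal RNG;
seed it via :func:`seed_polya_gamma` for reproducibility.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64


@njit(cache=True)
def seed_polya_gamma(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _norm_cdf(x):  # pragma: no cover
    return 0.5 * (1.0 + math.erf(x / np.sqrt(2.0)))


@njit(cache=True)
def _mass_right(z):  # pragma: no cover
    """Probability the proposal comes from the exponential tail (x > t)."""
    t = _TRUNC
    fz = 0.125 * np.pi**2 + 0.5 * z * z
    b = np.sqrt(1.0 / t) * (t * z - 1.0)
    a = -np.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = np.log(fz) + fz * t
    xb = x0 - z + np.log(_norm_cdf(b))
    xa = x0 + z + np.log(_norm_cdf(a))
    qdivp = 4.0 / np.pi * (np.exp(xb) + np.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z):  # pragma: no cover
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, t]."""
    t = _TRUNC
    x = t + 1.0
    if 1.0 / z > t:
        # mu > t: rejection sampling against the z = 0 (one-over-chi^2) body
        while True:
            while True:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) ** 2)
            if np.random.random() <= np.exp(-0.5 * z * z * x):
                return x
    mu = 1.0 / z
    while x > t:
        y = np.random.standard_normal() ** 2
        muy = mu * y
        x = mu + 0.5 * mu * muy - 0.5 * mu * np.sqrt(4.0 * muy + muy * muy)
        if np.random.random() > mu / (mu + x):
            x = mu * mu / x
    return x


@njit(cache=True)
def _a_coef(n, x):  # pragma: no cover
    if x > _TRUNC:
        return np.pi * (n + 0.5) * np.exp(-((n + 0.5) ** 2) * np.pi**2 * x / 2.0)
    return (
        np.pi
        * (n + 0.5)
        * (2.0 / (np.pi * x)) ** 1.5
        * np.exp(-2.0 * (n + 0.5) ** 2 / x)
    )


@njit(cache=True)
def pg_draw(psi):  # pragma: no cover - exercised via moments test
    """One draw from PG(1, psi)."""
    z = 0.5 * abs(psi)
    fz = 0.125 * np.pi**2 + 0.5 * z * z
    p_right = _mass_right(z)
    while True:
        if np.random.random() < p_right:
            x = _TRUNC + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z) if z > 0 else _rtigauss(1e-12)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def pg_vector(psi, out):  # pragma: no cover
    for i in range(psi.shape[0]):
        out[i] = pg_draw(psi[i])
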