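"""Gaussian competition between larvae and the density-dependent fitness term.

Larvae compete for space along the depth axis.  The interaction strength
between two larvae at depths D_j and D_i is a Gaussian kernel
exp(-(D_j - D_i)^2 / (2 Cw^2)); the competition load on a focal larva is the
sum over all *other* larvae in the generation (self excluded).  The kernel
width Cw sets how far apart larvae must be before they stop competing.

The competition fitness component is Fc(I) = K / (exp(10 I / K) + K), a
strictly decreasing function of load: close to 1 when competition is minimal
and near 0 when the load approaches the carrying capacity K.
"""

from __future__ import annotations

import numpy as np

__all__ = ["competition_strengths", "competition_fitness", "total_fitness"]

# Row-block size for the pairwise kernel; bounds peak memory at
# ~BLOCK * n doubles for populations of size n.
_BLOCK = 512


def competition_strengths(depths, Cw: float) -> np.ndarray:
    """Competition load I_j = sum_{i != j} exp(-(D_j - D_i)^2 / (2 Cw^2)).

    All larvae of a generation interact at once (generations do not
    overlap).  A lone individual has load 0; an empty population yields an
    empty array.  O(n^2), computed in row blocks.
    """
    if Cw <= 0:
        raise ValueError("competition kernel width Cw must be positive")
    D = np.asarray(depths, dtype=float).ravel()
    n = D.size
    if n == 0:
        return np.empty(0)
    inv = 1.0 / (2.0 * Cw * Cw)
    I = np.empty(n)
    for lo in range(0, n, _BLOCK):
        hi = min(lo + _BLOCK, n)
        diff = D[lo:hi, None] - D[None, :]
        I[lo:hi] = np.exp(-(diff * diff) * inv).sum(axis=1)
    return I - 1.0  # remove the self term exp(0)


def competition_fitness(I, K: int):
    """Fc = K / (exp(10 I / K) + K), evaluated overflow-safely.

    Equals K/(1+K) at zero load and decays to 0 as the load grows.
    """
    if K < 1:
        raise ValueError("carrying capacity K must be >= 1")
    I = np.asarray(I, dtype=float)
    # K/(e^x + K) == K e^-x / (1 + K e^-x): underflows gracefully for large x
    e = np.exp(-10.0 * I / K)
    out = K * e / (1.0 + K * e)
    if out.ndim == 0:
        return float(out)
    return out


def total_fitness(Fe, Fc):
    """Total fitness Ftot = Fe * Fc (the two components act multiplicatively)."""
    out = np.asarray(Fe, dtype=float) * np.asarray(Fc, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out
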