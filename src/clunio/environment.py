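"""Tidal geometry and the environmental component of larval fitness.

The habitat is a one-dimensional bathymetric axis in tidal-range units,
spanning +1 (top of the intertidal) to -1 (bottom).  The low-tide waterline
sweeps the band [-1, 0] over a 30-day lunar month: lowest low tides on
spring-tide days (near days 8 and 23), highest on neap days (near days 1
and 16).  An adult emerging on lunar day ``T`` oviposits at the waterline,
so ``T`` maps deterministically to an egg-laying depth.

Environmental fitness ``Fe(D)`` expresses how favourable a larval depth is.
The default is a sigmoid that is high below the neap low-water line and low
above it; four alternatives (flat, linear, unimodal, bimodal) probe the
sensitivity of divergence to this assumption.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "LUNAR_PERIOD",
    "FITNESS_VARIANTS",
    "wrap_lunar_day",
    "low_tide_depth",
    "environmental_fitness",
]

#: Number of days in the modelled lunar month.
LUNAR_PERIOD = 30

#: Tidal cycle length in days: two spring/neap cycles per lunar month.
TIDAL_PERIOD = 15

#: Recognised environmental fitness variants.
FITNESS_VARIANTS = ("sigmoid", "flat", "linear", "unimodal", "bimodal")

# The unimodal/bimodal Gaussians are implemented with the denominator
# (2*sigma)^2 -- i.e. 0.36 and 0.16 -- rather than the more conventional
# 2*sigma^2.  Switch these two constants to 2*0.3**2 / 2*0.2**2 to get the
# alternative reading.
UNIMODAL_DENOM = (2 * 0.3) ** 2
BIMODAL_DENOM = (2 * 0.2) ** 2


def wrap_lunar_day(t_raw):
    """Fold any integer onto the periodic lunar day scale 1..30.

    Lunar day arithmetic is circular: day 31 is day 1 and day 0 is day 30.
    Accepts a scalar or array of integers and returns the same shape.
    """
    t_raw = np.asarray(t_raw)
    wrapped = (t_raw - 1) % LUNAR_PERIOD + 1
    if wrapped.ndim == 0:
        return int(wrapped)
    return wrapped.astype(np.int64)


def low_tide_depth(T):
    """Depth of the low-tide waterline on lunar day ``T`` (1..30).

    D(T) = 1/2 * [sin(2*pi*T/15 - 5) - 1], in tidal-range units.  The image
    lies in [-1, 0] and D has period 15 in T (two tidal cycles per lunar
    month).  The phase constant -5 is a pure radian offset.

    Raises ``ValueError`` for non-integer or out-of-range days.
    """
    T_arr = np.asarray(T)
    if not np.issubdtype(T_arr.dtype, np.integer):
        raise ValueError(f"lunar day must be integer, got dtype {T_arr.dtype}")
    if np.any(T_arr < 1) or np.any(T_arr > LUNAR_PERIOD):
        raise ValueError("lunar day must lie in 1..30")
    D = _tide_depth(T_arr)
    if D.ndim == 0:
        return float(D)
    return D


def _tide_depth(T_arr):
    """Unchecked vectorised tide depth (internal hot path)."""
    return 0.5 * (np.sin(2.0 * np.pi * np.asarray(T_arr) / TIDAL_PERIOD - 5.0) - 1.0)


def environmental_fitness(D, variant: str = "sigmoid"):
    """Environmental fitness Fe at depth ``D`` in [-1, 1].

    Variants
    --------
    sigmoid : ``1 / (1 + exp(6 D + 1))`` -- strictly decreasing in D, near 1
        at the bottom (-1) and near 0 at the top (+1); the default.
    flat : ``1`` -- depth-independent.
    linear : ``-0.25 D + 0.75`` -- mild advantage with depth.
    unimodal : ``0.5 exp(-(-0.5 - D)^2 / 0.36) + 0.5`` -- single optimum at
        D = -0.5.
    bimodal : ``0.5 (exp(-(-1 - D)^2 / 0.16) + exp(-(-0.15 - D)^2 / 0.16)) + 0.5``
        -- optima near the bottom and just below the neap waterline.  Peaks
        overlap slightly so the value at D = -1 exceeds 1 by about 0.0055;
        this is intentional and left unclamped (offspring counts are floored
        downstream, so a fitness marginally above 1 is harmless).

    Accepts a scalar or array of depths.
    """
    D = np.asarray(D, dtype=float)
    if variant == "sigmoid":
        out = 1.0 / (1.0 + np.exp(6.0 * D + 1.0))
    elif variant == "flat":
        out = np.ones_like(D)
    elif variant == "linear":
        out = -0.25 * D + 0.75
    elif variant == "unimodal":
        out = 0.5 * np.exp(-((-0.5 - D) ** 2) / UNIMODAL_DENOM) + 0.5
    elif variant == "bimodal":
        out = 0.5 * (
            np.exp(-((-1.0 - D) ** 2) / BIMODAL_DENOM)
            + np.exp(-((-0.15 - D) ** 2) / BIMODAL_DENOM)
        ) + 0.5
    else:
        raise ValueError(
            f"unknown fitness variant {variant!r}; choose from {FITNESS_VARIANTS}"
        )
    if out.ndim == 0:
        return float(out)
    return out
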