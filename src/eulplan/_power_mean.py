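"""Generalized (power) mean, shared by gEUD and EUL.

Both metrics are the same functional ``M_a(x) = (mean(x_i^a))^(1/a)`` applied
to different per-voxel quantities (dose in Gy, distance-to-target in cm).
The volume-effect exponent ``a`` selects which part of the distribution
dominates: ``a = 1`` is the arithmetic mean, large positive ``a`` approaches
the maximum, large negative ``a`` the minimum.
"""

from __future__ import annotations

import numpy as np

__all__ = ["power_mean"]


def power_mean(values: np.ndarray, a: float) -> float:
    """Power mean of order ``a`` over a 1-D array of non-negative values.

    The computation is rescaled by the extreme element so that large ``|a|``
    does not overflow: ``M_a(x) = m * (mean((x/m)^a))^(1/a)`` with ``m`` the
    maximum (``a > 0``) or minimum (``a < 0``) of ``x``.

    Raises
    ------
    ValueError
        If ``a == 0`` (undefined exponent), the array is empty, any value is
        negative, or ``a < 0`` with a zero value (``0^a`` diverges).
    """
    a = float(a)
    if a == 0.0:
        raise ValueError("power mean undefined for a = 0")
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("power mean of an empty set is undefined")
    if (x < 0).any():
        raise ValueError("power mean requires non-negative values")
    if a < 0:
        if (x == 0).any():
            raise ValueError("a < 0 requires strictly positive values (0^a diverges)")
        m = float(x.min())
    else:
        m = float(x.max())
        if m == 0.0:
            return 0.0
    # (x/m)^a <= 1 for a > 0 with m = max, and for a < 0 with m = min,
    # so the mean is in (0, 1] and the final root is overflow-safe.
    return float(m * np.mean((x / m) ** a) ** (1.0 / a))
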