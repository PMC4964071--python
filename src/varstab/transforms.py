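"""Inverse-hyperbolic-sine (asinh) cofactor transformation and unit rescaling.

The workhorse transform is ``asinh(z / c) = ln(z/c + sqrt((z/c)^2 + 1))``
with a single positive scale parameter *c*, the normalization cofactor.
The general three-parameter form ``a * asinh(b + z/c)`` is deliberately not
exposed: a rescaling after the transform does not affect downstream
analysis and a pre-shift would displace cell populations, so ``a = 1`` and
``b = 0`` are fixed.

asinh is defined on all reals, so compensated (possibly negative)
fluorescence values pass through without clipping.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["asinh_transform", "rescale_unit"]


def asinh_transform(values: ArrayLike, cofactor: float) -> NDArray[np.float64]:
    """Apply the asinh transformation with cofactor ``c``.

    Parameters
    ----------
    values
        Raw intensities; any shape, any sign.
    cofactor
        Positive scale parameter. Values much smaller than ``c`` map
        nearly linearly (``z/c``); values much larger map nearly
        logarithmically (``ln(2 z / c)``).

    Returns
    -------
    Transformed array of the same shape, float64.
    """
    c = float(cofactor)
    if not np.isfinite(c) or c <= 0:
        raise ValueError(f"cofactor must be a positive finite number, got {cofactor!r}")
    z = np.asarray(values, dtype=np.float64)
    return np.arcsinh(z / c)


def rescale_unit(values: ArrayLike) -> NDArray[np.float64]:
    """Rescale a vector linearly onto [0, 1].

    Maps the minimum to 0 and the maximum to 1 via
    ``(z - min z) / (max z - min z)``; used to put channels transformed by
    different methods on a common scale for comparison. Order preserving
    and idempotent.

    Raises
    ------
    ValueError
        If the vector is constant (the map is degenerate) or has
        fewer than 2 values.
    """
    z = np.asarray(values, dtype=np.float64)
    if z.size < 2:
        raise ValueError("rescale_unit requires at least 2 values")
    lo, hi = np.min(z), np.max(z)
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("rescale_unit requires finite values")
    if hi == lo:
        raise ValueError("cannot rescale a constant vector to [0, 1]")
    return (z - lo) / (hi - lo)
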