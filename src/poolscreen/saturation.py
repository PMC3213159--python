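"""Hyperbolic array-feature response and its inverse.

The simulator and the intensity corrector share this single invertible
form: I = Imax * s / (s + K). A non-finite (or None) K selects the linear
limit I = s, in which case correction is the identity.
"""
from __future__ import annotations

import warnings

import numpy as np


def saturate(signal, imax: float = 65535.0, k: float | None = None):
    """Map true signal ``s`` to observed intensity ``Imax*s/(s+K)``."""
    s = np.asarray(signal, dtype=float)
    if k is None or not np.isfinite(k):
        out = s.copy()
    else:
        if k <= 0:
            raise ValueError("saturation constant K must be positive")
        out = imax * s / (s + k)
    return out if out.ndim else float(out)


def desaturate(intensity, imax: float = 65535.0, k: float | None = None,
               ceiling: float = 0.999):
    """Invert :func:`saturate`: ``s = K*I/(Imax - I)``.

    Intensities at or above ``Imax`` are clipped to ``ceiling*Imax`` with a
    warning (the response is not invertible there). Monotone increasing in I.
    """
    i = np.asarray(intensity, dtype=float)
    if k is None or not np.isfinite(k):
        out = i.copy()
        return out if out.ndim else float(out)
    if k <= 0:
        raise ValueError("saturation constant K must be positive")
    if not 0 < ceiling < 1:
        raise ValueError("ceiling must be in (0, 1)")
    clipped = i >= imax
    if np.any(clipped):
        warnings.warn(
            f"{int(np.sum(clipped))} intensity value(s) at or above Imax; "
            f"clipped to {ceiling:g}*Imax before inversion",
            stacklevel=2,
        )
        i = np.where(clipped, ceiling * imax, i)
    out = k * i / (imax - i)
    return out if out.ndim else float(out)
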