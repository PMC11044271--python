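"""Rational switching function shared by the contact-map CV and featurization.

The form is S(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m) with m > n, the standard
rational switch used for residue-contact collective variables.  S decreases
monotonically from 1 at r = 0 to 0 as r -> inf; the removable singularity at
r = r0 evaluates to the limit n/m.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rational_switch", "rational_switch_deriv"]

# relative half-width around r/r0 = 1 inside which the series limit is used
_SINGULAR_TOL = 1e-9


def rational_switch(r, r0: float = 0.8, n: int = 4, m: int = 8):
    """Evaluate S(r) elementwise.

    Parameters
    ----------
    r : array_like
        Distance(s), same units as ``r0``.  Must be >= 0.
    r0 : float
        Switching midpoint scale.
    n, m : int
        Numerator / denominator exponents, ``m > n > 0``.

    Returns
    -------
    ndarray or float in [0, 1].
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("rational_switch: negative distance")
    if not (m > n > 0):
        raise ValueError("rational_switch: require m > n > 0")
    x = r / r0
    num = 1.0 - x**n
    den = 1.0 - x**m
    near = np.abs(x - 1.0) < _SINGULAR_TOL
    # first-order expansion about x=1: S ~= (n/m) * (1 + (n-m)/2 * (x-1))
    limit = (n / m) * (1.0 + 0.5 * (n - m) * (x - 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(near, limit, num / np.where(near, 1.0, den))
    if val.ndim == 0:
        return float(val)
    return val


def rational_switch_deriv(r, r0: float = 0.8, n: int = 4, m: int = 8):
    """dS/dr, used for contact-wall restraint forces."""
    r = np.asarray(r, dtype=float)
    x = r / r0
    num = 1.0 - x**n
    den = 1.0 - x**m
    near = np.abs(x - 1.0) < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        dSdx = (-n * x ** (n - 1) * den + m * x ** (m - 1) * num) / np.where(
            near, 1.0, den**2
        )
    # limit of dS/dx at x=1 is n(n-m)/(2m)
    dSdx = np.where(near, n * (n - m) / (2.0 * m), dSdx)
    out = dSdx / r0
    if out.ndim == 0:
        return float(out)
    return out
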