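"""Exact stable-isotope arithmetic on the VPDB carbon scale.

All label accounting in this package is done in atom-fraction space: at the
13.4-99 atom% label strengths used in polymer tracer assays, linear mixing of
delta values is biased, whereas atom fractions mix exactly by mass balance.
Delta values (per mille vs VPDB) are the I/O representation; they are converted
on entry and back on exit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: 13C/12C isotope ratio of the VPDB standard.
R_VPDB = 0.0111802


class IsotopeError(ValueError):
    """An isotope quantity outside its physical domain."""


def delta_to_atom_fraction(delta_permil, r_standard: float = R_VPDB):
    """Convert delta-13C (per mille vs VPDB) to the 13C atom fraction.

    x = R / (1 + R) with R = (delta/1000 + 1) * R_standard.

    Parameters
    ----------
    delta_permil : float or array_like
        delta-13C in per mille; must be > -1000 (R > 0).
    r_standard : float
        Isotope ratio of the reference standard (VPDB by default).

    Returns
    -------
    float or ndarray
        Atom fraction of 13C among all carbon atoms, in (0, 1).
    """
    delta = np.asarray(delta_permil, dtype=float)
    if np.any(delta <= -1000.0):
        raise IsotopeError("delta-13C must exceed -1000 permil (R > 0)")
    r = (delta / 1000.0 + 1.0) * r_standard
    x = r / (1.0 + r)
    return float(x) if x.ndim == 0 else x


def atom_fraction_to_delta(x, r_standard: float = R_VPDB):
    """Convert a 13C atom fraction in (0, 1) to delta-13C (per mille vs VPDB)."""
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise IsotopeError("atom fraction must lie strictly inside (0, 1)")
    r = x / (1.0 - x)
    delta = (r / r_standard - 1.0) * 1000.0
    return float(delta) if delta.ndim == 0 else delta


@dataclass(frozen=True)
class MixingResult:
    """Two-pool mixing outcome.

    Attributes
    ----------
    f : float or ndarray
        Fraction of pool carbon derived from the labelled source, clamped
        to [0, 1].
    f_raw : float or ndarray
        The unclamped mixing fraction. Rate estimation uses this value so
        that measurement noise around zero uptake averages out instead of
        accumulating a positive bias.
    clamped : bool or ndarray
        True where ``f_raw`` fell outside [0, 1] by more than the tolerance.
    """

    f: object
    f_raw: object
    clamped: object


def source_fraction(x_sample, x_background, x_source, tol: float = 1e-9) -> MixingResult:
    """Two-pool atom-fraction mixing: fraction of carbon from the source.

    f = (x_sample - x_background) / (x_source - x_background)

    Mixing is exact in atom-fraction space; callers must convert delta values
    first (delta-space mixing is biased at high enrichment).

    Raises
    ------
    IsotopeError
        If the source and background endpoints coincide.
    """
    x_sample = np.asarray(x_sample, dtype=float)
    x_background = np.asarray(x_background, dtype=float)
    x_source = np.asarray(x_source, dtype=float)
    denom = x_source - x_background
    if np.any(np.abs(denom) < 1e-15):
        raise IsotopeError("degenerate endpoints: x_source == x_background")
    f_raw = (x_sample - x_background) / denom
    clamped = (f_raw < -tol) | (f_raw > 1.0 + tol)
    f = np.clip(f_raw, 0.0, 1.0)
    if f_raw.ndim == 0:
        return MixingResult(float(f), float(f_raw), bool(clamped))
    return MixingResult(f, f_raw, clamped)


def excess_carbon(pool_c_mg, f):
    """Substrate-derived carbon mass (mg C) in a pool: pool_c * f."""
    pool = np.asarray(pool_c_mg, dtype=float)
    if np.any(pool < 0.0):
        raise IsotopeError("pool carbon mass must be non-negative")
    out = pool * np.asarray(f, dtype=float)
    return float(out) if out.ndim == 0 else out
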