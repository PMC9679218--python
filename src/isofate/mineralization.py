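"""Headspace CO2 and end-point DIC accounting for closed-bottle assays.

A bottle holds ``water_volume`` mL of lake water under a closed headspace.
Weekly 5 mL gas samples yield a CO2 mixing ratio (or GC peak area) and a
delta-13C; at the end of the incubation a 5 mL water subsample is acidified to
liberate DIC. Treatment bottles received a 13C-labelled substrate; control
bottles of the same water received none and define the background isotope
endpoint. Substrate-derived ("excess") carbon in each inorganic pool follows
from two-pool atom-fraction mixing against the control mean, and the
mineralization rate is the excess expressed as a percentage of the added
substrate carbon per month or year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .isotope import delta_to_atom_fraction, source_fraction

#: a month is exactly 1/12 of a 365.25-day year (30.4375 d), so that
#: per-month <-> per-year conversions are an exact factor of 12
YEAR_DAYS = 365.25
MONTH_DAYS = YEAR_DAYS / 12.0
#: molar mass of carbon, g/mol
C_MOLAR = 12.011
#: gas constant, L atm / (mol K)
R_GAS = 0.0820574


class CalibrationError(ValueError):
    """A calibration curve is missing, unfit, or out of QC bounds."""


@dataclass
class CalibrationCurve:
    """Linear instrument calibration: amount = slope * signal + intercept."""

    slope: float
    intercept: float = 0.0

    @classmethod
    def from_standards(cls, amounts, signals) -> "CalibrationCurve":
        """Least-squares line through >= 2 (signal, amount) standards."""
        amounts = np.asarray(amounts, dtype=float)
        signals = np.asarray(signals, dtype=float)
        if amounts.size < 2:
            raise CalibrationError("need at least two calibration standards")
        slope, intercept = np.polyfit(signals, amounts, 1)
        return cls(slope=float(slope), intercept=float(intercept))

    def predict(self, signal):
        """Amount at a signal; negative predictions clamp to 0."""
        signal = np.asarray(signal, dtype=float)
        if np.any(signal < 0):
            raise CalibrationError("signal must be non-negative")
        amount = self.slope * signal + self.intercept
        out = np.maximum(amount, 0.0)
        return float(out) if out.ndim == 0 else out


def headspace_co2_umol(mixing_ratio_ppm, headspace_ml, temperature_c, pressure_atm: float = 1.0):
    """Moles of CO2 (umol) in the headspace from its mixing ratio (ideal gas)."""
    v = np.asarray(headspace_ml, dtype=float)
    if np.any(v <= 0):
        raise ValueError("headspace volume must be positive")
    t = np.asarray(temperature_c, dtype=float)
    if np.any((t <= -20) | (t >= 60)):
        raise ValueError("temperature outside plausible incubation range")
    ppm = np.asarray(mixing_ratio_ppm, dtype=float)
    n_mol = ppm * 1e-6 * (v / 1000.0) * pressure_atm / (R_GAS * (t + 273.15))
    out = n_mol * 1e6
    return float(out) if out.ndim == 0 else out


def umol_to_ppm(n_umol, headspace_ml, temperature_c, pressure_atm: float = 1.0):
    """Inverse of :func:`headspace_co2_umol`."""
    total_umol = (
        pressure_atm * (np.asarray(headspace_ml, float) / 1000.0)
        / (R_GAS * (np.asarray(temperature_c, float) + 273.15))
        * 1e6
    )
    out = np.asarray(n_umol, float) / total_umol * 1e6
    return float(out) if np.ndim(out) == 0 else out


def dic_bottle_umol(dic_umol_subsample, subsample_ml, water_volume_ml):
    """Scale an acidified-subsample DIC amount up to the whole water column.

    delta-13C is unchanged by the scaling.
    """
    sub = np.asarray(subsample_ml, dtype=float)
    if np.any(sub <= 0):
        raise ValueError("subsample volume must be positive")
    out = np.asarray(dic_umol_subsample, float) * (
        np.asarray(water_volume_ml, float) / sub
    )
    return float(out) if np.ndim(out) == 0 else out


def withdrawal_corrected_total(excess_series, withdrawn_ml, headspace_ml):
    """Total labelled C delivered to the headspace, correcting for gas sampling.

    Each weekly sample removes the fraction w = withdrawn/headspace of the
    then-current pool. With E_k the before-withdrawal excess at time k, the
    labelled C arriving in interval k is R_k = E_k - (1-w) E_{k-1}, so the
    total ever delivered is E_K + w * sum_{k<K} E_k.

    Parameters
    ----------
    excess_series : array_like, shape (..., T)
        Excess carbon in the headspace at each sampling time, measured before
        that time's withdrawal.
    """
    e = np.asarray(excess_series, dtype=float)
    w = withdrawn_ml / headspace_ml
    if not 0 <= w < 1:
        raise ValueError("withdrawn volume must be smaller than the headspace")
    out = e[..., -1] + w * e[..., :-1].sum(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def gas_excess_mg(
    pool_umol,
    delta_co2,
    control_delta_mean,
    x_source,
    withdrawn_ml: float = 5.0,
    headspace_ml: float = 240.0,
    correct_withdrawals: bool = True,
):
    """Substrate-derived C (mg) respired into the headspace over the assay.

    Arrays carry time on the last axis; ``control_delta_mean`` must broadcast
    against ``delta_co2`` (typically the control-replicate mean per time
    point). Mixing is done in atom-fraction space on the unclamped fraction.
    """
    x_t = delta_to_atom_fraction(delta_co2)
    x_c = delta_to_atom_fraction(control_delta_mean)
    f = source_fraction(x_t, np.broadcast_to(x_c, np.shape(x_t)), x_source).f_raw
    excess = f * np.asarray(pool_umol, float) * C_MOLAR / 1000.0
    if correct_withdrawals:
        return withdrawal_corrected_total(excess, withdrawn_ml, headspace_ml)
    out = np.asarray(excess)[..., -1]
    return float(out) if np.ndim(out) == 0 else out


def dic_excess_mg(
    dic_umol_subsample,
    delta_dic,
    control_delta_mean,
    x_source,
    subsample_ml: float = 5.0,
    water_volume_ml: float = 300.0,
):
    """Substrate-derived C (mg) in the end-point DIC pool of the whole bottle."""
    pool_umol = dic_bottle_umol(dic_umol_subsample, subsample_ml, water_volume_ml)
    x_t = delta_to_atom_fraction(delta_dic)
    x_c = delta_to_atom_fraction(control_delta_mean)
    f = source_fraction(x_t, np.broadcast_to(x_c, np.shape(x_t)), x_source).f_raw
    out = f * pool_umol * C_MOLAR / 1000.0
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# rate units

_SCALE = {"%": 1.0, "permil": 10.0}
_PERIOD = {"month": MONTH_DAYS, "year": YEAR_DAYS}


def _parse_unit(unit: str):
    try:
        scale, period = unit.split("/")
        return _SCALE[scale], _PERIOD[period]
    except (ValueError, KeyError):
        raise ValueError(
            f"unknown rate unit {unit!r}; expected e.g. '%/month', 'permil/year'"
        ) from None


def convert_rate(value, from_unit: str, to_unit: str):
    """Convert between %/permil per month/year. Conversions are exact."""
    s0, p0 = _parse_unit(from_unit)
    s1, p1 = _parse_unit(to_unit)
    return np.asarray(value, float) * (s1 / s0) * (p1 / p0)


@dataclass
class RateEstimate:
    """A per-replicate rate with its dispersion.

    ``values`` holds one rate per replicate bottle in ``unit``; summary
    statistics use the sample standard deviation (n-1).
    """

    values: np.ndarray
    unit: str = "%/month"
    label: str = ""

    def __post_init__(self):
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        _parse_unit(self.unit)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        if self.n < 2:
            return float("nan")
        return float(np.std(self.values, ddof=1))

    @property
    def below_detection(self) -> bool:
        """True when mean - SD <= 0 (rate indistinguishable from zero)."""
        return self.n >= 2 and self.mean - self.sd <= 0.0

    def to(self, unit: str) -> "RateEstimate":
        return RateEstimate(
            convert_rate(self.values, self.unit, unit), unit=unit, label=self.label
        )

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"RateEstimate({self.mean:.4g} +/- {self.sd:.4g} {self.unit}, n={self.n})"


def mineralization_rate(
    excess_total_mg, added_c_mg: float, duration_days: float, unit: str = "%/month"
) -> RateEstimate:
    """Excess C as a rate: 100 * excess/added, normalized linearly in time.

    A month is 30.44 days and a year 365.25 days; the per mille unit is 10x
    the percent value.
    """
    if added_c_mg <= 0:
        raise ValueError("added substrate carbon must be positive")
    if duration_days <= 0:
        raise ValueError("incubation duration must be positive")
    frac = 100.0 * np.atleast_1d(np.asarray(excess_total_mg, float)) / added_c_mg
    per_month = frac * (MONTH_DAYS / duration_days)
    return RateEstimate(convert_rate(per_month, "%/month", unit), unit=unit)
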