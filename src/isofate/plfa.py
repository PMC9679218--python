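"""PLFA quantification and 13C assimilation into microbial biomass.

Phospholipid fatty acids (PLFAs) mark live microbial biomass; compound-specific
isotope analysis of individual PLFAs traces labelled substrate carbon into the
community, and particular compounds attribute it to microbial groups (16:1w7
and 18:1w7 to Alpha/Gammaproteobacteria, 18:1w9 to Planctomycetes and fungi,
18:2w6 to fungi, 16:1w9 to Spumella-like flagellates).

Amounts are measured by GC-MS against a multi-point reference-standard curve
and corrected for extraction losses by the recovery of the C19:0 / C23:0
internal standards. Assimilated carbon is obtained per compound by two-pool
mixing against the control-bottle mean profile, summed, and scaled from PLFA
carbon to total biomass carbon with the conversion factor
``f_plfa_of_biomass`` (PLFA-C / biomass-C, default 0.056).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .isotope import delta_to_atom_fraction, source_fraction
from .mineralization import CalibrationCurve, MONTH_DAYS, RateEstimate, convert_rate

#: Controlled vocabulary: compound -> (carbon atoms, double bonds).
#: BrSFA is a pooled branched-saturated pseudo-compound with a representative
#: C16 saturated formula. C19:0 and C23:0 are internal standards and are
#: excluded from biomass totals.
FATTY_ACIDS: dict[str, tuple[int, int]] = {
    "i14:0": (14, 0),
    "14:0": (14, 0),
    "i15:0": (15, 0),
    "a15:0": (15, 0),
    "15:0": (15, 0),
    "16:0": (16, 0),
    "16:1w9": (16, 1),
    "16:1w7": (16, 1),
    "17:0": (17, 0),
    "18:0": (18, 0),
    "18:1w9": (18, 1),
    "18:1w7": (18, 1),
    "18:2w6": (18, 2),
    "BrSFA": (16, 0),
    "19:0": (19, 0),
    "23:0": (23, 0),
}

INTERNAL_STANDARDS = ("19:0", "23:0")

_H = 1.008
_O = 15.999
_C = 12.011


class PLFAError(ValueError):
    """Invalid PLFA input (unknown compound, failed QC, empty overlap)."""


def normalize_compound(name: str) -> str:
    """Canonical compound key: unicode omega -> 'w', strip 'C' prefixes."""
    name = name.strip().replace("ω", "w")
    if name.upper() == "BULK":
        return "BULK"
    if name.startswith(("C", "c")) and ":" in name:
        name = name[1:]
    return name


def carbon_fraction(compound: str) -> float:
    """Mass fraction of carbon in a fatty acid, from its molecular formula.

    A saturated acid is CnH(2n)O2; each double bond removes two hydrogens.
    """
    key = normalize_compound(compound)
    if key not in FATTY_ACIDS:
        raise PLFAError(f"unknown fatty acid {compound!r}")
    n, db = FATTY_ACIDS[key]
    h = 2 * n - 2 * db
    mw = _C * n + _H * h + _O * 2
    return _C * n / mw


def quantify_fatty_acids(
    peak_areas: dict,
    curves: dict,
    internal_standard_measured: dict,
    internal_standard_added: dict,
    recovery_bounds: tuple = (0.0, 1.5),
) -> dict:
    """Amounts from peak areas via standard curves and internal-standard recovery.

    amount = curve(area) / recovery, where recovery is the mean of
    measured/added over the C19:0 and C23:0 internal standards.

    Raises
    ------
    PLFAError
        If recovery is <= 0 or above the QC ceiling (default 1.5).
    """
    ratios = []
    for std in INTERNAL_STANDARDS:
        if std in internal_standard_measured and std in internal_standard_added:
            added = internal_standard_added[std]
            if added <= 0:
                raise PLFAError(f"added internal standard {std} must be positive")
            ratios.append(internal_standard_measured[std] / added)
    if not ratios:
        raise PLFAError("no internal-standard recovery available")
    recovery = float(np.mean(ratios))
    lo, hi = recovery_bounds
    if recovery <= lo or recovery > hi:
        raise PLFAError(f"internal-standard recovery {recovery:.3f} fails QC bounds {recovery_bounds}")
    amounts = {}
    for compound, area in peak_areas.items():
        key = normalize_compound(compound)
        if key not in curves:
            raise PLFAError(f"no calibration curve for {compound!r}")
        curve: CalibrationCurve = curves[key]
        amounts[key] = curve.predict(area) / recovery
    return amounts


def delta_delta(treatment_delta: dict, control_delta: dict) -> dict:
    """Per-compound label uptake: delta-13C(treatment) - delta-13C(control).

    Compounds absent from either profile are dropped (with a warning); an
    empty intersection is an error.
    """
    t = {normalize_compound(k): v for k, v in treatment_delta.items()}
    c = {normalize_compound(k): v for k, v in control_delta.items()}
    shared = [k for k in t if k in c]
    if not shared:
        raise PLFAError("treatment and control profiles share no compounds")
    dropped = (set(t) | set(c)) - set(shared)
    if dropped:
        warnings.warn(f"compounds present on one side only were dropped: {sorted(dropped)}")
    return {k: t[k] - c[k] for k in shared}


def plfa_excess_mg(amount_c_mg, delta, control_delta_mean, x_source):
    """Substrate-derived PLFA carbon (mg), summed over compounds.

    Arrays carry compounds on the last axis; mixing uses the unclamped
    atom-fraction mixing fraction against the control mean profile.
    """
    x_t = delta_to_atom_fraction(delta)
    x_c = delta_to_atom_fraction(control_delta_mean)
    f = source_fraction(x_t, np.broadcast_to(x_c, np.shape(x_t)), x_source).f_raw
    out = (f * np.asarray(amount_c_mg, float)).sum(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class AssimilationEstimate:
    """Labelled carbon recovered in PLFAs, scaled to whole biomass."""

    excess_c_plfa_mg: float
    excess_c_biomass_mg: float
    rate: RateEstimate | None = None


def assimilated_carbon(
    amounts_mg: dict,
    delta_t: dict,
    control_delta: dict,
    x_source: float,
    f_plfa_of_biomass: float = 0.056,
    amounts_are_carbon: bool = False,
) -> AssimilationEstimate:
    """Per-compound mixing -> total assimilated biomass carbon.

    Parameters
    ----------
    amounts_mg : mapping compound -> amount (mg of fatty acid, or mg C when
        ``amounts_are_carbon``); internal standards are ignored.
    delta_t, control_delta : mapping compound -> delta-13C (per mille). Use a
        single key ``"BULK"`` with the total PLFA amount for bulk mode.
    x_source : atom fraction of the labelled substrate.
    f_plfa_of_biomass : PLFA carbon as a fraction of total biomass carbon.
    """
    if not 0 < f_plfa_of_biomass <= 1:
        raise PLFAError("f_plfa_of_biomass must lie in (0, 1]")
    dd = delta_delta(delta_t, control_delta)  # validates the shared set
    amounts = {normalize_compound(k): v for k, v in amounts_mg.items()}
    shared = [k for k in dd if k in amounts and k not in INTERNAL_STANDARDS]
    if not shared:
        raise PLFAError("no quantified compounds overlap the isotope profiles")
    t_norm = {normalize_compound(k): v for k, v in delta_t.items()}
    c_norm = {normalize_compound(k): v for k, v in control_delta.items()}
    amount_c = np.array(
        [
            amounts[k] * (1.0 if (amounts_are_carbon or k == "BULK") else carbon_fraction(k))
            for k in shared
        ]
    )
    deltas = np.array([t_norm[k] for k in shared])
    ctrl = np.array([c_norm[k] for k in shared])
    excess_plfa = plfa_excess_mg(amount_c, deltas, ctrl, x_source)
    return AssimilationEstimate(
        excess_c_plfa_mg=float(excess_plfa),
        excess_c_biomass_mg=float(excess_plfa / f_plfa_of_biomass),
    )


def assimilation_rate(
    excess_biomass_mg, added_c_mg: float, duration_days: float, unit: str = "%/month"
) -> RateEstimate:
    """Biomass excess C as a rate on the same convention as mineralization."""
    if added_c_mg <= 0 or duration_days <= 0:
        raise ValueError("added carbon and duration must be positive")
    frac = 100.0 * np.atleast_1d(np.asarray(excess_biomass_mg, float)) / added_c_mg
    per_month = frac * (MONTH_DAYS / duration_days)
    return RateEstimate(convert_rate(per_month, "%/month", unit), unit=unit)


def bacterial_growth_efficiency(assimilated_mg, respired_mg):
    """BGE = assimilated / (assimilated + respired).

    Returns NaN (with a warning) when neither pathway received any carbon,
    i.e. the substrate was not decomposed.
    """
    a = np.asarray(assimilated_mg, float)
    r = np.asarray(respired_mg, float)
    total = a + r
    if np.all(np.asarray(total) == 0.0):
        warnings.warn("substrate not decomposed: BGE undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, a / np.where(total == 0, np.nan, total), np.nan)
    return float(out) if np.ndim(out) == 0 else out
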