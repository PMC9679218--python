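"""Total decomposition rate, decomposition time, and biochemical fate.

The decomposition rate is the sum of the mineralization rate (CO2 + DIC) and
the assimilation rate (biomass) on a common unit; the decomposition time is
100 divided by the percentual rate. The biochemical fate expresses each
end-product's excess carbon as a percentage of the decomposed total, so the
biomass fate fraction divided by 100 is identically the bacterial growth
efficiency.

Summaries run per replicate bottle first and aggregate afterwards: time
intervals such as "500 +/- 150 years" are the mean and SD of per-replicate
100/D values, not 100/(mean D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mineralization import RateEstimate, convert_rate

#: reporting cap for decomposition times (years)
DEFAULT_CAP_YEARS = 1e4


@dataclass(frozen=True)
class ReplicateStats:
    mean: float
    sd: float
    n: int

    def __str__(self):
        sd = "NA" if np.isnan(self.sd) else f"{self.sd:.3g}"
        return f"{self.mean:.3g} +/- {sd} (n={self.n})"


def replicate_stats(values) -> ReplicateStats:
    """Arithmetic mean and sample SD (n-1); SD is NaN for a single replicate."""
    v = np.atleast_1d(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("no replicate values")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
    return ReplicateStats(mean=float(np.mean(v)), sd=sd, n=v.size)


def total_rate(mineralization: RateEstimate, assimilation: RateEstimate, unit: str = "%/year") -> RateEstimate:
    """Per-replicate sum D = M + A, harmonized to one unit."""
    m = mineralization.to(unit).values
    a = assimilation.to(unit).values
    if m.size != a.size:
        raise ValueError(
            f"replicate mismatch: {m.size} mineralization vs {a.size} assimilation values"
        )
    return RateEstimate(m + a, unit=unit, label="decomposition")


@dataclass(frozen=True)
class DecompositionTime:
    """100/rate with sentinels for undegraded and beyond-cap substrates."""

    years: float
    degraded: bool = True
    capped: bool = False
    cap_years: float = DEFAULT_CAP_YEARS

    def __str__(self):
        if not self.degraded:
            return "not degraded"
        if self.capped:
            return f">{self.cap_years:,.0f} years"
        if self.years < 1.0:
            return f"{self.years * 12:.1f} months"
        return f"{self.years:,.1f} years"


def decomposition_time(rate_pct_per_year: float, cap_years: float = DEFAULT_CAP_YEARS) -> DecompositionTime:
    """Decomposition time in years: 100 / (rate in % per year).

    A non-positive rate yields the "not degraded" sentinel; times beyond the
    reporting cap (10,000 years by default) are reported as ">cap".
    """
    rate = float(rate_pct_per_year)
    if not np.isfinite(rate):
        raise ValueError("rate must be finite")
    if rate <= 0.0:
        return DecompositionTime(years=float("inf"), degraded=False, cap_years=cap_years)
    years = 100.0 / rate
    return DecompositionTime(years=years, capped=years > cap_years, cap_years=cap_years)


@dataclass(frozen=True)
class FatePartition:
    """Percentages of decomposed substrate carbon by end product."""

    pct_co2: float
    pct_dic: float
    pct_biomass: float
    decomposed: bool = True

    @property
    def bge(self) -> float:
        """Bacterial growth efficiency: biomass fate fraction / 100."""
        return self.pct_biomass / 100.0 if self.decomposed else float("nan")

    def __str__(self):
        if not self.decomposed:
            return "not decomposed"
        return (
            f"CO2 {self.pct_co2:.1f}% | DIC {self.pct_dic:.1f}% | "
            f"biomass {self.pct_biomass:.1f}%"
        )


def fate_partition(excess_co2_mg, excess_dic_mg, excess_biomass_mg) -> FatePartition:
    """Partition decomposed carbon among CO2 gas, DIC, and biomass.

    Negative inputs (noise around zero uptake) are clamped to zero before
    normalization. A zero total returns the "not decomposed" sentinel.
    """
    parts = np.maximum(
        np.asarray([excess_co2_mg, excess_dic_mg, excess_biomass_mg], dtype=float), 0.0
    )
    total = parts.sum()
    if total <= 0.0:
        return FatePartition(0.0, 0.0, 0.0, decomposed=False)
    pct = parts / total * 100.0
    return FatePartition(*map(float, pct))


@dataclass
class DecompositionSummary:
    """Replicate-level and aggregated decomposition summary for one treatment."""

    substrate: str
    water: str
    mineralization: RateEstimate
    assimilation: RateEstimate
    decomposition: RateEstimate
    time_years: ReplicateStats
    time_display: DecompositionTime
    fate: FatePartition
    bge: float

    @property
    def below_detection(self) -> bool:
        return self.decomposition.below_detection


def summarize(
    substrate: str,
    water: str,
    mineralization: RateEstimate,
    assimilation: RateEstimate,
    excess_co2_mg,
    excess_dic_mg,
    excess_biomass_mg,
    cap_years: float = DEFAULT_CAP_YEARS,
) -> DecompositionSummary:
    """Assemble the full decomposition summary from per-replicate pieces."""
    decomp = total_rate(mineralization, assimilation, unit="%/year")
    times = [decomposition_time(r, cap_years) for r in decomp.values]
    finite = [t.years for t in times if t.degraded]
    time_stats = (
        replicate_stats(finite) if finite else ReplicateStats(float("nan"), float("nan"), 0)
    )
    time_display = decomposition_time(decomp.mean, cap_years)
    fate = fate_partition(
        float(np.sum(np.maximum(excess_co2_mg, 0.0))),
        float(np.sum(np.maximum(excess_dic_mg, 0.0))),
        float(np.sum(np.maximum(excess_biomass_mg, 0.0))),
    )
    return DecompositionSummary(
        substrate=substrate,
        water=water,
        mineralization=mineralization,
        assimilation=assimilation,
        decomposition=decomp,
        time_years=time_stats,
        time_display=time_display,
        fate=fate,
        bge=fate.bge,
    )
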