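"""Model/results facade over the tracer-accounting pipeline.

`TracerExperiment` is built from the three measurement tables of one
closed-bottle experiment (weekly headspace gas, end-point DIC, end-point PLFA
profiles) plus the experiment configuration; `.fit()` runs the full
estimation — excess carbon in CO2, DIC and biomass per replicate bottle,
mineralization/assimilation/decomposition rates, decomposition time, fate
partition and BGE — and returns a `TracerResults` with a summary() table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import (
    DecompositionSummary,
    decomposition_time,
    fate_partition,
    replicate_stats,
    summarize,
)
from .isotope import atom_fraction_to_delta, delta_to_atom_fraction
from .mineralization import (
    MONTH_DAYS,
    RateEstimate,
    dic_excess_mg,
    gas_excess_mg,
    headspace_co2_umol,
    mineralization_rate,
)
from .plfa import assimilation_rate, carbon_fraction, normalize_compound, plfa_excess_mg


class ValidationError(ValueError):
    """Input tables fail cross-reference or schema checks."""


@dataclass
class ExperimentConfig:
    """Design constants for one treatment (geometry, label, duration)."""

    substrate: str = "leaf"
    water: str = "humic"
    label_atom_percent: float = 13.4
    added_c_mg: float = 4.0
    bottle_volume_ml: float = 540.0
    water_volume_ml: float = 300.0
    gas_sample_ml: float = 5.0
    temperature_c: float = 17.5
    duration_days: float = 21.0
    f_plfa_of_biomass: float = 0.056
    cap_years: float = 1e4

    @property
    def headspace_ml(self) -> float:
        return self.bottle_volume_ml - self.water_volume_ml

    @property
    def x_source(self) -> float:
        return self.label_atom_percent / 100.0

    @classmethod
    def from_scenario(cls, scenario) -> "ExperimentConfig":
        return cls(
            substrate=scenario.substrate,
            water=scenario.water,
            label_atom_percent=scenario.label_atom_percent,
            added_c_mg=scenario.added_c_mg,
            bottle_volume_ml=scenario.bottle_volume_ml,
            water_volume_ml=scenario.water_volume_ml,
            gas_sample_ml=scenario.gas_sample_ml,
            temperature_c=scenario.temperature_c,
            duration_days=scenario.duration_days,
            f_plfa_of_biomass=scenario.f_plfa_of_biomass,
        )


_GAS_COLS = {"bottle_id", "role", "day", "delta13C_co2"}
_DIC_COLS = {"bottle_id", "role", "subsample_ml", "dic_umol", "delta13C_dic"}
_PLFA_COLS = {"bottle_id", "role", "compound", "amount_mg", "delta13C"}


class TracerExperiment:
    """A 13C closed-bottle tracer experiment ready to be fit.

    Parameters
    ----------
    gas : DataFrame with columns bottle_id, role, day, co2_ppm (or pool_umol),
        delta13C_co2; one row per bottle x sampling day.
    dic : DataFrame with columns bottle_id, role, subsample_ml, dic_umol,
        delta13C_dic; one end-point row per bottle.
    plfa : DataFrame with columns bottle_id, role, compound, amount_mg,
        delta13C; end-point per-compound rows per bottle (optional: None
        skips assimilation).
    config : ExperimentConfig
    """

    def __init__(self, gas: pd.DataFrame, dic: pd.DataFrame, plfa: pd.DataFrame | None, config: ExperimentConfig):
        self.gas = gas.copy()
        self.dic = dic.copy()
        self.plfa = plfa.copy() if plfa is not None else None
        self.config = config
        self._validate()

    @classmethod
    def from_frames(cls, gas, dic, plfa=None, config: ExperimentConfig | None = None):
        return cls(gas, dic, plfa, config or ExperimentConfig())

    @classmethod
    def from_simulation(cls, sim) -> "TracerExperiment":
        """Build directly from a :class:`~isofate.simulate.SimulatedExperiment`."""
        return cls(sim.gas, sim.dic, sim.plfa, ExperimentConfig.from_scenario(sim.config))

    @classmethod
    def from_files(cls, gas_path, dic_path, plfa_path=None, config_path=None):
        from .io import read_config, read_table

        config = read_config(config_path) if config_path else ExperimentConfig()
        plfa = read_table(plfa_path) if plfa_path else None
        return cls(read_table(gas_path), read_table(dic_path), plfa, config)

    # -- validation --------------------------------------------------------

    def _validate(self):
        problems = []
        for name, df, required in (
            ("gas", self.gas, _GAS_COLS),
            ("dic", self.dic, _DIC_COLS),
        ):
            missing = required - set(df.columns)
            if missing:
                problems.append(f"{name} table missing columns {sorted(missing)}")
        if "co2_ppm" not in self.gas.columns and "pool_umol" not in self.gas.columns:
            problems.append("gas table needs a co2_ppm or pool_umol column")
        if self.plfa is not None:
            missing = _PLFA_COLS - set(self.plfa.columns)
            if missing:
                problems.append(f"plfa table missing columns {sorted(missing)}")
        if problems:
            raise ValidationError("; ".join(problems))
        roles = set(self.gas["role"].unique())
        if "control" not in roles:
            raise ValidationError(
                f"no control bottles for {self.config.water} water: "
                "the background isotope endpoint cannot be formed"
            )
        if "treatment" not in roles:
            raise ValidationError("no treatment bottles in the gas table")
        gas_ids = set(self.gas["bottle_id"])
        dic_ids = set(self.dic["bottle_id"])
        if not dic_ids <= gas_ids:
            raise ValidationError(f"DIC bottles absent from gas table: {sorted(dic_ids - gas_ids)}")

    # -- fitting -----------------------------------------------------------

    def _gas_pools(self, sub: pd.DataFrame):
        """(bottles x days) pool [umol] and delta pivot tables."""
        cfg = self.config
        if "pool_umol" in sub.columns:
            pool = sub.pivot(index="bottle_id", columns="day", values="pool_umol")
        else:
            ppm = sub.pivot(index="bottle_id", columns="day", values="co2_ppm")
            pool = headspace_co2_umol(ppm, cfg.headspace_ml, cfg.temperature_c)
            pool = pd.DataFrame(pool, index=ppm.index, columns=ppm.columns)
        delta = sub.pivot(index="bottle_id", columns="day", values="delta13C_co2")
        return pool.sort_index(axis=1), delta.sort_index(axis=1)

    def fit(self, correct_withdrawals: bool = True, unit: str = "%/month") -> "TracerResults":
        cfg = self.config
        gas_t = self.gas[self.gas["role"] == "treatment"]
        gas_c = self.gas[self.gas["role"] == "control"]
        pool_t, delta_t = self._gas_pools(gas_t)
        pool_c, delta_c = self._gas_pools(gas_c)
        if list(pool_t.columns) != list(pool_c.columns):
            raise ValidationError("treatment and control gas time grids differ")

        ctrl_delta = atom_fraction_to_delta(
            delta_to_atom_fraction(delta_c.to_numpy()).mean(axis=0)
        )
        excess_gas = gas_excess_mg(
            pool_t.to_numpy(),
            delta_t.to_numpy(),
            ctrl_delta,
            cfg.x_source,
            withdrawn_ml=cfg.gas_sample_ml,
            headspace_ml=cfg.headspace_ml,
            correct_withdrawals=correct_withdrawals,
        )

        dic_t = self.dic[self.dic["role"] == "treatment"].set_index("bottle_id").loc[pool_t.index]
        dic_c = self.dic[self.dic["role"] == "control"]
        ctrl_dic_delta = atom_fraction_to_delta(
            delta_to_atom_fraction(dic_c["delta13C_dic"].to_numpy()).mean()
        )
        excess_dic = dic_excess_mg(
            dic_t["dic_umol"].to_numpy(),
            dic_t["delta13C_dic"].to_numpy(),
            ctrl_dic_delta,
            cfg.x_source,
            subsample_ml=float(dic_t["subsample_ml"].iloc[0]),
            water_volume_ml=cfg.water_volume_ml,
        )

        m_rate = mineralization_rate(
            excess_gas + excess_dic, cfg.added_c_mg, cfg.duration_days, unit="%/month"
        )

        if self.plfa is not None:
            excess_biomass = self._fit_plfa(pool_t.index)
            a_rate = assimilation_rate(
                excess_biomass, cfg.added_c_mg, cfg.duration_days, unit="%/month"
            )
        else:
            excess_biomass = np.zeros(len(pool_t.index))
            a_rate = RateEstimate(excess_biomass, unit="%/month")

        summary = summarize(
            cfg.substrate,
            cfg.water,
            m_rate,
            a_rate,
            excess_gas,
            excess_dic,
            excess_biomass,
            cap_years=cfg.cap_years,
        )
        replicates = pd.DataFrame(
            {
                "bottle_id": pool_t.index,
                "excess_co2_mg": excess_gas,
                "excess_dic_mg": excess_dic,
                "excess_biomass_mg": excess_biomass,
                "mineralization_pct_month": m_rate.values,
                "assimilation_pct_month": a_rate.values,
            }
        ).set_index("bottle_id")
        return TracerResults(self, summary, replicates, unit=unit)

    def _fit_plfa(self, treatment_index) -> np.ndarray:
        cfg = self.config
        df = self.plfa.copy()
        df["compound"] = df["compound"].map(normalize_compound)
        df = df[df["compound"] != "BULK"]
        piv_amt = df.pivot_table(index="bottle_id", columns="compound", values="amount_mg")
        piv_del = df.pivot_table(index="bottle_id", columns="compound", values="delta13C")
        ctrl_ids = df.loc[df["role"] == "control", "bottle_id"].unique()
        if len(ctrl_ids) == 0:
            raise ValidationError("no control bottles in the PLFA table")
        ctrl_delta = atom_fraction_to_delta(
            delta_to_atom_fraction(piv_del.loc[ctrl_ids].to_numpy()).mean(axis=0)
        )
        cfrac = np.array([carbon_fraction(c) for c in piv_amt.columns])
        amount_c = piv_amt.loc[treatment_index].to_numpy() * cfrac
        excess_plfa = plfa_excess_mg(
            amount_c, piv_del.loc[treatment_index].to_numpy(), ctrl_delta, cfg.x_source
        )
        return excess_plfa / cfg.f_plfa_of_biomass


class TracerResults:
    """Fitted estimates for one treatment, with replicate-level detail."""

    def __init__(self, model: TracerExperiment, summary: DecompositionSummary, replicates: pd.DataFrame, unit: str = "%/month"):
        self.model = model
        self._summary = summary
        self.replicates = replicates
        self.unit = unit

    # convenient accessors
    @property
    def mineralization(self) -> RateEstimate:
        return self._summary.mineralization.to(self.unit)

    @property
    def assimilation(self) -> RateEstimate:
        return self._summary.assimilation.to(self.unit)

    @property
    def decomposition(self) -> RateEstimate:
        return self._summary.decomposition.to(self.unit)

    @property
    def time(self):
        return self._summary.time_display

    @property
    def time_years(self):
        return self._summary.time_years

    @property
    def fate(self):
        return self._summary.fate

    @property
    def bge(self) -> float:
        return self._summary.bge

    @property
    def below_detection(self) -> bool:
        return self._summary.below_detection

    def summary(self) -> str:
        s = self._summary
        m, a, d = s.mineralization, s.assimilation, s.decomposition
        lines = [
            "13C tracer decomposition accounting",
            "=" * 52,
            f"substrate: {s.substrate:<22} water: {s.water}",
            f"replicates: {m.n}",
            "-" * 52,
            f"mineralization  {m.mean:12.4g} +/- {m.sd:<10.3g} {m.unit}",
            f"assimilation    {a.mean:12.4g} +/- {a.sd:<10.3g} {a.unit}",
            f"decomposition   {d.mean:12.4g} +/- {d.sd:<10.3g} {d.unit}",
            f"decomposition time: {s.time_display}",
            f"fate: {s.fate}",
            f"BGE: {s.bge:.3f}" if np.isfinite(s.bge) else "BGE: undefined (not decomposed)",
        ]
        if s.below_detection:
            lines.append("flag: rate below detection (mean - SD <= 0)")
        return "\n".join(lines)

    def to_frames(self) -> dict:
        """rates and fate tables in the pipeline's TSV dialect."""
        s = self._summary
        rates = pd.DataFrame(
            [
                {
                    "substrate": s.substrate,
                    "water": s.water,
                    "mineralization_pct_month": s.mineralization.mean,
                    "mineralization_sd": s.mineralization.sd,
                    "assimilation_pct_month": s.assimilation.mean,
                    "assimilation_sd": s.assimilation.sd,
                    "decomposition_pct_year": s.decomposition.mean,
                    "decomposition_sd": s.decomposition.sd,
                    "time": str(s.time_display),
                    "below_detection": s.below_detection,
                    "n": s.mineralization.n,
                }
            ]
        )
        fate = pd.DataFrame(
            [
                {
                    "substrate": s.substrate,
                    "water": s.water,
                    "pct_co2": s.fate.pct_co2,
                    "pct_dic": s.fate.pct_dic,
                    "pct_biomass": s.fate.pct_biomass,
                    "bge": s.bge,
                    "decomposed": s.fate.decomposed,
                }
            ]
        )
        return {"rates": rates, "fate": fate, "replicates": self.replicates.reset_index()}
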