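"""Forward simulation of closed-bottle tracer experiments with known truth.

The generator is the inverse of the estimation pipeline: a scenario fixes a
true mineralization and assimilation rate for a substrate/water combination,
labelled carbon is respired into the headspace/DIC and assimilated into PLFA
pools by exact atom-fraction mixing, measurement noise is added, and the
resulting tables have exactly the shape of the real assay (weekly gas samples
with 5 mL withdrawals, end-point DIC subsample, per-compound PLFA profiles,
and matched no-substrate control bottles).

Array-valued helpers (``simulate_gas_arrays`` etc.) vectorize over whole
batches of independent experiments for recovery studies; ``simulate_bottles``
wraps a single experiment into the CSV-dialect data frames the pipeline reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .isotope import atom_fraction_to_delta, delta_to_atom_fraction
from .mineralization import C_MOLAR, MONTH_DAYS, umol_to_ppm
from .plfa import carbon_fraction


class ScenarioError(ValueError):
    pass


#: Default distribution of baseline PLFA carbon over compounds (fractions of
#: total PLFA-C in an unamended lake-water community).
BASELINE_PLFA_WEIGHTS = {
    "i14:0": 0.04,
    "i15:0": 0.08,
    "a15:0": 0.08,
    "16:0": 0.22,
    "16:1w9": 0.05,
    "16:1w7": 0.16,
    "18:0": 0.08,
    "18:1w9": 0.10,
    "18:1w7": 0.12,
    "18:2w6": 0.04,
    "BrSFA": 0.03,
}

#: Which PLFA compounds receive the assimilated label, per substrate: the
#: biomarker attribution of decomposer groups (16:1w7/18:1w7 for
#: Alpha/Gammaproteobacteria, 18:1w9 for Planctomycetes, 16:1w9 for
#: Spumella-like flagellates, 18:2w6 for fungi).
BIOMARKER_WEIGHTS = {
    "leaf": {"16:1w7": 0.30, "18:1w7": 0.20, "18:1w9": 0.15, "i15:0": 0.10,
             "a15:0": 0.10, "i14:0": 0.05, "BrSFA": 0.10},
    "lignin_hemicellulose": {"i14:0": 0.20, "i15:0": 0.20, "a15:0": 0.20,
                             "16:1w7": 0.25, "18:1w7": 0.15},
    "PS": {"16:1w7": 0.45, "18:1w7": 0.35, "16:1w9": 0.20},
    "PP": {"16:1w9": 0.40, "18:1w9": 0.60},
    "PE": {"16:1w9": 0.40, "18:1w9": 0.60},
}


@dataclass
class ScenarioConfig:
    """Study conditions for one substrate x water treatment.

    Rates are end-point conventions: the true rate R (% of added C per month)
    fixes the cumulative amount processed by the end of the incubation,
    ``added_c * R/100 * duration/30.44``; the kinetic shape only distributes
    it over time (saturating mimics the rapid first-week signal of humic
    water, linear the steady rise of clear water).
    """

    substrate: str = "leaf"
    water: str = "humic"
    mineralization_pct_month: float = 9.0
    assimilation_pct_month: float = 14.0
    kinetics: str = "saturating"  # or "linear"
    k_sat_per_day: float = 0.3
    label_atom_percent: float = 13.4
    added_c_mg: float = 4.0
    n_replicates: int = 4
    n_controls: int = 4
    duration_days: int = 21
    sampling_interval_days: int = 7
    bottle_volume_ml: float = 540.0
    water_volume_ml: float = 300.0
    gas_sample_ml: float = 5.0
    dic_subsample_ml: float = 5.0
    temperature_c: float = 17.5
    # noise
    sigma_delta: float = 0.2          # permil, IRMS precision on every delta
    co2_cv: float = 0.02              # relative noise on CO2 quantification
    amount_cv: float = 0.05           # relative noise on PLFA amounts
    replicate_rate_cv: float = 0.10   # biological rate variation among bottles
    # background chemistry
    doc_mg_per_l: float = 22.6
    background_respired_fraction: float = 0.05  # of DOC over the incubation
    f_gas: float = 0.4                # respired C appearing in the headspace
    air_co2_ppm: float = 420.0
    delta_air: float = -8.5
    delta_doc: float = -27.0
    dic0_umol: float = 90.0
    delta_dic0: float = -14.0
    # biomass / PLFA
    baseline_biomass_mg_c: float = 0.3
    f_plfa_of_biomass: float = 0.056
    delta_biomass: float = -30.0
    seed: int | None = None

    @property
    def headspace_ml(self) -> float:
        return self.bottle_volume_ml - self.water_volume_ml

    @property
    def x_source(self) -> float:
        return self.label_atom_percent / 100.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(
            self.sampling_interval_days, self.duration_days + 1, self.sampling_interval_days
        )

    def validate(self) -> "ScenarioConfig":
        if self.headspace_ml <= 0:
            raise ScenarioError("headspace volume must be positive")
        if self.mineralization_pct_month < 0 or self.assimilation_pct_month < 0:
            raise ScenarioError("rates must be non-negative")
        processed = (
            (self.mineralization_pct_month + self.assimilation_pct_month)
            / 100.0
            * self.duration_days
            / MONTH_DAYS
        )
        if processed > 1.0:
            raise ScenarioError(
                f"impossible mass balance: {processed:.2f} of the added C "
                "respired+assimilated by the end of the incubation"
            )
        if not 0 < self.x_source < 1:
            raise ScenarioError("label atom percent must lie in (0, 100)")
        if self.sigma_delta <= 0:
            raise ScenarioError("sigma_delta must be positive")
        return self


def _pm(permil_per_year: float) -> float:
    """Printed per-mille-per-year rate -> % per month."""
    return permil_per_year / 10.0 / 12.0


#: Scenario presets for the study's substrate x water grid. Mineralization
#: truths are the treatment-level rates the assay reports; assimilation truths
#: for hemicellulose are back-derived from the biomass fate fraction.
SCENARIOS: dict[str, ScenarioConfig] = {
    "humic_leaf": ScenarioConfig(
        substrate="leaf", water="humic", mineralization_pct_month=9.0,
        assimilation_pct_month=14.0, label_atom_percent=13.4,
        duration_days=21, kinetics="saturating",
    ),
    "clear_leaf": ScenarioConfig(
        substrate="leaf", water="clear", mineralization_pct_month=4.0,
        assimilation_pct_month=51.0, label_atom_percent=13.4,
        duration_days=21, kinetics="linear", doc_mg_per_l=5.19,
    ),
    "humic_hemicellulose": ScenarioConfig(
        substrate="lignin_hemicellulose", water="humic",
        mineralization_pct_month=11.9, assimilation_pct_month=22.0,
        label_atom_percent=97.0, duration_days=42, kinetics="saturating",
    ),
    "clear_hemicellulose": ScenarioConfig(
        substrate="lignin_hemicellulose", water="clear",
        mineralization_pct_month=7.3, assimilation_pct_month=53.5,
        label_atom_percent=97.0, duration_days=42, kinetics="linear",
        doc_mg_per_l=5.19,
    ),
    "humic_ps": ScenarioConfig(
        substrate="PS", water="humic", mineralization_pct_month=_pm(0.22),
        assimilation_pct_month=0.2 / 12.0, label_atom_percent=99.0,
        duration_days=42, kinetics="saturating",
    ),
    "clear_ps": ScenarioConfig(
        substrate="PS", water="clear", mineralization_pct_month=_pm(0.17),
        assimilation_pct_month=0.1 / 12.0, label_atom_percent=99.0,
        duration_days=42, kinetics="linear", doc_mg_per_l=5.19,
    ),
    "humic_pp": ScenarioConfig(
        substrate="PP", water="humic", mineralization_pct_month=0.0,
        assimilation_pct_month=0.0, label_atom_percent=99.0,
        duration_days=42, kinetics="saturating",
    ),
    "clear_pp": ScenarioConfig(
        substrate="PP", water="clear", mineralization_pct_month=_pm(0.006),
        assimilation_pct_month=0.003 / 12.0, label_atom_percent=99.0,
        duration_days=42, kinetics="linear", doc_mg_per_l=5.19,
    ),
    "humic_pe": ScenarioConfig(
        substrate="PE", water="humic", mineralization_pct_month=_pm(0.003),
        assimilation_pct_month=0.1 / 12.0, label_atom_percent=99.0,
        duration_days=42, kinetics="saturating",
    ),
    "clear_pe": ScenarioConfig(
        substrate="PE", water="clear", mineralization_pct_month=_pm(0.005),
        assimilation_pct_month=0.04 / 12.0, label_atom_percent=99.0,
        duration_days=42, kinetics="linear", doc_mg_per_l=5.19,
    ),
    "null": ScenarioConfig(
        substrate="PP", water="humic", mineralization_pct_month=0.0,
        assimilation_pct_month=0.0, label_atom_percent=97.0,
        duration_days=42, kinetics="linear", replicate_rate_cv=0.0,
    ),
}


def get_scenario(name: str, **overrides) -> ScenarioConfig:
    if name not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    return replace(SCENARIOS[name], **overrides).validate()


def _shape(cfg: ScenarioConfig, t: np.ndarray) -> np.ndarray:
    """Cumulative fraction of the end-point total processed by time t."""
    t_end = cfg.duration_days
    if cfg.kinetics == "saturating":
        k = cfg.k_sat_per_day
        return (1.0 - np.exp(-k * t)) / (1.0 - np.exp(-k * t_end))
    if cfg.kinetics == "linear":
        return t / t_end
    raise ScenarioError(f"unknown kinetics {cfg.kinetics!r}")


def _per_bottle_rates(cfg: ScenarioConfig, n_exp: int, n_rep: int, rng) -> np.ndarray:
    """True per-bottle rates: mean-preserving biological variation, >= 0."""
    base = np.array([cfg.mineralization_pct_month, cfg.assimilation_pct_month])
    if cfg.replicate_rate_cv <= 0:
        return np.broadcast_to(base, (n_exp, n_rep, 2)).copy()
    noise = 1.0 + cfg.replicate_rate_cv * rng.standard_normal((n_exp, n_rep, 2))
    return np.maximum(base * noise, 0.0)


def simulate_gas_arrays(cfg: ScenarioConfig, n_experiments: int, rng, rates=None):
    """Headspace and DIC measurements for treatment and control bottles.

    Returns a dict of arrays; treatment arrays have shape
    (n_experiments, n_replicates[, T]) and control arrays
    (n_experiments, n_controls[, T]).
    """
    cfg.validate()
    t = cfg.times
    n_t = len(t)
    x_s = cfg.x_source
    x_air = delta_to_atom_fraction(cfg.delta_air)
    x_doc = delta_to_atom_fraction(cfg.delta_doc)
    x_dic0 = delta_to_atom_fraction(cfg.delta_dic0)
    w = cfg.gas_sample_ml / cfg.headspace_ml

    if rates is None:
        rates = _per_bottle_rates(cfg, n_experiments, cfg.n_replicates, rng)
    m_rate = rates[..., 0]  # (E, R) % per month

    # end-point labelled C mineralized per bottle (mg)
    r_total = cfg.added_c_mg * m_rate / 100.0 * cfg.duration_days / MONTH_DAYS
    shape = _shape(cfg, t)  # (T,)
    lab_cum = r_total[..., None] * shape  # (E, R, T)
    doc_mg = cfg.doc_mg_per_l * cfg.water_volume_ml / 1000.0
    bg_cum = doc_mg * cfg.background_respired_fraction * (t / cfg.duration_days)  # (T,)

    air_umol = (
        cfg.air_co2_ppm * 1e-6 * (cfg.headspace_ml / 1000.0)
        / (0.0820574 * (cfg.temperature_c + 273.15)) * 1e6
    )
    air_mg = air_umol * C_MOLAR / 1000.0

    def run(lab, n_bottles):
        # lab: (E, n_bottles, T) cumulative labelled mineralized C, or None
        c_tot = np.full((n_experiments, n_bottles), air_mg)
        c13 = c_tot * x_air
        ppm = np.empty((n_experiments, n_bottles, n_t))
        delta = np.empty_like(ppm)
        prev_lab = np.zeros((n_experiments, n_bottles))
        prev_bg = 0.0
        for j in range(n_t):
            d_bg = (bg_cum[j] - prev_bg) * cfg.f_gas
            prev_bg = bg_cum[j]
            c_tot = c_tot + d_bg
            c13 = c13 + d_bg * x_doc
            if lab is not None:
                d_lab = (lab[..., j] - prev_lab) * cfg.f_gas
                prev_lab = lab[..., j]
                c_tot = c_tot + d_lab
                c13 = c13 + d_lab * x_s
            pool_umol = c_tot / C_MOLAR * 1000.0
            meas = pool_umol * (1.0 + cfg.co2_cv * rng.standard_normal(pool_umol.shape))
            ppm[..., j] = umol_to_ppm(np.maximum(meas, 1e-9), cfg.headspace_ml, cfg.temperature_c)
            x = c13 / c_tot
            delta[..., j] = atom_fraction_to_delta(x) + cfg.sigma_delta * rng.standard_normal(
                x.shape
            )
            c_tot = c_tot * (1.0 - w)
            c13 = c13 * (1.0 - w)
        return ppm, delta

    ppm_t, delta_t = run(lab_cum, cfg.n_replicates)
    ppm_c, delta_c = run(None, cfg.n_controls)

    # end-point DIC (no withdrawals; water-phase share of respired C)
    dic0_mg = cfg.dic0_umol * C_MOLAR / 1000.0
    bg_dic = bg_cum[-1] * (1.0 - cfg.f_gas)

    def dic(lab_end):
        c_tot = dic0_mg + bg_dic + (lab_end if lab_end is not None else 0.0)
        c13 = dic0_mg * x_dic0 + bg_dic * x_doc
        if lab_end is not None:
            c13 = c13 + lab_end * x_s
        pool_umol = c_tot / C_MOLAR * 1000.0
        sub = pool_umol * (cfg.dic_subsample_ml / cfg.water_volume_ml)
        sub = sub * (1.0 + cfg.co2_cv * rng.standard_normal(np.shape(sub)))
        d = atom_fraction_to_delta(c13 / c_tot) + cfg.sigma_delta * rng.standard_normal(
            np.shape(c_tot)
        )
        return sub, d

    lab_dic_t = r_total * (1.0 - cfg.f_gas)
    dic_t, ddelta_t = dic(lab_dic_t)
    dic_c, ddelta_c = dic(np.zeros((n_experiments, cfg.n_controls)))

    return {
        "times": t,
        "rates": rates,
        "treatment_ppm": ppm_t,
        "treatment_delta": delta_t,
        "control_ppm": ppm_c,
        "control_delta": delta_c,
        "treatment_dic_umol": dic_t,
        "treatment_dic_delta": ddelta_t,
        "control_dic_umol": dic_c,
        "control_dic_delta": ddelta_c,
        "truth_mineralized_mg": r_total,
    }


def simulate_plfa_arrays(cfg: ScenarioConfig, n_experiments: int, rng, rates=None):
    """Per-compound PLFA amounts (mg fatty acid) and delta-13C values."""
    cfg.validate()
    compounds = list(BASELINE_PLFA_WEIGHTS)
    base_w = np.array([BASELINE_PLFA_WEIGHTS[c] for c in compounds])
    bw_map = BIOMARKER_WEIGHTS.get(cfg.substrate, BIOMARKER_WEIGHTS["leaf"])
    bio_w = np.array([bw_map.get(c, 0.0) for c in compounds])
    if bio_w.sum() > 0:
        bio_w = bio_w / bio_w.sum()
    cfrac = np.array([carbon_fraction(c) for c in compounds])
    x_bio = delta_to_atom_fraction(cfg.delta_biomass)
    x_s = cfg.x_source

    if rates is None:
        rates = _per_bottle_rates(cfg, n_experiments, cfg.n_replicates, rng)
    a_rate = rates[..., 1]  # (E, R)
    assim_biomass = cfg.added_c_mg * a_rate / 100.0 * cfg.duration_days / MONTH_DAYS
    lab_plfa = assim_biomass * cfg.f_plfa_of_biomass  # (E, R)

    base_c = cfg.baseline_biomass_mg_c * cfg.f_plfa_of_biomass * base_w  # (C,)

    def profile(lab, n_bottles):
        base = np.broadcast_to(base_c, (n_experiments, n_bottles, len(compounds)))
        lab_c = (lab[..., None] * bio_w) if lab is not None else np.zeros_like(base)
        tot_c = base + lab_c
        x = (base * x_bio + lab_c * x_s) / tot_c
        delta = atom_fraction_to_delta(x) + cfg.sigma_delta * rng.standard_normal(x.shape)
        amount_mg = tot_c / cfrac * (1.0 + cfg.amount_cv * rng.standard_normal(tot_c.shape))
        return np.maximum(amount_mg, 0.0), delta

    amt_t, delta_t = profile(lab_plfa, cfg.n_replicates)
    amt_c, delta_c = profile(None, cfg.n_controls)
    return {
        "compounds": compounds,
        "rates": rates,
        "treatment_amount_mg": amt_t,
        "treatment_delta": delta_t,
        "control_amount_mg": amt_c,
        "control_delta": delta_c,
        "truth_assimilated_mg": assim_biomass,
    }


@dataclass
class SimulatedExperiment:
    """One experiment rendered as the CSV-dialect tables the pipeline reads."""

    gas: pd.DataFrame
    dic: pd.DataFrame
    plfa: pd.DataFrame
    config: ScenarioConfig
    truth: dict


def simulate_bottles(cfg: ScenarioConfig, seed: int | None = None) -> SimulatedExperiment:
    """Simulate one experiment (treatments + controls) into tidy tables."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    gas = simulate_gas_arrays(cfg, 1, rng)
    plfa = simulate_plfa_arrays(cfg, 1, rng, rates=gas["rates"])

    rows = []
    for role, ppm, delta, n in (
        ("treatment", gas["treatment_ppm"][0], gas["treatment_delta"][0], cfg.n_replicates),
        ("control", gas["control_ppm"][0], gas["control_delta"][0], cfg.n_controls),
    ):
        for b in range(n):
            for j, day in enumerate(gas["times"]):
                rows.append(
                    (f"{role[0].upper()}{b + 1}", role, int(day), ppm[b, j], delta[b, j])
                )
    gas_df = pd.DataFrame(rows, columns=["bottle_id", "role", "day", "co2_ppm", "delta13C_co2"])

    rows = []
    for role, umol, delta, n in (
        ("treatment", gas["treatment_dic_umol"][0], gas["treatment_dic_delta"][0], cfg.n_replicates),
        ("control", gas["control_dic_umol"][0], gas["control_dic_delta"][0], cfg.n_controls),
    ):
        for b in range(n):
            rows.append(
                (f"{role[0].upper()}{b + 1}", role, cfg.dic_subsample_ml, umol[b], delta[b])
            )
    dic_df = pd.DataFrame(
        rows, columns=["bottle_id", "role", "subsample_ml", "dic_umol", "delta13C_dic"]
    )

    rows = []
    comps = plfa["compounds"]
    for role, amt, delta, n in (
        ("treatment", plfa["treatment_amount_mg"][0], plfa["treatment_delta"][0], cfg.n_replicates),
        ("control", plfa["control_amount_mg"][0], plfa["control_delta"][0], cfg.n_controls),
    ):
        for b in range(n):
            for ci, comp in enumerate(comps):
                rows.append((f"{role[0].upper()}{b + 1}", role, comp, amt[b, ci], delta[b, ci]))
    plfa_df = pd.DataFrame(
        rows, columns=["bottle_id", "role", "compound", "amount_mg", "delta13C"]
    )

    truth = {
        "mineralization_pct_month": cfg.mineralization_pct_month,
        "assimilation_pct_month": cfg.assimilation_pct_month,
        "per_bottle_rates": gas["rates"][0],
        "mineralized_mg": gas["truth_mineralized_mg"][0],
        "assimilated_mg": plfa["truth_assimilated_mg"][0],
    }
    return SimulatedExperiment(gas=gas_df, dic=dic_df, plfa=plfa_df, config=cfg, truth=truth)


# ---------------------------------------------------------------------------
# community simulation

#: synthetic 16S taxa (OTU id, 7-rank lineage); decomposer-relevant genera
#: mirror the biomarker attribution map.
TAXA_16S = [
    ("OTU0001", "Bacteria;Proteobacteria;Gammaproteobacteria;Burkholderiales;Burkholderiaceae;Polynucleobacter;sp."),
    ("OTU0002", "Bacteria;Proteobacteria;Gammaproteobacteria;Burkholderiales;Burkholderiaceae;Pelomonas;sp."),
    ("OTU0003", "Bacteria;Proteobacteria;Gammaproteobacteria;Burkholderiales;Burkholderiaceae;Malikia;sp."),
    ("OTU0004", "Bacteria;Proteobacteria;Gammaproteobacteria;Burkholderiales;Burkholderiaceae;Hydrogenophaga;sp."),
    ("OTU0005", "Bacteria;Proteobacteria;Gammaproteobacteria;Nevskiales;Sinobacteraceae;Hydrocarboniphaga;sp."),
    ("OTU0006", "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodospirillales;Rhodospirillaceae;Elstera;sp."),
    ("OTU0007", "Bacteria;Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Novosphingobium;sp."),
    ("OTU0008", "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Boseaceae;Bosea;sp."),
    ("OTU0009", "Bacteria;Proteobacteria;Alphaproteobacteria;Reyranellales;Reyranellaceae;Reyranella;sp."),
    ("OTU0010", "Bacteria;Proteobacteria;Alphaproteobacteria;Hyphomonadales;Hyphomonadaceae;Hirschia;sp."),
    ("OTU0011", "Bacteria;Bacteroidetes;Cytophagia;Cytophagales;Spirosomaceae;Arcicella;sp."),
    ("OTU0012", "Bacteria;Planctomycetes;Planctomycetia;Isosphaerales;Isosphaeraceae;Singulisphaera;sp."),
    ("OTU0013", "Bacteria;Planctomycetes;Phycisphaerae;Phycisphaerales;Phycisphaeraceae;I-8;sp."),
    ("OTU0014", "Bacteria;Planctomycetes;Planctomycetia;Pirellulales;Pirellulaceae;uncultured_Pirellulaceae;sp."),
    ("OTU0015", "Bacteria;Verrucomicrobia;Verrucomicrobiae;Verrucomicrobiales;Verrucomicrobiaceae;Prosthecobacter;sp."),
    ("OTU0016", "Bacteria;Actinobacteria;Actinomycetia;Frankiales;Sporichthyaceae;hgcI_clade;sp."),
    ("OTU0017", "Bacteria;Actinobacteria;Actinomycetia;Micrococcales;Microbacteriaceae;Candidatus_Planktophila;sp."),
    ("OTU0018", "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae;Flavobacterium;sp."),
    ("OTU0019", "Bacteria;Proteobacteria;Alphaproteobacteria;SAR11_clade;Pelagibacteraceae;Candidatus_Pelagibacter;sp."),
    ("OTU0020", "Bacteria;Chloroflexi;Anaerolineae;Anaerolineales;Anaerolineaceae;uncultured_Anaerolineaceae;sp."),
    ("OTU0021", "Bacteria;Cyanobacteria;Cyanophyceae;Synechococcales;Synechococcaceae;Synechococcus;sp."),
    ("OTU0022", "Bacteria;Proteobacteria;Deltaproteobacteria;Myxococcales;Polyangiaceae;Sorangium;sp."),
    ("OTU0023", "Bacteria;Verrucomicrobia;Opitutae;Opitutales;Opitutaceae;Opitutus;sp."),
    ("OTU0024", "Bacteria;Bacteroidetes;Sphingobacteriia;Sphingobacteriales;Chitinophagaceae;Sediminibacterium;sp."),
]

TAXA_ITS = [
    ("ITS0001", "Fungi;Basidiomycota;Microbotryomycetes;Sporidiobolales;Sporidiobolaceae;Rhodotorula;sp."),
    ("ITS0002", "Fungi;Basidiomycota;Tremellomycetes;Tremellales;Cryptococcaceae;Cryptococcus;sp."),
    ("ITS0003", "Fungi;Ascomycota;Dothideomycetes;Pleosporales;Pleosporaceae;Alternaria;sp."),
    ("ITS0004", "Fungi;Ascomycota;Sordariomycetes;Hypocreales;Nectriaceae;Fusarium;sp."),
    ("ITS0005", "Fungi;Ascomycota;Eurotiomycetes;Eurotiales;Aspergillaceae;Penicillium;sp."),
    ("ITS0006", "Fungi;Chytridiomycota;Chytridiomycetes;Rhizophydiales;Rhizophydiaceae;Rhizophydium;sp."),
    ("ITS0007", "Fungi;Basidiomycota;Agaricomycetes;Polyporales;Polyporaceae;Trametes;sp."),
    ("ITS0008", "Fungi;Ascomycota;Leotiomycetes;Helotiales;Helotiaceae;Articulospora;sp."),
]


@dataclass
class CommunityConfig:
    """Synthetic amplicon survey: Dirichlet-multinomial counts whose
    designated decomposer taxa co-vary with the per-sample label signal."""

    marker: str = "16S"
    n_samples: int = 8
    decomposer_genera: tuple = ("Polynucleobacter", "Pelomonas", "Hydrocarboniphaga")
    effect_size: float = 2.0   # log-abundance change per SD of signal
    depth_mean: int = 30_000
    depth_sigma: float = 0.15  # lognormal sigma of library size
    concentration: float = 50.0
    seed: int | None = None


def simulate_community(comm: CommunityConfig, signal=None, seed: int | None = None):
    """Counts (samples x OTUs), taxonomy Series, and the per-sample signal.

    ``signal`` is the standardized label-uptake covariate (e.g. biomarker
    delta-delta-13C); if omitted, a standard normal draw is used. Effect size
    0 leaves every taxon independent of the signal.
    """
    rng = np.random.default_rng(comm.seed if seed is None else seed)
    taxa = TAXA_16S if comm.marker == "16S" else TAXA_ITS
    otu_ids = [t[0] for t in taxa]
    taxonomy = pd.Series({t[0]: t[1] for t in taxa}, name="taxonomy")
    genera = np.array([parse_genus(t[1]) for t in taxa])

    if signal is None:
        signal = rng.standard_normal(comm.n_samples)
    signal = np.asarray(signal, dtype=float)
    sd = signal.std()
    z = (signal - signal.mean()) / sd if sd > 0 else np.zeros_like(signal)

    base = rng.dirichlet(np.full(len(taxa), comm.concentration / len(taxa)))
    is_dec = np.isin(genera, comm.decomposer_genera)
    counts = np.empty((comm.n_samples, len(taxa)), dtype=np.int64)
    sample_ids = [f"S{i + 1}" for i in range(comm.n_samples)]
    for i in range(comm.n_samples):
        p = base * np.where(is_dec, np.exp(comm.effect_size * z[i]), 1.0)
        p = rng.dirichlet(p / p.sum() * comm.concentration * 10)
        depth = int(np.round(comm.depth_mean * np.exp(comm.depth_sigma * rng.standard_normal())))
        counts[i] = rng.multinomial(max(depth, 1), p)
    table = pd.DataFrame(counts, index=sample_ids, columns=otu_ids)
    return table, taxonomy, pd.Series(signal, index=sample_ids, name="signal")


def parse_genus(lineage: str) -> str:
    parts = lineage.split(";")
    return parts[5] if len(parts) > 5 else "unclassified"
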