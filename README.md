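# isofate

**¹³C tracer accounting for the decomposition of natural polymers and
microplastics in lake water.**

Closed-bottle assays with ¹³C-labelled substrates (beech leaves,
lignin–hemicellulose, polystyrene, polypropylene, polyethylene) are the most
sensitive way to measure how fast freshwater microbes decompose recalcitrant
carbon and where that carbon ends up. `isofate` turns the raw measurements of
such an assay — weekly headspace CO₂ mixing ratios with δ¹³C-CO₂, end-point
acidified-subsample DIC, and compound-specific δ¹³C of phospholipid fatty
acids (PLFAs) — into mineralization and assimilation rates, total
decomposition times, the biochemical fate of the decomposed carbon, bacterial
growth efficiency, and correlation-based attribution of decomposer taxa from
16S/ITS OTU tables. A forward simulator generates complete synthetic
experiments with known ground truth, so every stage of the pipeline is
testable without access to the original raw data.

## The accounting model

All label bookkeeping happens in **atom-fraction space**. A δ¹³C value (‰ vs
VPDB) maps to the ¹³C atom fraction

x = R / (1 + R),  R = (δ/1000 + 1) · R_VPDB,  R_VPDB = 0.0111802,

and the fraction of a carbon pool derived from the labelled substrate follows
from two-pool mixing against the matched no-substrate control bottles:

f = (x_sample − x_control) / (x_substrate − x_control),  excess C = f · pool C.

At the 13.4–99 atom% label strengths used here, mixing δ values directly
would be badly biased; atom fractions mix exactly by mass balance.

Excess carbon is accumulated in three pools per replicate bottle — headspace
CO₂ (ideal-gas pool, corrected for the five weekly 5 mL gas withdrawals),
end-point DIC (5 mL subsample scaled to the 300 mL water column), and
microbial biomass (per-compound PLFA mixing, scaled by the PLFA-C : biomass-C
ratio, default 0.056). Rates, times and fates then follow:

- mineralization rate M = 100 · (excess CO₂ + excess DIC) / added C,
  normalized to a 30.44-day month or 365.25-day year;
- assimilation rate A on the same convention from the biomass excess;
- decomposition rate D = M + A; decomposition time T = 100 / D
  (reported "not degraded" when D ≤ 0 and ">10,000 years" beyond the cap);
- fate partition = each pool's excess as a percentage of the total, so
  BGE = biomass fate / 100 ≡ A / (M + A).

Decomposer taxa are nominated by Pearson correlation (r > 0.9) between
genus-aggregated, standardized and square-root-transformed OTU abundances and
the per-sample Δδ¹³C of biomarker PLFAs, alongside Bray–Curtis / NMDS
ordination and pairwise PERMANOVA (exhaustive label enumeration for small
designs, Monte Carlo otherwise).

## Worked example

Simulate one humic-lake-water leaf experiment (true mineralization
9 %/month, true assimilation 14 %/month, 13.4 atom% label, 4 replicate
bottles + 4 controls, 3-week incubation) and re-estimate everything:

```python
from isofate import TracerExperiment, get_scenario, simulate_bottles

sim = simulate_bottles(get_scenario("humic_leaf"), seed=42)
res = TracerExperiment.from_simulation(sim).fit()
print(res.summary())
```

```
13C tracer decomposition accounting
====================================================
substrate: leaf                   water: humic
replicates: 4
----------------------------------------------------
mineralization         8.871 +/- 1.15       %/month
assimilation           13.51 +/- 1.11       %/month
decomposition          268.5 +/- 25.8       %/year
decomposition time: 4.5 months
fate: CO2 15.8% | DIC 23.9% | biomass 60.4%
BGE: 0.604
```

The estimates recover the simulated truths within replicate noise: leaves
decompose within a few months, and about 60% of the decomposed leaf carbon
ends up in microbial biomass rather than being respired. `res.replicates`
holds the per-bottle excess masses and rates; `res.to_frames()` exports the
rates/fate tables.

The same workflow is available from the shell:

```bash
isofate simulate --scenario humic_leaf --out demo --seed 42
isofate rates --gas demo/gas.csv --dic demo/dic.csv --out demo/rates.tsv
isofate run --config run.yaml          # full pipeline incl. OTU attribution
```

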