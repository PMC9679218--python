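# Methods

## Isotope arithmetic

Delta values are converted to ¹³C atom fractions with R_VPDB = 0.0111802
(configurable) and all mixing is performed on atom fractions. The two-pool
mixing fraction is computed unclamped for rate estimation and clamped to
[0, 1] (with a flag) for reported excess masses and fate partitions. The
distinction matters for the null behaviour: around zero uptake, instrument
noise makes the raw fraction fluctuate symmetrically about zero, so rates
built from the unclamped value average to zero over replicates, whereas
clamping would accumulate a positive bias. Conversions round-trip to well
below 1e-10 ‰ at natural abundance; at extreme enrichment (δ ~ 10⁷ ‰) the
round-trip is limited by double precision to ~1e-8 ‰.

## Closed-bottle mineralization

Geometry defaults follow the assay design: 540 mL bottle, 300 mL water,
240 mL headspace, 4 mg C substrate, 17.5 °C, weekly 5 mL gas samples, one
end-point 5 mL DIC subsample.

- **Headspace pool.** CO₂ mixing ratio → µmol via the ideal gas law at 1 atm.
  Pressure loss from sampling is neglected (each withdrawal removes 2.1% of
  the headspace moles); mixing ratios are unaffected by withdrawal.
- **Background endpoint.** The control endpoint at each time point is the
  mean *atom fraction* over control replicates of the same water, converted
  back to δ only for display. Controls share the treatment bottles'
  unlabelled carbon sources (initial air CO₂ and respired lake DOC), so this
  endpoint matches the treatment's unlabelled mixture and the estimator is
  unbiased.
- **Withdrawal correction** (default on). With E_k the before-withdrawal
  excess at sampling k and w = 5/240 the withdrawn fraction, the labelled C
  delivered to the headspace over the assay is E_K + w · Σ_{k<K} E_k. This is
  exact for arbitrary arrival kinetics: the labelled C arriving in interval k
  is R_k = E_k − (1−w) E_{k−1} and the sum telescopes. Disabling the
  correction reports the end-point pool only, which underestimates truth by
  up to ~10% over six weekly samplings.
- **DIC.** The subsample amount is scaled by water volume / subsample volume
  with δ unchanged; no withdrawal correction is needed (single end-point
  measurement). Henry-law partitioning during the incubation is not modelled:
  the end-point DIC measurement captures the dissolved phase directly, and
  the simulator's gas/water split (below) is a free parameter rather than an
  equilibrium calculation.
- **Units.** Rates normalize the end-point excess linearly to a 365.25-day
  year; a month is exactly 1/12 of that (30.4375 d), so per-month ↔ per-year
  conversions are an exact factor of 12 and % ↔ ‰ an exact factor of 10.
  Both per-time bases therefore round-trip exactly, at the cost of a 0.01%
  difference from a literal 30.44-day month.

## PLFA assimilation

Amounts come from multi-point linear standard curves divided by the
internal-standard recovery (mean over C19:0 and C23:0; QC failure outside
(0, 1.5]). The carbon content of each compound is computed from its molecular
formula (CnH(2n−2·db)O₂); BrSFA is a pooled pseudo-compound assigned a
representative C16 saturated formula. Per-compound excess C sums over the
compounds shared between treatment and control and is divided by
f_plfa_of_biomass (default 0.056, the order-of-magnitude standard for
bacterial PLFA-C per biomass-C) to give biomass excess. All recovery results
are conversion-factor independent because the simulator and the estimator
share the configured value; absolute biomass numbers on real data inherit its
(factor ~2) uncertainty. A bulk mode (single "BULK" row with total PLFA C)
is equivalent to per-compound mode whenever all compounds share one δ.

## Decomposition synthesis

All syntheses run per replicate first and aggregate afterwards: D = M + A and
T = 100/D are computed per bottle, then summarized as mean ± sample SD
(n−1). This is the only order that produces dispersion intervals on times.
Sentinels: D ≤ 0 → "not degraded"; T beyond the 10,000-year reporting cap →
"> 10,000 years"; a rate whose mean − SD ≤ 0 is flagged below detection.
Fate partitions clamp negative excesses at zero and normalize to 100%, so
biomass-fate/100 is identically the bacterial growth efficiency
A/(A+M) whenever anything decomposed, and a zero total returns a
"not decomposed" sentinel rather than dividing by zero.

## Community attribution

Rarefaction is a single seeded multivariate-hypergeometric draw per sample
(no averaging over draws); samples below the depth are dropped. The rare-OTU
floor (default 1%) keeps an OTU that reaches the floor in *any* sample; a
mean-abundance variant is available by flag. Transformation is per-sample
relative abundance followed by square root. Bray–Curtis is computed from the
standard formula; all-zero sample pairs are NaN-flagged. NMDS wraps
scikit-learn's non-metric MDS with random starts, reporting Kruskal stress-1
and the best restart with centered coordinates; a stress above 0.2 warns.
Pairwise PERMANOVA uses the among/within squared-dissimilarity pseudo-F with
t = √F; p-values enumerate all distinct relabelings exhaustively when there
are ≤ 10,000 (label-swap symmetry collapsed for equal group sizes), else
Monte Carlo with the observed labelling included. Label permutation is the
permutation scheme; residual permutation is not implemented. Decomposer
candidates are genus-aggregated (rank configurable) taxa whose transformed
abundance correlates with a biomarker's per-sample Δδ¹³C above r = 0.9;
zero-variance taxa/compounds are skipped, and a counts-vs-rate linear
regression (slope, R²) is provided for single-taxon follow-up.

## Synthetic experiments

The generator is the estimator's exact inverse plus noise, and its defaults
are the study conditions: 4 replicates + 4 controls, 4 mg C added, label
strengths 13.4 / 97 / 99 atom% by substrate, 3- or 6-week incubations with
weekly sampling, σ_δ = 0.2 ‰ (typical IRMS precision). The true rate fixes
the cumulative labelled C processed by the end of the incubation; a kinetic
shape distributes it over time — saturating (k = 0.3 d⁻¹, ~88% of the signal
within week one) for humic water, linear for clear water — without changing
the end-point total, so end-point estimation is unbiased under either shape.
Choices the assay itself does not pin down, made once here: respired C splits
40% to the headspace and 60% to DIC (f_gas, configurable); background DOC
respiration converts 5% of the water's DOC (22.6 mg/L humic, 5.19 mg/L
clear) over the incubation at δ = −27 ‰; initial headspace air is 420 ppm
CO₂ at −8.5 ‰; initial DIC 90 µmol at −14 ‰; baseline biomass 0.3 mg C at
δ_PLFA = −30 ‰; CO₂ quantification CV 2%, PLFA amount CV 5%; and a 10%
mean-preserving biological CV on per-bottle rates, which is what generates
replicate dispersion of the magnitude real assays show. Assimilated label is
distributed over biomarker compounds per substrate (16:1ω7/18:1ω7 for the
proteobacterial leaf/PS decomposers, 18:1ω9/16:1ω9 for the aliphatic-plastic
ones, branched C15 compounds for hemicellulose).

Scenario presets encode the study grid; where a scenario needs an
assimilation default that the rate table does not state directly
(hemicellulose), it is back-derived from the biomass fate fraction.

The community generator draws Dirichlet-multinomial counts over a fixed
synthetic taxonomy (24 bacterial genera including the Burkholderiaceae and
*Arcicella*/*Hydrocarboniphaga* decomposer set, 8 fungal genera for ITS) with
lognormal library sizes around 30,000 reads so rarefaction is exercised;
designated decomposer taxa scale as exp(effect · z) in the per-sample label
signal.

**What the simulator does not emulate:** substrate particle physics
(floating PE/PP vs submerged PS), photo- or thermo-oxidative degradation,
CH₄ production, community succession over the incubation, chimeras or other
sequencing artifacts, and compositional correlations between taxa beyond the
Dirichlet. Passing recovery tests therefore demonstrates that the estimation
chain is unbiased and correctly propagates the designed noise sources — not
that real-lake rate estimates carry no systematic error from those
unmodelled processes.

## Problem sizes and numerics

Recovery studies use 200 simulated experiments per scenario (SE of the grand
mean ~0.3% of the rate, comfortably resolving bias at the 3·SE criterion);
null calibrations use 200 draws. The PERMANOVA exhaustive/Monte-Carlo
crossover is 10,000 relabelings. Degenerate inputs favour sentinels over
exceptions wherever the assay itself produces them (no decomposition, below
detection, undefined BGE); errors are reserved for impossible configurations
(non-positive volumes, label outside (0, 100) atom%, mass balance exceeding
the added carbon).
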