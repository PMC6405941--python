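# bluecarb

Inorganic-carbon (C<sub>inorg</sub>) burial accounting for Blue Carbon
sediments: lead-210 chronologies, CaCO₃ burial rates, global upscaling,
and the CO₂ budget of carbonate dynamics in seagrass meadows, mangrove
forests and saltmarshes.

## The problem

Vegetated coastal ecosystems bury organic carbon (C<sub>org</sub>) and are
managed as CO₂ sinks. Their sediments, however, also accumulate large
amounts of calcium carbonate — and calcification is a CO₂ *source*: each
mole of CaCO₃ precipitated releases ψ ≈ 0.6 mol of CO₂ to the
atmosphere–seawater pool. Whether buried carbonate undermines the sink
therefore depends on where the CaCO₃ came from. Carbonate produced *in
situ* by the associated fauna and flora carries the ψ-emission; carbonate
imported from adjacent reefs or karstic terrain carries none, and its
dissolution inside the meadow even adds to the sink. `bluecarb` implements
the complete accounting chain needed to make that argument quantitative,
for anyone compiling dated sediment cores from these habitats.

## The methods

**Chronology (CF:CS).** Excess ²¹⁰Pb declines exponentially with
cumulative dry mass *m* under constant flux and constant sedimentation:
*A*(m) = *A*₀ e^(−λm/MAR), λ = ln2 / 22.3 yr⁻¹. A least-squares fit of
ln *A* on *m* gives the mass accumulation rate MAR = λ/|slope|
(g cm⁻² yr⁻¹), the sediment accretion rate SAR = MAR / ρ̄ (cm yr⁻¹, ρ̄ the
mean dry bulk density of the fitted interval), and slice ages *m*/MAR.

**Carbonate accounting.** Per dated core, CaCO₃ %DW is averaged over the
slices younger than 1900 CE; the C<sub>inorg</sub> concentration is
ρ̄ · (%CaCO₃/100) · f<sub>C</sub> with f<sub>C</sub> = 0.12 the carbon mass
fraction of CaCO₃; the burial rate is SAR × concentration × 10⁴
(gC m⁻² yr⁻¹).

**Upscaling.** Cores from one site with the same allochthonous-source
state are replicates of a *location*; location medians (distributions are
strongly bimodal, so median/IQR is the headline statistic) scale to
Tg yr⁻¹ by habitat extent, optionally split 2/3 : 1/3 between tropical
and higher-latitude zones.

**CO₂ budget.** Emission = ψ × net calcification; net sequestration =
NPP uptake − emission; and the burial-vs-calcification mass balance
1 − calcification/burial gives the fraction of buried carbonate that must
be allochthonous.

**Effect statistics.** Hedges' g with small-sample correction J and
variance V<sub>g</sub>, DerSimonian–Laird random-effects pooling for
paired vegetated/unvegetated comparisons, and Mann–Whitney U tests for
the non-normal carbonate distributions.

A synthetic-core generator produces cores satisfying the CF:CS
assumptions with known ground truth (lognormal activity noise, bimodal
logit-normal CaCO₃ regimes conditioned on source presence, optional
paired unvegetated cores), so the whole pipeline is testable end to end.

## Worked example

Simulate a 17-location seagrass compilation (51 cores, ²²⁶Ra-style
supported-activity measurements included), date every core, compute
burial rates, and scale to the global seagrass extent:

```python
from bluecarb import (DatasetScenario, CoreScenario, generate_dataset,
                      fit_cfcs, core_carbonate, group_locations,
                      summarize_distribution, global_burial, round_sig,
                      load_config)

constants = load_config(None)
scen = DatasetScenario(n_locations=17,
                       core_scenario=CoreScenario(measure_supported=True))
cores, truth = generate_dataset(scen, seed=42)
chrons, carb = {}, {}
for core in cores:
    ch = fit_cfcs(core, constants)
    chrons[core.core_id] = ch
    carb[core.core_id] = core_carbonate(core, ch, constants)

locs = group_locations(cores, carb, chrons)
burial = summarize_distribution([l.cinorg_burial_mean for l in locs])
sar = summarize_distribution([l.sar_mean for l in locs])
print(f"{len(cores)} cores in {len(locs)} locations")
print(f"median SAR           {sar.median:.2f} cm/yr (IQR {sar.iqr:.2f})")
print(f"median Cinorg burial {burial.median:.0f} gC/m2/yr (IQR {burial.iqr:.0f}), "
      f"normally distributed: {burial.normal_flag}")
est = global_burial(burial.median, constants.seagrass_area_low,
                    constants.seagrass_area_high)
print(f"global burial        {round_sig(est.burial_low)} to "
      f"{round_sig(est.burial_high)} TgC/yr")
```

prints

```
51 cores in 17 locations
median SAR           0.22 cm/yr (IQR 0.01)
median Cinorg burial 148 gC/m2/yr (IQR 147), normally distributed: False
global burial        22.0 to 89.0 TgC/yr
```

The median SAR recovers the generator's true accretion rate
(0.22 cm yr⁻¹); the burial median reflects the simulated mix of
carbonate-rich (source-adjacent) and carbonate-poor locations, and the
Shapiro–Wilk screen correctly flags the location-level distribution as
non-normal; the global range is that median times the 150,000–600,000 km²
extent range, in Tg yr⁻¹.

The same pipeline is available from the shell:

```sh
bluecarb simulate --seed 42 --out sim
bluecarb chronology sim_slices.csv sim_cores.csv --out sim
bluecarb burial sim_slices.csv sim_cores.csv --out sim_burial.csv
bluecarb summarize sim_burial.csv --column cinorg_burial --out sim_summary.json
bluecarb global --rate 87 --out global.csv
```

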