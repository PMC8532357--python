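# vinoflux

Constraint-based flux sampling and strain comparison for wine-yeast
fermentations.

Commercial *Saccharomyces cerevisiae* wine strains produce markedly different
aroma profiles (fusel alcohols, acetate and fatty-acid esters — the volatile
organic compounds, VOCs) from near-identical musts. The extracellular data a
winery or lab actually has — concentration-vs-time courses of sugars, amino
acids, biomass and VOCs — underdetermines the intracellular state, so this
package characterises it statistically instead of point-estimating it:

1. **Flux estimation** — specific exchange fluxes q(tᵢ) and growth rates μ(tᵢ)
   (mmol gDW⁻¹ h⁻¹, h⁻¹) are derived from the time courses by central
   (midpoint) finite differences, normalised by measured biomass, with no
   smoothing.
2. **Enological model setup** — a genome-scale (or built-in toy) metabolic
   model is made anaerobic (oxygen exchange closed, sterol/oleate uptakes
   opened, respiratory shuttles blocked, heme A dropped from biomass) and the
   measured fluxes are imposed as LB = UB bounds on the matching exchange
   reactions, the growth rate on the biomass reaction.
3. **Uniform flux sampling** — the remaining steady-state polytope
   {v : Sv = 0, lb ≤ v ≤ ub} is sampled uniformly with an
   artificially-centered hit-and-run (ACHR) chain (FVA-vertex warmup,
   null-space projection, seeded and reproducible), validated against an
   exactly uniform rejection sampler on low-dimensional polytopes.
4. **Strain comparison** — per-reaction sample medians are ranked by their
   across-strain spread (absolute and percent, with a 10⁻¹² mmol gDW⁻¹ h⁻¹
   miniscule-flux filter), strains are compared by PCA with squared-cosine
   (cos2) diagnostics on the extracellular fluxes, and clustered by
   average-linkage hierarchical clustering on 1 − Pearson correlation of
   their median flux vectors.

It is aimed at systems-biology and fermentation researchers who want an
objective-function-free readout of where strain metabolism differs.

Because real multi-strain fermentation datasets are rarely public, the
package ships a first-class synthetic-data module: a ~25-reaction toy wine
network (glycolysis, glycerol and ethanol branches, an Ehrlich pathway with
ester formation, biomass) and a 4-strain benchmark scenario with planted,
recoverable differences, so the entire pipeline is testable end to end.

## Worked example

Four simulated strains, constrained at the 24 h time point and sampled at
n = 2000 each (S1 and S2 share identical physiology; S3 has a 3× Ehrlich-branch
flux; S4 ferments faster with fewer VOCs and more glycerol):

```python
from vinoflux import (
    apply_anaerobic_modifications, build_stoichiometric_system, reaction_medians,
    rank_absolute_median_difference, cluster_strains, achr_sample, SamplerConfig,
    build_flux_table, make_benchmark_scenario, simulate_strain_timeseries,
    toy_anaerobic_recipe,
)
from vinoflux.pipeline import fix_with_band_ladder, DEFAULT_BAND_LADDER, _derive_seed

model, scenario, truth = make_benchmark_scenario(seed=11)
series = simulate_strain_timeseries(model, scenario)
table = build_flux_table(series, [24.0], scenario.compound_to_exchange)
anaerobic = apply_anaerobic_modifications(model, toy_anaerobic_recipe())

sample_sets = []
for i, strain in enumerate(scenario.strain_names):
    constrained, band = fix_with_band_ladder(anaerobic, table.row(strain, 24.0),
                                             DEFAULT_BAND_LADDER)
    system = build_stoichiometric_system(constrained)
    cfg = SamplerConfig(n_samples=2000, seed=_derive_seed(11, i), steps_per_sample=30)
    sample_sets.append(achr_sample(system, cfg, strain=strain, time_h=24.0))

medians = reaction_medians(sample_sets)
ranking = rank_absolute_median_difference(medians, k=20)
print(ranking.to_frame(model).head(5).round(3).to_string(index=False))
cluster = cluster_strains(medians, subset=ranking.reaction_ids())
print("first merge:", cluster.first_merge())
```

prints

```
reaction_id     gene_association           subsystem  median_S1  median_S2  median_S3  median_S4  spread
    EX_etoh                                 Exchange      4.816      4.897      4.674      7.638   2.964
        PYK             TOY_PYK1          Glycolysis      4.866      4.950      4.723      7.654   2.931
        PDC TOY_PDC1 or TOY_PDC5 Pyruvate metabolism      4.866      4.950      4.723      7.654   2.931
     EX_co2                                 Exchange      5.300      5.412      5.978      7.761   2.461
     EX_glc                                 Exchange     -2.570     -2.613     -2.502     -4.154   1.652
first merge: ('S1', 'S2')
```

The ranking surfaces S4's elevated central-carbon flux (ethanol, pyruvate
kinase, pyruvate decarboxylase medians ~7.7 vs ~4.8) and the clustergram's
first merge recovers the planted identical pair — the analysis reads the
strain design back out of nothing but noisy concentration curves.

The same run as one command, with all CSV/Newick reports and a manifest:

```bash
vinoflux run --benchmark --seed 11 --out-dir results_run
```

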