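# camtrapdensity

Simulation-based estimation of mesocarnivore population density from
camera-trap records.

Unmarked species — foxes, skunks, small wild cats — cannot be counted by
capture–recapture because individuals are not identifiable on photographs.
`camtrapdensity` implements the simulation-matching alternative used in
recent camera-trap studies of Chilean carnivores: simulate how many photo
events a survey *would* produce for each candidate population size, then
ask which candidate best explains the events actually observed. It is
aimed at field ecologists with a deployment table and a photo-record
table, and at methodologists who want to probe the estimator's
calibration with synthetic data.

## The method

1. **Movement.** Each of the `N` hypothetical individuals moves by a
   correlated random walk: step length `L ~ Normal(μ, σ)` truncated at
   zero, heading `θ_t = θ_{t−1} + ε`, `ε ~ Normal(0, σ_θ)`, with a fixed
   number of steps per calendar month. The walk is confined to a circular
   home range of area `A_hr` centred on the individual's home centre
   (proposals outside the disc are redrawn). Species defaults ship for
   *Lycalopex* spp. (pooled foxes), *Leopardus guigna* and *Conepatus
   chinga*.
2. **Detection.** A camera photographs an animal whenever a step endpoint
   falls within its detection zone — a 20 m radius, 45° sector in front
   of the camera — while the camera is active.
3. **Events.** Simulated and observed records pass through the same
   independence filter: within each camera × species, a photo counts as a
   new event only if it is >60 min after the last counted one. The
   per-camera event counts are the feature vector.
4. **Matching.** Surveys are simulated for an abundance gradient
   `N = 1..20` (replicated), and a random-forest regressor (5,000 trees,
   `mtry = √#cameras`) learns abundance from count vectors. Applied to the
   observed vector, the forest mean is `N̂`; the 2.5th/97.5th percentiles
   of the per-tree predictions give the 95% CI; dividing by the effective
   sampling area (camera bounding box buffered by the home-range radius)
   converts abundance to density. An estimate is flagged *reliable* only
   if the CI excludes zero, the per-tree prediction distribution is
   bell-shaped, and enough independent events back it.

## Worked example

Generate a synthetic one-site study with a known true density, then
estimate it (about two minutes; heavier settings only change precision):

```python
from camtrapdensity import (DensityModel, RFConfig, SimConfig, StudyTemplate,
                            count_events, filter_independent, generate_study,
                            species_defaults)

params = species_defaults()
study = generate_study(StudyTemplate(n_sites=1, seed=7), params)
events = filter_independent(study.records)          # >60-min rule
grid = study.grids["La Estrella"]
obs = count_events(events, grid, "Lycalopex spp.")

model = DensityModel(
    obs, grid, params["Lycalopex spp."],
    sim_config=SimConfig(replicates_per_abundance=30, base_seed=7),
    rf_config=RFConfig(n_trees=5000, seed=7))
results = model.fit()
print(results.summary())
```

```
Camera-trap density estimate (simulation matching, random forest)
==================================================================
Species:              Lycalopex spp.
Site:                 La Estrella
Independent events:   57
Training simulations: 600 (abundance 1..20)
Forest:               5000 trees
------------------------------------------------------------------
Abundance n_hat:      14.27 individuals
Effective area:       23.76 km²
Density:              0.60 individuals/km²
95% CI:               (0.25, 0.84)
Reliable:             False  [tree-prediction distribution not bell-shaped; insufficient events (57 < 100)]
==================================================================
```

The study was generated with 10 individuals (true density
10 / 23.76 = 0.42 /km²): the 95% CI covers the truth, while the
reliability flags correctly warn that 57 independent events are too few
for a trustworthy point estimate. `results.plot_distribution()` draws the
per-tree density distribution behind the CI.

The same pipeline is scriptable from the shell:

```sh
camtrapdensity synth --density "Lycalopex spp.=0.4" --sites 1 --seed 7 --outdir study/
camtrapdensity filter study/records.csv study/events.csv
camtrapdensity estimate --records study/records.csv --deployments study/deployments.csv \
    --species "Lycalopex spp." --trees 5000 --seed 7 --out estimate.json
camtrapdensity recover --runs 20 --seed 1 --out recovery.json
```

`estimate` writes a run manifest next to its output; re-running with
`--from-manifest` reproduces the estimate bit-for-bit.

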