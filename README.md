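# aomquant

Microscopy-based quantification of microbial community growth for anaerobic
methane-oxidizing (AOM) enrichments: from DAPI field counts to per-ml
concentrations and spherical biovolume by aggregate size class, CARD-FISH
group composition with detection limits, 16S clone-library percentages, and
two-timepoint growth estimates — relative increase, doubling time and
dry-weight biomass — with replicate-based uncertainty throughout.

## The problem

Communities of anaerobic methanotrophic archaea (ANME) and their
sulphate-reducing bacterial partners (SRB) grow too slowly for plate counts
or optical density; their enrichment in bioreactors is instead tracked by
microscopy. A slurry sample is diluted, filtered, DAPI-stained and counted
in *n* fields of view per staining replicate, recording free single cells
and aggregates binned by integer diameter class Ø (µm). Treating every
object as a sphere, the biovolume concentration is

    B = Σ_c  N_c · (π/6) Ø_c³   +   N_cells · (π/6) (0.45 µm)³      [µm³/ml slurry]

where `N_c` is the concentration of class-c aggregates obtained from the
mean per-field count via the filtration geometry (filter area / field area,
filtered volume, dilution), and 0.45 µm is the standard average ANME/SRB
cell diameter. CARD-FISH with single taxon-specific probes (ANME1-350,
EelMS932, ANME3-1249, DSS658) against a DAPI counterstain gives each group's
fraction of cells, of aggregates, and of biovolume — ratios that are
invariant to geometry and to washing losses, provided all object types wash
out in the same ratio. Combining total biovolume `B` with a group's
biovolume fraction `f` at two timepoints Δt apart gives the group biovolume
`V = B·f`, its relative increase `(V₂−V₁)/V₁`, and — under exponential
("logarithmic growth curve") kinetics — the doubling time

    t_d = Δt · ln 2 / ln(V₂/V₁),

reported in months of 30.44 days. Biovolume converts to dry biomass with
0.2 g cell dry weight per ml of biovolume.

The package is organised as model objects with `fit()` methods returning
results objects (`BiovolumeModel → SampleBiovolumeResults`,
`CompositionModel → CompositionResults`, `GrowthModel → GrowthResults`),
plus a synthetic-data module (`aomquant.simulate`) that draws Poisson field
counts, binomially thinned probe counts and multinomial clone libraries from
a declared truth, so every stage of the pipeline is testable against known
parameters.

## Worked example

Simulate the calibrated two-timepoint enrichment scenario (total biovolume
1.28×10⁹ → 4.49×10⁹ µm³/ml over 286 days; 4 stainings × 50 fields) and
re-estimate the ANME-2 doubling time from the synthetic counts:

```python
from aomquant import (paper_scenario, simulate_counts, simulate_probe_counts,
                      BiovolumeModel, CompositionModel, GrowthModel)

study = paper_scenario()
seed = 1
bv, frac = {}, {}
for truth in (study.s1, study.s2):
    counts = simulate_counts(truth, seed)        # DAPI field counts
    probes = simulate_probe_counts(truth, seed)  # CARD-FISH probe/DAPI counts
    res = BiovolumeModel(counts, truth.geometry).fit()
    comp = CompositionModel(probes, truth.geometry).fit()
    print(res.summary())
    bv[truth.sample_id] = res
    f = comp.fraction(truth.sample_id, "EelMS932", "biovolume")  # ANME-2 probe
    frac[truth.sample_id] = (f.mean, f.se)

growth = GrowthModel.from_estimates(
    (bv["S1"].total_biovolume, bv["S1"].total_biovolume_se), frac["S1"],
    (bv["S2"].total_biovolume, bv["S2"].total_biovolume_se), frac["S2"],
    delta_t_days=study.delta_t_days, group_id="ANME-2").fit()
print(growth.summary())
```

Output:

```
Biovolume quantification — sample S1 (4 staining replicates)
  total biovolume:      (1.23 ± 0.07)*10^9 um^3/ml slurry
  aggregate biovolume:  (1.22 ± 0.07)*10^9 um^3/ml slurry
  aggregate share:      99.6% of total biovolume
  single cells:         (1.14 ± 0.01)*10^8 cells/ml slurry
Biovolume quantification — sample S2 (4 staining replicates)
  total biovolume:      (4.36 ± 0.28)*10^9 um^3/ml slurry
  aggregate biovolume:  (4.34 ± 0.28)*10^9 um^3/ml slurry
  aggregate share:      99.6% of total biovolume
  single cells:         (3.67 ± 0.03)*10^8 cells/ml slurry
Growth of ANME-2 over 286 days (full mode)
  biovolume:      (1.60 ± 0.11)*10^8 -> (2.20 ± 0.19)*10^9 um^3/ml slurry
  increase:       12.573 times  (fold change 13.6)
  doubling time:  2.49704 months
  dry weight:     0.03243 -> 0.440171 g/l slurry
```

The estimated totals (1.23×10⁹, 4.36×10⁹ µm³/ml) recover the declared truths
(1.28×10⁹, 4.49×10⁹) within their standard errors, and the estimated
doubling time (2.50 months) recovers the truth implied by the scenario
(2.52 months). The same pipeline runs from the shell:

```sh
aomquant simulate --seed 1 --out sim/
aomquant quantify --counts sim/counts.tsv --geometry sim/geometry.yaml --out bv.tsv
aomquant fish     --probe-counts sim/probe_counts.tsv --geometry sim/geometry.yaml --out fish.tsv
aomquant growth   --counts sim/counts.tsv --fish sim/probe_counts.tsv \
                  --geometry sim/geometry.yaml --delta-t-days 286 --out growth.tsv
aomquant clones   --clones sim/clones.tsv --out clones_pct.tsv
aomquant report   --growth growth.tsv
```

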