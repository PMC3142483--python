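# Methods

## Observation model

A slurry sample is diluted by a factor *D*, a volume *V* (ml) is filtered
onto a filter of effective area *A_f* (µm²), and objects are counted in
microscope fields of area *a* (µm²). The mean per-field count of an object
class converts to a slurry concentration through one scale factor

    scale = (A_f / a) / V · D        [1/ml],

implemented in `MicroscopeGeometry`. Counts are recorded separately for
free single cells and for aggregates binned by integer diameter class Ø
(2–15 µm by default); the class label is used directly as the sphere
diameter (reports in this field quote per-integer classes and no
bin-midpoint rule; a `diameter_map` can override any class). Every object is
treated as a solid sphere of biomass — no porosity or packing correction —
so class c contributes `N_c · (π/6) Ø_c³` µm³/ml and single cells
`N_cells · (π/6) d³` with d = 0.45 µm, the field's standard average
ANME/SRB cell diameter (a literature value, not re-measured here; it is a
parameter of every model object).

Counting follows the replicated-staining design: *k* independent stainings
(default 4), *n* fields each (default 50). Per-field counts are averaged
within a staining, and all reported means and standard errors are taken
across stainings (sample SD with the n−1 denominator over √k). Averaging
per staining before summarising — rather than pooling all k·n fields — is
the convention adopted here; pooling would change SEs whenever stainings
differ systematically. With one staining the mean is reported and the SE is
flagged undefined (NaN) with a warning. The aggregate biovolume share of a
zero-biovolume replicate is defined as 0 (with a warning) to avoid 0/0.

All internal volumes are µm³ and concentrations per ml slurry
(1 ml = 10¹² µm³); months are 30.44 days (mean Gregorian month,
configurable).

## CARD-FISH composition

Each probe hybridization is an independent experiment counted against a
DAPI counterstain in the same fields. The fraction of a category
(cells / aggregates / biovolume) is the ratio of weighted sums over a
staining's fields — weights 1 for the count categories, spherical volume
for the biovolume category (single cells included at the 0.45 µm volume;
the volume weighting is the only self-consistent reading of a
"% of biovolume" column) — summarised across stainings like any other
replicate quantity. Because the probe and DAPI counts share every geometry
factor, fractions are invariant to dilution, filtration geometry, and to
washing losses under the equal-washout assumption. Probe fractions are
*not* forced to sum to 1: single-probe hybridizations can double-count
consortia in which ANME-2 aggregates also contain SRB.

A probe with zero positives across all fields is reported "below detection"
with an upper-bound concentration instead of a point estimate: by default
the concentration implied by exactly one object in all fields examined
(k·n), with a one-sided Poisson-95% alternative (≈3 expected objects)
available. Under the default bench geometry (below), one object in a single
staining's 50 fields at 2000× dilution corresponds to 4×10⁴ objects/ml —
the usual order of magnitude quoted for such bounds.

## Growth and enrichment

Group biovolume is `V = B·f` (total biovolume × biovolume fraction), with
product-rule SE `V·√(cv_B² + cv_f²)`. "Increased X times" is the relative
increase `(V₂−V₁)/V₁`; the plain ratio `V₂/V₁` is exposed as `fold_change`
alongside, since both conventions circulate. This choice makes the
canonical 2.5× (total), 12.5× (ANME-2) and 8.4× (SRB) factors mutually
consistent with their underlying biovolumes. Doubling time assumes
exponential growth between the two timepoints: `t_d = Δt·ln2 / ln(V₂/V₁)`,
defined only for V₂ > V₁ > 0. Dry weight uses 0.2 g cell dry weight per ml
biovolume (the standard sediment-community assumption; it derives from
small marine isolates and is the dominant systematic uncertainty in any
absolute biomass figure). Washout of biomass during reactor operation is
treated as zero.

Uncertainty propagation defaults to the first-order delta method with the
two timepoints independent: `SE(V₂/V₁) = (V₂/V₁)·√(cv₁²+cv₂²)` and
`SE(t_d) = Δt·ln2/(ln R)²·√(cv₁²+cv₂²)`. A seeded parametric bootstrap
(normal resampling, non-positive draws rejected) is available; it agrees
with the delta method within a few percent for CVs ≤ 0.1 and is the
independent oracle for it in the tests.

Two reporting modes: `full` keeps full precision; `reproduce` rounds group
biovolumes to 2 significant figures before deriving ratios and prints
factors, times and dry weights at 1 decimal — the arithmetic of reports
that quote printed intermediates. The two modes differ visibly: the ANME-2
increase is 12.5 from the 2-s.f. intermediates (1.7×10⁸, 2.3×10⁹) but 12.2
at full precision, while the SRB 8.4 requires the unrounded products; both
numbers are honest, they condition on different roundings.

## Clone libraries

Group percentage = 100 × clones in group / clones sequenced. The
FISH-concordance report flags `library_only` / `fish_only` groups and, for
a group FISH estimates at frequency f but absent among n sequenced clones,
the multinomial absence probability `(1−f)ⁿ` — e.g. a 2% group missing from
50 clones has absence probability 0.36, so such an absence is weak evidence
of a false-positive hybridization.

## Synthetic data

Field counts are Poisson per field and class with mean
`λ_c = N_c / scale` — the dilute, well-mixed-slurry assumption; an optional
negative-binomial knob (variance µ + µ²/k) models aggregate clumping, which
real filters can show and the default does not. Probe tables draw fresh
Poisson DAPI counts per hybridization (each probe occupies its own filter
piece) at a washout-thinned expectation `q·λ_c` (default retention q = 0.8,
applied equally to every class so that fraction estimators can be tested
for washout invariance), then probe positives ~ Binomial(DAPI, f_c). Clone
libraries are Multinomial(n, composition). All streams derive from one
global seed via stable name-keyed sub-seeds, so adding a stage never
perturbs existing draws and fixed seeds give byte-identical tables.

### Geometry defaults

The bench geometry is not part of the published record for this kind of
experiment, so absolute concentrations are unverifiable without a config;
every ratio (fractions, increases, doubling times) is geometry-invariant.
The defaults — 2.5 cm filter with 2.0 cm effective diameter (A_f = π·10⁸
µm²), 200 µm field of view at 1000× (a = π·10⁴ µm², area ratio exactly
10⁴), V = 10 ml — were chosen so that (i) the one-object-per-staining
detection bound at 2000× dilution lands at 4×10⁴ objects/ml and (ii) the
implied per-field counts (~60 single cells, ~6 aggregates per field) give
staining-replicate SEs of the magnitude such studies print.

### The `paper_scenario` preset

The preset encodes the canonical two-timepoint high-pressure AOM enrichment
conditions: totals 1.28×10⁹ (S1, 2000× dilution) and 4.49×10⁹ µm³/ml (S2,
5600×) 286 days apart; mid-band (6–10 µm) biovolume shares 52.73%/47.02%
and big-band (11–15 µm) 26.67%/33.34%; small aggregates (2–5 µm)
73.35%/73.28% of aggregate counts; S1 big-band concentration 2.22×10⁵/ml;
the published per-probe fractions of cells, aggregates and biovolume; clone
libraries of 50 (archaea: 88% ANME-2a, 12% MBG-D) and 100 (bacteria)
sequenced clones. The per-class distribution is under-determined by these
summaries; within each band the count weights are geometric with ratios
solved exactly against them, single cells are fixed at 10× the aggregate
count (one order more abundant; this yields an aggregate biovolume share of
~99.6%, marginally below the quoted 99.7% — the published count ratio and
biovolume share cannot both hold exactly), and per-class probe fractions
are linear in sphere volume, clipped to [0,1], solved to hit each probe's
aggregate-count and biovolume fractions simultaneously. One published
figure is arithmetically infeasible: an S2 big-band concentration of
4.93×10⁵/ml cannot carry 33.34% of 4.49×10⁹ µm³/ml (it would need a mean
aggregate volume above the 15 µm sphere maximum), so S2 reuses S1's
big-band size shape and that concentration floats to ~1×10⁶/ml.

The implied ANME-2 truth of the preset — V₁ = 1.715×10⁸,
V₂ = 2.263×10⁹ µm³/ml — corresponds to a doubling time of 2.52 months; the
full-loop acceptance test recovers it within 15% at the study's own 4×50
design and within 5% at 4×5000 fields.

### What the simulator does not emulate

Spatial consortium architecture (shell/core ANME/SRB geometry),
hybridization efficiency and mis-hybridization, EPS, diameter-measurement
error, operator variability between stainings beyond Poisson noise, and any
real overlap between probe groups (the preset's groups are effectively
disjoint). Passing recovery tests therefore demonstrates estimator
correctness under the declared sampling laws, not robustness to these
real-data effects.

## Numerical choices and degenerate inputs

Negative diameters, fractions outside [0,1], zero filtered volume or field
area, probe counts exceeding DAPI, duplicate (sample, replicate, field,
type, class) rows, unknown diameter classes and V₂ ≤ V₁ doubling-time
requests all raise typed errors (`aomquant.errors`). Biovolume totals are
exact linear combinations of per-class terms, so conservation holds to
floating-point (tested at 1e-9 relative). Writers are atomic (temp file +
rename): invalid input never leaves partial output. Run manifests contain
parameters only, no timestamps, so reruns are byte-identical.

## Problem sizes

Default analyses and simulations use the study's own design (2 samples ×
4 stainings × 50 fields, 14 aggregate classes, 4 probes); the convergence
check scales the same pipeline to 4 × 5000 fields. The whole test suite and
the acceptance script each run in well under a minute on one CPU.
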