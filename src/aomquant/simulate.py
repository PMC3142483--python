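"""Synthetic data generator for the full quantification pipeline.

A :class:`TruthModel` declares, per sample, the true object concentrations
(single cells and each aggregate diameter class), per-probe fractions, and
the counting design (staining replicates x fields, geometry).  From it the
module draws

* DAPI field counts — Poisson per field and class with mean
  ``lambda_c = concentration_c / geometry.scale_factor`` (dilute, well-mixed
  slurry; an optional negative-binomial knob models clumping),
* probe/DAPI paired counts — each hybridization gets its own filter, so its
  DAPI counts are fresh Poisson draws, thinned by a common washout-retention
  factor applied equally to every class (the equal-washout assumption);
  probe positives are Binomial(dapi, group fraction) per field and class,
* clone libraries — Multinomial(n sequenced, community composition).

All randomness is derived from one global seed via stable named streams, so
adding a simulation stage never perturbs existing draws and a fixed seed
reproduces byte-identical tables.

The :func:`paper_scenario` preset encodes the canonical two-timepoint
high-pressure AOM enrichment study conditions: total biovolumes 1.28e9 and
4.49e9 um^3/ml slurry 286 days apart, the published probe fractions, size
structure (small 2-5 um aggregates ~73% of aggregate counts, mid classes
~half the biovolume), clone-library sizes (50/100 sequenced) and the
4 stainings x 50 fields counting design.  The per-class size distribution is
under-determined by the published summaries; the preset resolves it with
geometric within-band count weights solved against the printed shares (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .biovolume import sphere_volume
from .clones import CloneLibrary
from .errors import InvalidInputError
from .geometry import MicroscopeGeometry
from .util import DAYS_PER_MONTH, SINGLE_CELL_DIAMETER_UM, rng_for

__all__ = [
    "TruthModel",
    "StudyTruth",
    "PROBES",
    "PROBE_GROUPS",
    "simulate_counts",
    "simulate_probe_counts",
    "simulate_clone_library",
    "simulate_study",
    "evolve",
    "paper_scenario",
]

#: CARD-FISH probes and the groups they target
PROBE_GROUPS = {
    "ANME1-350": "ANME-1",
    "EelMS932": "ANME-2",
    "ANME3-1249": "ANME-3",
    "DSS658": "SRB",
}
PROBES = tuple(PROBE_GROUPS)

MAX_LAMBDA_PER_FIELD = 1.0e6


@dataclass
class TruthModel:
    """Declared ground truth for one sample.

    Concentrations are objects/ml slurry; fractions lie in [0, 1] per class.
    ``washout_retention`` is the fraction of objects surviving CARD-FISH
    washing (applied equally to all classes); ``overdispersion`` switches the
    count law from Poisson to negative binomial with that shape parameter
    (variance = mu + mu^2/k, smaller k = clumpier).
    """

    sample_id: str
    geometry: MicroscopeGeometry
    single_cell_concentration: float
    class_concentrations: Mapping[int, float]
    probe_single_fractions: Mapping[str, float] = field(default_factory=dict)
    probe_class_fractions: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    n_replicates: int = 4
    n_fields: int = 50
    washout_retention: float = 1.0
    overdispersion: float | None = None
    single_cell_diameter: float = SINGLE_CELL_DIAMETER_UM

    def __post_init__(self) -> None:
        if self.single_cell_concentration < 0 or any(
                v < 0 for v in self.class_concentrations.values()):
            raise InvalidInputError("concentrations must be >= 0")
        for probe, f in self.probe_single_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise InvalidInputError(f"single-cell fraction for {probe} outside [0,1]")
        for probe, fr in self.probe_class_fractions.items():
            if any(not 0.0 <= f <= 1.0 for f in fr.values()):
                raise InvalidInputError(f"class fraction for {probe} outside [0,1]")
        if not 0.0 < self.washout_retention <= 1.0:
            raise InvalidInputError("washout_retention must lie in (0, 1]")
        if self.n_replicates < 1 or self.n_fields < 1:
            raise InvalidInputError("need >=1 replicate and >=1 field")

    # -- derived truth ----------------------------------------------------

    @property
    def classes(self) -> list[int]:
        return sorted(self.class_concentrations)

    def total_biovolume(self) -> float:
        v = sum(c * sphere_volume(float(d))
                for d, c in self.class_concentrations.items())
        return v + self.single_cell_concentration * sphere_volume(self.single_cell_diameter)

    def group_biovolume(self, probe: str) -> float:
        fr = self.probe_class_fractions.get(probe, {})
        v = sum(self.class_concentrations[d] * fr.get(d, 0.0) * sphere_volume(float(d))
                for d in self.classes)
        fs = self.probe_single_fractions.get(probe, 0.0)
        return v + self.single_cell_concentration * fs * sphere_volume(self.single_cell_diameter)

    def group_fraction(self, probe: str, category: str) -> float:
        """True fraction of the given category attributable to a probe's group."""
        fr = self.probe_class_fractions.get(probe, {})
        n_c = np.array([self.class_concentrations[d] for d in self.classes])
        f_c = np.array([fr.get(d, 0.0) for d in self.classes])
        if category == "cells":
            return self.probe_single_fractions.get(probe, 0.0)
        if category == "aggregates":
            return float((n_c * f_c).sum() / n_c.sum()) if n_c.sum() > 0 else 0.0
        if category == "biovolume":
            return self.group_biovolume(probe) / self.total_biovolume()
        raise InvalidInputError(f"unknown category {category!r}")

    def to_dict(self) -> dict:
        return dict(
            sample_id=self.sample_id,
            geometry=dict(dilution_factor=self.geometry.dilution_factor,
                          filtered_volume_ml=self.geometry.filtered_volume_ml,
                          filter_effective_area_um2=self.geometry.filter_effective_area_um2,
                          field_area_um2=self.geometry.field_area_um2),
            single_cell_concentration=float(self.single_cell_concentration),
            class_concentrations={int(k): float(v)
                                  for k, v in self.class_concentrations.items()},
            probe_single_fractions={k: float(v)
                                    for k, v in self.probe_single_fractions.items()},
            probe_class_fractions={p: {int(k): float(v) for k, v in fr.items()}
                                   for p, fr in self.probe_class_fractions.items()},
            n_replicates=self.n_replicates, n_fields=self.n_fields,
            washout_retention=float(self.washout_retention),
            overdispersion=self.overdispersion,
            single_cell_diameter=float(self.single_cell_diameter),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "TruthModel":
        d = dict(d)
        d["geometry"] = MicroscopeGeometry.from_dict(d["geometry"])
        d["class_concentrations"] = {int(k): v
                                     for k, v in d["class_concentrations"].items()}
        d["probe_class_fractions"] = {p: {int(k): v for k, v in fr.items()}
                                      for p, fr in d["probe_class_fractions"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# count sampling

def _draw_counts(rng: np.random.Generator, lam: float, size: int,
                 overdispersion: float | None) -> np.ndarray:
    if lam > MAX_LAMBDA_PER_FIELD:
        raise InvalidInputError(
            f"per-field expectation {lam:.3g} exceeds {MAX_LAMBDA_PER_FIELD:g}; "
            "increase the dilution factor or reduce concentrations")
    if lam == 0:
        return np.zeros(size, dtype=np.int64)
    if overdispersion is None:
        return rng.poisson(lam, size=size)
    k = float(overdispersion)
    return rng.negative_binomial(k, k / (k + lam), size=size)


def _field_lambda(truth: TruthModel, concentration: float) -> float:
    return concentration / truth.geometry.scale_factor


def simulate_counts(truth: TruthModel, seed: int) -> pd.DataFrame:
    """Draw a DAPI count table (io schema) for one sample."""
    rng = rng_for(seed, f"counts:{truth.sample_id}")
    n = truth.n_replicates * truth.n_fields
    reps = np.repeat([str(i + 1) for i in range(truth.n_replicates)], truth.n_fields)
    fields = np.tile([str(i + 1) for i in range(truth.n_fields)], truth.n_replicates)
    frames = [pd.DataFrame(dict(
        sample_id=truth.sample_id, replicate_id=reps, field_id=fields,
        object_type="single_cell", diameter_class_um=np.nan,
        count=_draw_counts(rng, _field_lambda(truth, truth.single_cell_concentration),
                           n, truth.overdispersion)))]
    for d in truth.classes:
        lam = _field_lambda(truth, truth.class_concentrations[d])
        frames.append(pd.DataFrame(dict(
            sample_id=truth.sample_id, replicate_id=reps, field_id=fields,
            object_type="aggregate", diameter_class_um=float(d),
            count=_draw_counts(rng, lam, n, truth.overdispersion))))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["replicate_id", "field_id", "object_type", "diameter_class_um"],
                          na_position="first", kind="stable").reset_index(drop=True)


def simulate_probe_counts(truth: TruthModel, seed: int,
                          probes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Draw paired probe/DAPI counts for each hybridization of one sample.

    Each probe is hybridized on its own filter piece, so its DAPI counts are
    independent Poisson draws at the washout-thinned expectation; positives
    are binomial in the DAPI count with the class's true group fraction.
    """
    if probes is None:
        probes = tuple(sorted(set(truth.probe_single_fractions)
                              | set(truth.probe_class_fractions)))
    q = truth.washout_retention
    n = truth.n_replicates * truth.n_fields
    reps = np.repeat([str(i + 1) for i in range(truth.n_replicates)], truth.n_fields)
    fields = np.tile([str(i + 1) for i in range(truth.n_fields)], truth.n_replicates)
    frames = []
    for probe in probes:
        rng = rng_for(seed, f"probes:{truth.sample_id}:{probe}")
        fs = truth.probe_single_fractions.get(probe, 0.0)
        dapi = _draw_counts(rng, q * _field_lambda(truth, truth.single_cell_concentration),
                            n, truth.overdispersion)
        pos = rng.binomial(dapi, fs)
        frames.append(pd.DataFrame(dict(
            sample_id=truth.sample_id, probe_id=probe, replicate_id=reps,
            field_id=fields, object_type="single_cell", diameter_class_um=np.nan,
            probe_count=pos, dapi_count=dapi)))
        cls_fr = truth.probe_class_fractions.get(probe, {})
        for d in truth.classes:
            lam = q * _field_lambda(truth, truth.class_concentrations[d])
            dapi = _draw_counts(rng, lam, n, truth.overdispersion)
            pos = rng.binomial(dapi, cls_fr.get(d, 0.0))
            frames.append(pd.DataFrame(dict(
                sample_id=truth.sample_id, probe_id=probe, replicate_id=reps,
                field_id=fields, object_type="aggregate", diameter_class_um=float(d),
                probe_count=pos, dapi_count=dapi)))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["probe_id", "replicate_id", "field_id", "object_type",
                           "diameter_class_um"],
                          na_position="first", kind="stable").reset_index(drop=True)


def simulate_clone_library(composition: Mapping[str, float], n_sequenced: int,
                           seed: int, domain: str = "archaea",
                           clones_obtained: int | None = None) -> CloneLibrary:
    """Draw a clone library: group counts ~ Multinomial(n, composition)."""
    if n_sequenced <= 0:
        raise InvalidInputError("n_sequenced must be > 0")
    groups = list(composition)
    p = np.array([composition[g] for g in groups], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise InvalidInputError("composition must be non-negative and sum to 1")
    rng = rng_for(seed, f"clones:{domain}")
    counts = rng.multinomial(n_sequenced, p / p.sum())
    return CloneLibrary(domain=domain,
                        clones_obtained=clones_obtained or n_sequenced,
                        clones_sequenced=n_sequenced,
                        group_counts=dict(zip(groups, (int(c) for c in counts))))


# ---------------------------------------------------------------------------
# exponential growth of the truth

def evolve(truth: TruthModel, elapsed_days: float,
           doubling_times_months: Mapping[str, float],
           background_doubling_months: float | None = None) -> TruthModel:
    """Scale each probe group's abundance by exponential growth.

    Each group grows by ``2 ** (elapsed_days / (t_d * 30.44))``; class
    concentrations are rescaled proportionally within the group, and the
    probes are treated as disjoint for this purpose (any remainder of a
    class is 'background', growing at ``background_doubling_months`` or not
    at all).
    """
    if elapsed_days < 0:
        raise InvalidInputError("elapsed_days must be >= 0")
    for p, td in doubling_times_months.items():
        if td <= 0:
            raise InvalidInputError(f"doubling time for {p} must be > 0")

    def factor(td: float | None) -> float:
        if td is None:
            return 1.0
        return 2.0 ** (elapsed_days / (td * DAYS_PER_MONTH))

    bg = factor(background_doubling_months)
    probes = list(doubling_times_months)
    new_cls: dict[int, float] = {}
    new_fr: dict[str, dict[int, float]] = {p: {} for p in truth.probe_class_fractions}
    for d, conc in truth.class_concentrations.items():
        parts = {p: conc * truth.probe_class_fractions.get(p, {}).get(d, 0.0)
                 for p in probes}
        rest = conc - sum(parts.values())
        if rest < -1e-9 * max(conc, 1.0):
            raise InvalidInputError("probe fractions exceed 1 in a class; evolve "
                                    "requires disjoint groups")
        total = sum(parts[p] * factor(doubling_times_months[p]) for p in probes) \
            + max(rest, 0.0) * bg
        new_cls[d] = total
        for p in truth.probe_class_fractions:
            grown = parts.get(p, 0.0) * factor(doubling_times_months.get(p))
            new_fr[p][d] = grown / total if total > 0 else 0.0
    sc_parts = {p: truth.single_cell_concentration
                * truth.probe_single_fractions.get(p, 0.0) for p in probes}
    sc_rest = truth.single_cell_concentration - sum(sc_parts.values())
    sc_total = sum(sc_parts[p] * factor(doubling_times_months[p]) for p in probes) \
        + max(sc_rest, 0.0) * bg
    new_sf = {p: (sc_parts.get(p, 0.0) * factor(doubling_times_months.get(p)) / sc_total
                  if sc_total > 0 else 0.0)
              for p in truth.probe_single_fractions}
    return replace(truth, single_cell_concentration=sc_total,
                   class_concentrations=new_cls,
                   probe_single_fractions=new_sf,
                   probe_class_fractions=new_fr)


# ---------------------------------------------------------------------------
# the calibrated two-timepoint preset

SMALL = tuple(range(2, 6))
MID = tuple(range(6, 11))
BIG = tuple(range(11, 16))


def _geometric_weights(k: int, r: float) -> np.ndarray:
    w = r ** np.arange(k)
    return w / w.sum()


def _mean_volume(classes: tuple[int, ...], r: float) -> float:
    v = sphere_volume(np.array(classes, dtype=float))
    return float(_geometric_weights(len(classes), r) @ v)


def _solve_band_ratio(classes: tuple[int, ...], target_mean_volume: float) -> float:
    """Geometric count-weight ratio giving the requested mean sphere volume."""
    v = sphere_volume(np.array(classes, dtype=float))
    if not v.min() < target_mean_volume < v.max():
        raise InvalidInputError(
            f"target mean volume {target_mean_volume:.4g} infeasible for classes {classes}")
    return optimize.brentq(lambda lr: _mean_volume(classes, np.exp(lr)) - target_mean_volume,
                           -12.0, 12.0, xtol=1e-12)


def _solve_class_concentrations(total_biovolume: float, mid_share: float,
                                big_share: float, small_count_share: float,
                                big_mean_volume: float,
                                singles_per_aggregate: float = 10.0,
                                r_mid: float = 0.75) -> tuple[float, dict[int, float]]:
    """Per-class truth concentrations consistent with published summaries.

    Within each diameter band (small 2-5, mid 6-10, big 11-15 um) the count
    distribution is geometric; the free ratios are solved so that the mid
    and big bands carry the stated biovolume shares, the small band carries
    the stated share of aggregate counts, the big band has the stated mean
    aggregate volume, and single cells are ``singles_per_aggregate`` times
    as numerous as aggregates.  Returns (single-cell concentration, class
    concentration map).
    """
    b_mid = mid_share * total_biovolume
    b_big = big_share * total_biovolume
    n_mid = b_mid / _mean_volume(MID, r_mid)
    r_big = np.exp(_solve_band_ratio(BIG, big_mean_volume))
    n_big = b_big / big_mean_volume
    n_small = small_count_share / (1.0 - small_count_share) * (n_mid + n_big)
    n_agg = n_small + n_mid + n_big
    n_singles = singles_per_aggregate * n_agg
    b_singles = n_singles * sphere_volume(SINGLE_CELL_DIAMETER_UM)
    b_small = total_biovolume - b_mid - b_big - b_singles
    if b_small <= 0:
        raise InvalidInputError("infeasible preset: no biovolume left for small band")
    r_small = np.exp(_solve_band_ratio(SMALL, b_small / n_small))
    conc: dict[int, float] = {}
    for band, n_band, r in ((SMALL, n_small, r_small), (MID, n_mid, r_mid),
                            (BIG, n_big, r_big)):
        w = _geometric_weights(len(band), r)
        for d, wi in zip(band, w):
            conc[d] = float(n_band * wi)
    return float(n_singles), conc


def _solve_fraction_curve(conc: Mapping[int, float], single_conc: float,
                          single_fraction: float, count_target: float,
                          biovolume_target: float) -> dict[int, float]:
    """Per-class group fractions hitting aggregate-count and biovolume targets.

    The curve is linear in sphere volume, clipped to [0, 1]: enough freedom
    to represent groups concentrated in small aggregates (count share above
    biovolume share) or in large ones (the reverse).
    """
    classes = sorted(conc)
    n = np.array([conc[d] for d in classes], dtype=float)
    v = sphere_volume(np.array(classes, dtype=float))
    u = v / v.max()
    vs = sphere_volume(SINGLE_CELL_DIAMETER_UM)
    w_total = float((n * v).sum() + single_conc * vs)
    single_term = single_conc * single_fraction * vs

    def achieved(params: np.ndarray) -> np.ndarray:
        f = np.clip(params[0] + params[1] * u, 0.0, 1.0)
        cnt = (n * f).sum() / n.sum()
        bv = ((n * f * v).sum() + single_term) / w_total
        return np.array([cnt, bv])

    target = np.array([count_target, biovolume_target])
    # exact linear solve ignoring clipping, then derivative-free refinement
    a_mat = np.array([[1.0, (n * u).sum() / n.sum()],
                      [(n * v).sum() / w_total, (n * u * v).sum() / w_total]])
    b_vec = np.array([count_target, biovolume_target - single_term / w_total])
    params = np.linalg.solve(a_mat, b_vec)
    if np.max(np.abs(achieved(params) - target)) > 1e-6:
        res = optimize.minimize(lambda p: float(((achieved(p) - target) ** 2).sum()),
                                params, method="Nelder-Mead",
                                options=dict(xatol=1e-10, fatol=1e-16, maxiter=2000))
        params = res.x
    f = np.clip(params[0] + params[1] * u, 0.0, 1.0)
    return {d: float(fi) for d, fi in zip(classes, f)}


@dataclass
class StudyTruth:
    """Ground truth of a two-timepoint enrichment study."""

    s1: TruthModel
    s2: TruthModel
    delta_t_days: float
    archaeal_composition: Mapping[str, float]
    bacterial_composition: Mapping[str, float]
    archaeal_n_sequenced: int = 50
    archaeal_n_obtained: int = 56
    bacterial_n_sequenced: int = 100
    bacterial_n_obtained: int = 110

    def doubling_time_months(self, probe: str) -> float:
        v1, v2 = self.s1.group_biovolume(probe), self.s2.group_biovolume(probe)
        return float(self.delta_t_days * np.log(2.0) / np.log(v2 / v1) / DAYS_PER_MONTH)


def paper_scenario(washout_retention: float = 0.8) -> StudyTruth:
    """The calibrated two-timepoint high-pressure AOM enrichment scenario.

    Encodes: total biovolumes 1.28e9 (S1) / 4.49e9 (S2) um^3/ml slurry;
    dilutions 2000x / 5600x; mid-band biovolume shares 52.73% / 47.02% and
    big-band 26.67% / 33.34%; small aggregates 73.35% / 73.28% of aggregate
    counts; S1 big-band concentration 2.22e5/ml; published probe fractions
    of cells/aggregates/biovolume per probe; 286 days between samples.  The
    published S2 big-band concentration (4.93e5/ml) is arithmetically
    incompatible with its biovolume share (it would need a mean aggregate
    volume above the 15 um maximum), so S2 reuses S1's big-band size shape
    and lets that concentration float (~1e6/ml).
    """
    total1, total2 = 1.28e9, 4.49e9
    big_mean_1 = 0.2667 * total1 / 2.22e5
    sc1, conc1 = _solve_class_concentrations(total1, 0.5273, 0.2667, 0.7335, big_mean_1)
    sc2, conc2 = _solve_class_concentrations(total2, 0.4702, 0.3334, 0.7328, big_mean_1)

    # Table-2 targets: (cells, aggregates, biovolume) per probe and sample
    targets = {
        "S1": {"EelMS932": (0.082, 0.371, 0.134),
               "DSS658": (0.029, 0.320, 0.227),
               "ANME3-1249": (0.001, 0.021, 0.015),
               "ANME1-350": (0.0, 0.0, 0.0)},
        "S2": {"EelMS932": (0.025, 0.472, 0.504),
               "DSS658": (0.008, 0.376, 0.606),
               "ANME3-1249": (0.001, 0.008, 0.024),
               "ANME1-350": (0.0, 0.0, 0.0)},
    }

    def build(sample_id: str, dilution: float, sc: float,
              conc: Mapping[int, float]) -> TruthModel:
        singles_fr: dict[str, float] = {}
        class_fr: dict[str, dict[int, float]] = {}
        for probe, (f_cells, f_cnt, f_bv) in targets[sample_id].items():
            singles_fr[probe] = f_cells
            if f_cnt == 0.0 and f_bv == 0.0:
                class_fr[probe] = {d: 0.0 for d in conc}
            else:
                class_fr[probe] = _solve_fraction_curve(conc, sc, f_cells, f_cnt, f_bv)
        return TruthModel(
            sample_id=sample_id,
            geometry=MicroscopeGeometry.default(dilution_factor=dilution),
            single_cell_concentration=sc, class_concentrations=conc,
            probe_single_fractions=singles_fr, probe_class_fractions=class_fr,
            washout_retention=washout_retention)

    return StudyTruth(
        s1=build("S1", 2000.0, sc1, conc1),
        s2=build("S2", 5600.0, sc2, conc2),
        delta_t_days=286.0,
        archaeal_composition={"ANME-2a": 0.88, "MBG-D": 0.12},
        bacterial_composition={"Gammaproteobacteria": 0.43, "Deltaproteobacteria": 0.09,
                               "SEEP-SRB1a": 0.08, "Other": 0.40},
    )


def simulate_study(truth: StudyTruth, seed: int) -> dict:
    """Draw every table of the study: DAPI counts, probe counts, clones."""
    counts = pd.concat([simulate_counts(truth.s1, seed), simulate_counts(truth.s2, seed)],
                       ignore_index=True)
    probes = pd.concat([simulate_probe_counts(truth.s1, seed),
                        simulate_probe_counts(truth.s2, seed)], ignore_index=True)
    archaea = simulate_clone_library(truth.archaeal_composition,
                                     truth.archaeal_n_sequenced, seed, "archaea",
                                     truth.archaeal_n_obtained)
    bacteria = simulate_clone_library(truth.bacterial_composition,
                                      truth.bacterial_n_sequenced, seed, "bacteria",
                                      truth.bacterial_n_obtained)
    return dict(counts=counts, probe_counts=probes, clone_libraries=[archaea, bacteria])
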