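"""DAPI field counts -> concentrations and spherical biovolume per size class.

The observation model: a slurry sample is diluted, filtered, DAPI-stained and
counted in ``n`` microscope fields per staining replicate, recording free
single cells and aggregates binned by integer diameter class (um).  Both
cells and aggregates are treated as solid spheres, so an object of diameter
``d`` contributes ``(pi/6) d^3`` um^3.  Per-field counts are averaged within
each staining replicate, scaled to objects/ml slurry through the
:class:`~aomquant.geometry.MicroscopeGeometry`, and the mean and standard
error of every quantity are taken across the staining replicates (n-1 sample
SD / sqrt(k)), mirroring the 4-stainings x 50-fields design.

Single cells use a fixed representative diameter (0.45 um, the field's
standard average for ANME/SRB cells); aggregates use their class label as the
sphere diameter unless a ``diameter_map`` overrides it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError
from .geometry import MicroscopeGeometry
from .io import validate_counts
from .util import SINGLE_CELL_DIAMETER_UM

__all__ = [
    "sphere_volume",
    "counts_to_concentration",
    "replicate_summary",
    "SizeClassCounts",
    "BiovolumeModel",
    "SampleBiovolumeResults",
    "quantify_sample",
]

DEFAULT_CLASSES = tuple(range(2, 16))  # 2..15 um aggregate diameter classes


def sphere_volume(diameter):
    """Volume of a sphere of the given diameter, (pi/6) d^3.

    Accepts scalars or arrays (um -> um^3).  Negative diameters are invalid.
    """
    d = np.asarray(diameter, dtype=float)
    if np.any(d < 0):
        raise InvalidInputError("diameter must be >= 0")
    v = np.pi / 6.0 * d**3
    return float(v) if np.isscalar(diameter) or d.ndim == 0 else v


def counts_to_concentration(per_field_counts: Sequence[float],
                            geometry: MicroscopeGeometry) -> float:
    """Convert one replicate's per-field counts to objects/ml slurry.

    mean(count/field) * (filter_area / field_area) / filtered_volume
    * dilution_factor.
    """
    counts = np.asarray(per_field_counts, dtype=float)
    if counts.size == 0:
        raise InvalidInputError("need at least one field per replicate")
    if np.any(counts < 0):
        raise InvalidInputError("counts must be >= 0")
    return float(counts.mean() * geometry.scale_factor)


def replicate_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error across staining replicates.

    SE is the n-1 sample standard deviation over sqrt(k).  A single
    replicate yields ``(mean, nan)`` with a warning; SE is then undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InvalidInputError("replicate_summary of empty input")
    if x.size == 1:
        warnings.warn("single replicate: standard error undefined", stacklevel=2)
        return float(x[0]), float("nan")
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))


@dataclass
class SizeClassCounts:
    """One (replicate, field) DAPI observation.

    ``aggregate_counts`` maps diameter class (um, int) -> count.
    """

    sample_id: str
    replicate_id: str
    field_id: str
    single_cell_count: int = 0
    aggregate_counts: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.single_cell_count < 0 or any(v < 0 for v in self.aggregate_counts.values()):
            raise InvalidInputError("counts must be >= 0")

    def to_rows(self) -> list[dict]:
        rows = [dict(sample_id=self.sample_id, replicate_id=self.replicate_id,
                     field_id=self.field_id, object_type="single_cell",
                     diameter_class_um=np.nan, count=self.single_cell_count)]
        for c, n in sorted(self.aggregate_counts.items()):
            rows.append(dict(sample_id=self.sample_id, replicate_id=self.replicate_id,
                             field_id=self.field_id, object_type="aggregate",
                             diameter_class_um=c, count=n))
        return rows

    @staticmethod
    def set_to_frame(records: Iterable["SizeClassCounts"]) -> pd.DataFrame:
        rows = [r for rec in records for r in rec.to_rows()]
        return validate_counts(pd.DataFrame(rows))

    @staticmethod
    def set_from_frame(df: pd.DataFrame) -> list["SizeClassCounts"]:
        df = validate_counts(df)
        out = []
        for (s, r, f), sub in df.groupby(["sample_id", "replicate_id", "field_id"], sort=False):
            singles = int(sub.loc[sub.object_type == "single_cell", "count"].sum())
            aggs = {int(row.diameter_class_um): int(row["count"])
                    for _, row in sub[sub.object_type == "aggregate"].iterrows()}
            out.append(SizeClassCounts(s, r, f, singles, aggs))
        return out


class BiovolumeModel:
    """Estimator of per-class concentrations and biovolume for one sample.

    Parameters
    ----------
    data : pandas.DataFrame
        Tidy count table (see :mod:`aomquant.io` schema); must contain a
        single ``sample_id`` unless one is selected explicitly.
    geometry : MicroscopeGeometry
    single_cell_diameter : float, um
    diameter_map : mapping, optional
        class label -> representative sphere diameter (default: identity).
    allowed_classes : iterable of int or None
        Accepted aggregate diameter classes (default 2..15); a count in any
        other class raises :class:`~aomquant.errors.SchemaError`.
    """

    def __init__(self, data: pd.DataFrame, geometry: MicroscopeGeometry,
                 single_cell_diameter: float = SINGLE_CELL_DIAMETER_UM,
                 diameter_map: Mapping[int, float] | None = None,
                 allowed_classes: Iterable[int] | None = DEFAULT_CLASSES,
                 sample_id: str | None = None):
        df = validate_counts(data)
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
            if df.empty:
                raise InvalidInputError(f"no rows for sample_id={sample_id!r}")
        samples = df["sample_id"].unique()
        if len(samples) != 1:
            raise InvalidInputError(
                "BiovolumeModel fits one sample at a time; pass sample_id= to select one "
                f"of {sorted(samples)}")
        if single_cell_diameter <= 0:
            raise InvalidInputError("single_cell_diameter must be > 0")
        classes = sorted(int(c) for c in
                         df.loc[df.object_type == "aggregate", "diameter_class_um"].unique())
        if allowed_classes is not None:
            allowed = set(int(c) for c in allowed_classes)
            unknown = [c for c in classes if c not in allowed]
            if unknown:
                raise SchemaError(f"unknown diameter class(es): {unknown}")
        self.data = df
        self.geometry = geometry
        self.sample_id = str(samples[0])
        self.single_cell_diameter = float(single_cell_diameter)
        self.diameter_map = dict(diameter_map) if diameter_map else {}
        self.classes = classes

    def class_diameter(self, c: int) -> float:
        return float(self.diameter_map.get(c, c))

    def _per_replicate(self) -> pd.DataFrame:
        """Objects/ml per replicate: one column per class plus 'single_cell'."""
        df = self.data
        scale = self.geometry.scale_factor
        rows = {}
        for rep, sub in df.groupby("replicate_id", sort=True):
            n_fields = sub["field_id"].nunique()
            if n_fields == 0:
                raise InvalidInputError(f"replicate {rep} has no fields")
            rec = {}
            singles = sub.loc[sub.object_type == "single_cell", "count"].sum()
            rec["single_cell"] = singles / n_fields * scale
            agg = sub[sub.object_type == "aggregate"]
            per_class = agg.groupby(agg["diameter_class_um"].astype(int))["count"].sum()
            for c in self.classes:
                rec[c] = per_class.get(c, 0) / n_fields * scale
            rows[rep] = rec
        return pd.DataFrame.from_dict(rows, orient="index")

    def fit(self) -> "SampleBiovolumeResults":
        conc = self._per_replicate()
        k = len(conc)
        vol = {c: sphere_volume(self.class_diameter(c)) for c in self.classes}
        vol["single_cell"] = sphere_volume(self.single_cell_diameter)
        bv = conc * pd.Series(vol)

        agg_cols = [c for c in conc.columns if c != "single_cell"]
        rep_total = bv.sum(axis=1)
        rep_agg = bv[agg_cols].sum(axis=1) if agg_cols else pd.Series(0.0, index=bv.index)
        with np.errstate(invalid="ignore"):
            rep_share = np.where(rep_total > 0, rep_agg / rep_total, 0.0)
        if np.any(rep_total == 0):
            warnings.warn("zero total biovolume in >=1 replicate; "
                          "aggregate share defined as 0 there")

        def summ(series) -> tuple[float, float]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return replicate_summary(np.asarray(series, dtype=float))

        per_class = pd.DataFrame(index=pd.Index(self.classes, name="diameter_class_um"))
        for c in self.classes:
            per_class.loc[c, ["concentration_mean", "concentration_se"]] = summ(conc[c])
            per_class.loc[c, ["biovolume_mean", "biovolume_se"]] = summ(bv[c])
        sc_conc = summ(conc["single_cell"])
        sc_bv = summ(bv["single_cell"])
        total = summ(rep_total)
        agg_total = summ(rep_agg)
        share = summ(rep_share)
        if k == 1:
            warnings.warn("single staining replicate: standard errors undefined")
        return SampleBiovolumeResults(
            sample_id=self.sample_id, geometry=self.geometry, n_replicates=k,
            per_class=per_class,
            single_cell_concentration=sc_conc[0], single_cell_concentration_se=sc_conc[1],
            single_cell_biovolume=sc_bv[0], single_cell_biovolume_se=sc_bv[1],
            aggregate_biovolume=agg_total[0], aggregate_biovolume_se=agg_total[1],
            total_biovolume=total[0], total_biovolume_se=total[1],
            aggregate_biovolume_share=share[0], aggregate_biovolume_share_se=share[1],
            _replicate_concentrations=conc,
        )


@dataclass
class SampleBiovolumeResults:
    """Per-class and total concentration/biovolume estimates for one sample.

    Concentrations are objects/ml slurry, biovolumes um^3/ml slurry; all SEs
    are across staining replicates.
    """

    sample_id: str
    geometry: MicroscopeGeometry
    n_replicates: int
    per_class: pd.DataFrame
    single_cell_concentration: float
    single_cell_concentration_se: float
    single_cell_biovolume: float
    single_cell_biovolume_se: float
    aggregate_biovolume: float
    aggregate_biovolume_se: float
    total_biovolume: float
    total_biovolume_se: float
    aggregate_biovolume_share: float
    aggregate_biovolume_share_se: float
    _replicate_concentrations: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        """Tidy output table: one row per class, plus single-cell and totals."""
        rows = []
        for c, r in self.per_class.iterrows():
            rows.append(dict(sample_id=self.sample_id, object_class=str(c),
                             concentration_mean=r.concentration_mean,
                             concentration_se=r.concentration_se,
                             biovolume_mean=r.biovolume_mean, biovolume_se=r.biovolume_se))
        rows.append(dict(sample_id=self.sample_id, object_class="single_cell",
                         concentration_mean=self.single_cell_concentration,
                         concentration_se=self.single_cell_concentration_se,
                         biovolume_mean=self.single_cell_biovolume,
                         biovolume_se=self.single_cell_biovolume_se))
        rows.append(dict(sample_id=self.sample_id, object_class="total_aggregate",
                         concentration_mean=np.nan, concentration_se=np.nan,
                         biovolume_mean=self.aggregate_biovolume,
                         biovolume_se=self.aggregate_biovolume_se))
        rows.append(dict(sample_id=self.sample_id, object_class="total",
                         concentration_mean=np.nan, concentration_se=np.nan,
                         biovolume_mean=self.total_biovolume,
                         biovolume_se=self.total_biovolume_se))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        from .io import format_mean_se

        lines = [
            f"Biovolume quantification — sample {self.sample_id} "
            f"({self.n_replicates} staining replicates)",
            f"  total biovolume:      {format_mean_se(self.total_biovolume, self.total_biovolume_se)} um^3/ml slurry",
            f"  aggregate biovolume:  {format_mean_se(self.aggregate_biovolume, self.aggregate_biovolume_se)} um^3/ml slurry",
            f"  aggregate share:      {100 * self.aggregate_biovolume_share:.1f}% of total biovolume",
            f"  single cells:         {format_mean_se(self.single_cell_concentration, self.single_cell_concentration_se)} cells/ml slurry",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Two-panel bar chart of concentrations and biovolumes by class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.5))
        pc = self.per_class
        ax[0].bar(pc.index, pc.concentration_mean, yerr=pc.concentration_se, color="0.5")
        ax[0].set_xlabel("aggregate diameter class (um)")
        ax[0].set_ylabel("objects/ml slurry")
        ax[1].bar(pc.index, pc.biovolume_mean, yerr=pc.biovolume_se, color="0.3")
        ax[1].set_xlabel("aggregate diameter class (um)")
        ax[1].set_ylabel("biovolume (um^3/ml slurry)")
        return ax


def quantify_sample(counts: pd.DataFrame, geometry: MicroscopeGeometry,
                    single_cell_diameter: float = SINGLE_CELL_DIAMETER_UM,
                    **kwargs) -> SampleBiovolumeResults:
    """Fit a :class:`BiovolumeModel` and return its results in one call."""
    return BiovolumeModel(counts, geometry, single_cell_diameter, **kwargs).fit()
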