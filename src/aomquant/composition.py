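"""CARD-FISH composition: per-probe fractions of cells, aggregates, biovolume.

Each hybridization (one taxon-specific probe: ANME1-350, EelMS932 for ANME-2,
ANME3-1249, DSS658 for SRB) is counted against a DAPI counterstain in the
same fields, so the probe-positive / DAPI ratio estimates the group's share
of the community.  Filter washing may lose objects, but under the standard
assumption that all object types wash out in the same ratio the fractions
are unaffected — and they are likewise invariant to dilution and counting
geometry, which cancel in the ratio.

Fractions are computed per category:

``cells``
    probe-positive single cells / DAPI single cells.
``aggregates``
    probe-positive aggregates / DAPI aggregates, all size classes pooled.
``biovolume``
    as above but each object weighted by its spherical volume (class label
    as diameter; single cells at the 0.45 um default), single cells included.

The point estimate within one staining replicate is the ratio of sums over
its fields; the reported mean ± SE is taken across replicates.  A probe with
zero positives in every field is reported as below detection with an
upper-bound concentration instead of a point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .biovolume import replicate_summary, sphere_volume
from .errors import (InvalidInputError, NotApplicableError, UndefinedFractionError)
from .geometry import MicroscopeGeometry
from .io import BELOW_DETECTION, validate_probe_counts
from .util import SINGLE_CELL_DIAMETER_UM

__all__ = [
    "CATEGORIES",
    "probe_fraction",
    "detection_bound",
    "FractionEstimate",
    "CompositionModel",
    "CompositionResults",
]

CATEGORIES = ("cells", "aggregates", "biovolume")


@dataclass
class FractionEstimate:
    """A fraction in [0, 1] with replicate-based SE and detection status."""

    mean: float
    se: float
    n_blocks: int
    below_detection: bool = False
    detection_bound: float | None = None  # objects/ml slurry, when flagged


def _weights(df: pd.DataFrame, category: str,
             single_cell_diameter: float) -> pd.Series:
    if category == "cells":
        w = (df.object_type == "single_cell").astype(float)
    elif category == "aggregates":
        w = (df.object_type == "aggregate").astype(float)
    elif category == "biovolume":
        d = df.diameter_class_um.where(df.object_type == "aggregate",
                                       single_cell_diameter)
        w = sphere_volume(d.to_numpy(dtype=float))
        w = pd.Series(w, index=df.index)
    else:
        raise InvalidInputError(f"unknown category {category!r}; use one of {CATEGORIES}")
    return w


def probe_fraction(probe_counts: pd.DataFrame, category: str,
                   single_cell_diameter: float = SINGLE_CELL_DIAMETER_UM) -> FractionEstimate:
    """Estimate one probe's fraction of the community for one category.

    ``probe_counts`` is a validated probe table for a single (sample, probe).
    Within each replicate the fraction is sum(w * probe) / sum(w * dapi) over
    its fields; mean and SE are across replicates (SE undefined, NaN, when
    only one replicate block exists).
    """
    df = validate_probe_counts(probe_counts)
    w = _weights(df, category, single_cell_diameter)
    num = w * df.probe_count
    den = w * df.dapi_count
    if den.sum() == 0:
        raise UndefinedFractionError(
            f"all-zero DAPI denominator for category {category!r}")
    by_rep_num = num.groupby(df.replicate_id).sum()
    by_rep_den = den.groupby(df.replicate_id).sum()
    ok = by_rep_den > 0
    if not ok.all():
        warnings.warn("replicate(s) with zero DAPI denominator dropped from SE blocks")
    fracs = (by_rep_num[ok] / by_rep_den[ok]).to_numpy(dtype=float)
    if len(fracs) >= 2:
        mean, se = replicate_summary(fracs)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean, se = float(num.sum() / den.sum()), float("nan")
    return FractionEstimate(mean=mean, se=se, n_blocks=int(ok.sum()))


def detection_bound(total_fields: int, geometry: MicroscopeGeometry,
                    positives: int = 0, method: str = "one_count") -> float:
    """Upper-bound concentration for a probe with zero positive observations.

    ``one_count`` (default): the concentration implied by exactly one object
    in the ``total_fields`` fields examined.  ``poisson95``: the one-sided
    Poisson 95% bound of ~3 expected objects in those fields.
    """
    if positives > 0:
        raise NotApplicableError("detection bound only applies to zero positives")
    if total_fields <= 0:
        raise InvalidInputError("total_fields must be > 0")
    k = {"one_count": 1.0, "poisson95": 3.0}.get(method)
    if k is None:
        raise InvalidInputError(f"unknown detection-bound method {method!r}")
    return k / total_fields * geometry.scale_factor


class CompositionModel:
    """Estimator of the Table-2-style composition for one or more samples.

    Parameters
    ----------
    data : pandas.DataFrame
        Probe count table (schema in :mod:`aomquant.io`), any number of
        (sample_id, probe_id) pairs.
    geometry : MicroscopeGeometry or mapping sample_id -> MicroscopeGeometry
        Needed only for detection bounds (fractions are geometry-free).
    detection_method : {'one_count', 'poisson95'}
    """

    def __init__(self, data: pd.DataFrame,
                 geometry: MicroscopeGeometry | Mapping[str, MicroscopeGeometry] | None = None,
                 single_cell_diameter: float = SINGLE_CELL_DIAMETER_UM,
                 detection_method: str = "one_count"):
        self.data = validate_probe_counts(data)
        self.geometry = geometry
        self.single_cell_diameter = float(single_cell_diameter)
        self.detection_method = detection_method

    def _geometry_for(self, sample_id: str) -> MicroscopeGeometry | None:
        if self.geometry is None or isinstance(self.geometry, MicroscopeGeometry):
            return self.geometry
        return self.geometry.get(sample_id)

    def fit(self) -> "CompositionResults":
        rows = []
        for (sample, probe), sub in self.data.groupby(["sample_id", "probe_id"], sort=True):
            n_fields = sub.groupby("replicate_id")["field_id"].nunique().sum()
            for category in CATEGORIES:
                if sub.probe_count.sum() == 0:
                    geom = self._geometry_for(sample)
                    bound = (detection_bound(int(n_fields), geom, 0, self.detection_method)
                             if geom is not None else np.nan)
                    est = FractionEstimate(np.nan, np.nan, 0, below_detection=True,
                                           detection_bound=bound)
                else:
                    try:
                        est = probe_fraction(sub, category, self.single_cell_diameter)
                    except UndefinedFractionError:
                        # no DAPI objects of this category anywhere: fraction undefined
                        est = FractionEstimate(np.nan, np.nan, 0)
                rows.append(dict(sample_id=sample, probe_id=probe, category=category,
                                 fraction_mean=est.mean, fraction_se=est.se,
                                 n_blocks=est.n_blocks,
                                 below_detection=est.below_detection,
                                 detection_bound=est.detection_bound))
        table = pd.DataFrame(rows).set_index(["sample_id", "probe_id", "category"])
        return CompositionResults(table=table)


@dataclass
class CompositionResults:
    """Per-(sample, probe, category) fraction estimates with detection flags."""

    table: pd.DataFrame

    def fraction(self, sample_id: str, probe_id: str, category: str) -> FractionEstimate:
        r = self.table.loc[(sample_id, probe_id, category)]
        return FractionEstimate(mean=float(r.fraction_mean), se=float(r.fraction_se),
                                n_blocks=int(r.n_blocks),
                                below_detection=bool(r.below_detection),
                                detection_bound=None if pd.isna(r.detection_bound)
                                else float(r.detection_bound))

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index()

    def summary(self) -> str:
        """Render the composition in the familiar probe x category layout."""
        lines = ["Community composition (CARD-FISH)",
                 f"{'sample':8s}{'probe':12s}{'% of cells':>24s}{'% of aggregates':>24s}{'% of biovolume':>24s}"]
        wide = {}
        for (sample, probe, cat), r in self.table.iterrows():
            wide.setdefault((sample, probe), {})[cat] = r

        def cell(r) -> str:
            if r.below_detection:
                return BELOW_DETECTION
            se = "" if pd.isna(r.fraction_se) else f" ± {100 * r.fraction_se:.1f}"
            return f"{100 * r.fraction_mean:.1f}{se}"

        for (sample, probe), cats in wide.items():
            lines.append(f"{sample:8s}{probe:12s}"
                         f"{cell(cats['cells']):>24s}{cell(cats['aggregates']):>24s}"
                         f"{cell(cats['biovolume']):>24s}")
        return "\n".join(lines)
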