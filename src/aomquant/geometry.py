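"""Microscope and filtration geometry.

Counts made in microscope fields of view are converted to concentrations in
the original (undiluted) slurry through a single scale factor

    scale = (filter_effective_area / field_area) / filtered_volume
            * dilution_factor            [1 / ml]

i.e. objects/field * scale = objects/ml slurry.  The geometry is not part of
the published record for this kind of experiment, so it lives in a small
config object with documented defaults; every ratio-type quantity downstream
(probe fractions, relative increases, doubling times) is invariant to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import InvalidGeometryError

__all__ = ["MicroscopeGeometry"]


@dataclass(frozen=True)
class MicroscopeGeometry:
    """Filtration and counting geometry for one sample.

    Parameters
    ----------
    dilution_factor : float
        Fold-dilution of the slurry before filtration (>= 1); e.g. 2000 for
        the pre-incubation sample, 5600 for the post-incubation sample.
    filtered_volume_ml : float
        Volume of diluted sample drawn through the filter, ml.
    filter_effective_area_um2 : float
        Area of the filter over which objects are deposited, um^2.
    field_area_um2 : float
        Area of one microscope field of view, um^2.
    """

    dilution_factor: float = 1.0
    filtered_volume_ml: float = 1.0
    filter_effective_area_um2: float = 1.0
    field_area_um2: float = 1.0

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise InvalidGeometryError("dilution_factor must be >= 1")
        if self.filtered_volume_ml <= 0:
            raise InvalidGeometryError("filtered_volume_ml must be > 0")
        if self.filter_effective_area_um2 <= 0 or self.field_area_um2 <= 0:
            raise InvalidGeometryError("filter and field areas must be > 0")
        if self.field_area_um2 > self.filter_effective_area_um2:
            raise InvalidGeometryError("field_area_um2 cannot exceed filter_effective_area_um2")
        if not math.isfinite(self.scale_factor) or self.scale_factor <= 0:
            raise InvalidGeometryError("scale factor must be finite and > 0")

    @property
    def scale_factor(self) -> float:
        """Objects/ml slurry per mean object/field."""
        return (
            (self.filter_effective_area_um2 / self.field_area_um2)
            / self.filtered_volume_ml
            * self.dilution_factor
        )

    # -- constructors -----------------------------------------------------

    @classmethod
    def unit(cls) -> "MicroscopeGeometry":
        """Identity geometry: 1 count/field == 1 object/ml."""
        return cls(1.0, 1.0, 1.0, 1.0)

    @classmethod
    def default(cls, dilution_factor: float = 1.0, filtered_volume_ml: float = 10.0) -> "MicroscopeGeometry":
        """Default bench geometry.

        A 2.5 cm polycarbonate filter with an effective (exposed) diameter of
        2.0 cm gives an effective area of pi*1e8 um^2; a 200 um field of view
        at 1000x magnification gives pi*1e4 um^2, i.e. an area ratio of
        exactly 1e4.  With 10 ml filtered, a single object found in one
        staining's 50 fields corresponds to 4e4 objects/ml at 2000x dilution.
        """
        return cls(
            dilution_factor=dilution_factor,
            filtered_volume_ml=filtered_volume_ml,
            filter_effective_area_um2=math.pi * 1.0e8,
            field_area_um2=math.pi * 1.0e4,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "MicroscopeGeometry":
        known = {
            "dilution_factor",
            "filtered_volume_ml",
            "filter_effective_area_um2",
            "field_area_um2",
        }
        extra = set(d) - known - {"single_cell_diameter_um", "samples"}
        if extra:
            raise InvalidGeometryError(f"unknown geometry keys: {sorted(extra)}")
        return cls(**{k: float(v) for k, v in d.items() if k in known})

    @classmethod
    def from_config(cls, path: str | Path, sample_id: str | None = None) -> "MicroscopeGeometry":
        """Read a YAML geometry config; per-sample overrides under ``samples:``."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        base = {k: v for k, v in cfg.items() if k != "samples"}
        if sample_id is not None and "samples" in cfg and sample_id in cfg["samples"]:
            base.update(cfg["samples"][sample_id])
        return cls.from_dict(base)
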