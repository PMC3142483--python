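"""Growth and enrichment: group biovolumes, relative increases, doubling time,
dry-weight biomass, with first-order (delta-method) or bootstrap uncertainty.

Given total biovolumes at two timepoints and a group's fraction of each, the
group biovolume is their product.  "Increased X times" follows the relative
-increase convention (V2 - V1) / V1 — the only convention under which the
canonical 2.5x (total), 12.5x (ANME-2) and 8.4x (SRB) factors are mutually
consistent with the underlying biovolumes — while the plain ratio V2/V1 is
exposed alongside as ``fold_change``.  Exponential ("logarithmic growth
curve") kinetics convert the two-timepoint ratio into a doubling time

    t_d = delta_t * ln 2 / ln(V2 / V1),

expressed in months of 30.44 days.  Biovolume converts to dry mass with the
standard 0.2 g cell dry weight per ml of biovolume.

Two reporting modes exist: ``full`` keeps full precision; ``reproduce``
rounds group biovolumes to 2 significant figures before deriving ratios,
matching the printed-intermediate arithmetic of typical reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (InvalidInputError, NoGrowthError, UndefinedBaselineError)
from .util import DAYS_PER_MONTH, UM3_PER_ML, round_sig

__all__ = [
    "group_biovolume",
    "increase_factor",
    "fold_change",
    "doubling_time",
    "dry_weight",
    "propagate_uncertainty",
    "GrowthModel",
    "GrowthResults",
]

DRY_WEIGHT_G_PER_ML_BIOVOLUME = 0.2
ML_PER_L = 1.0e3


def group_biovolume(total_biovolume: float, fraction: float) -> float:
    """Biovolume of one group: total biovolume (um^3/ml) times its fraction."""
    if not 0.0 <= fraction <= 1.0:
        raise InvalidInputError("fraction must lie in [0, 1]")
    if total_biovolume < 0:
        raise InvalidInputError("total biovolume must be >= 0")
    return total_biovolume * fraction


def fold_change(v1: float, v2: float) -> float:
    """Plain ratio V2/V1."""
    if v1 <= 0:
        raise UndefinedBaselineError("fold change undefined for V1 <= 0")
    if v2 < 0:
        raise InvalidInputError("V2 must be >= 0")
    return v2 / v1


def increase_factor(v1: float, v2: float) -> float:
    """Relative increase (V2 - V1) / V1; equals fold_change - 1."""
    return fold_change(v1, v2) - 1.0


def doubling_time(v1: float, v2: float, delta_t_days: float,
                  days_per_month: float = DAYS_PER_MONTH) -> float:
    """Exponential-growth doubling time in months from two biovolumes.

    t_d = delta_t * ln 2 / ln(V2/V1), delta_t in days, result in months.
    """
    if delta_t_days <= 0:
        raise InvalidInputError("delta_t_days must be > 0")
    if v1 <= 0 or v2 <= 0:
        raise InvalidInputError("biovolumes must be > 0")
    if v2 <= v1:
        raise NoGrowthError("doubling time requires V2 > V1")
    return delta_t_days * np.log(2.0) / np.log(v2 / v1) / days_per_month


def dry_weight(biovolume_conc: float,
               factor_g_per_ml: float = DRY_WEIGHT_G_PER_ML_BIOVOLUME) -> float:
    """Convert biovolume concentration (um^3/ml slurry) to g dry weight / l slurry."""
    if biovolume_conc < 0 or factor_g_per_ml < 0:
        raise InvalidInputError("inputs must be >= 0")
    return biovolume_conc / UM3_PER_ML * factor_g_per_ml * ML_PER_L


def propagate_uncertainty(v1: float, v1_se: float, v2: float, v2_se: float,
                          delta_t_days: float | None = None,
                          days_per_month: float = DAYS_PER_MONTH,
                          method: str = "delta",
                          n_boot: int = 10_000,
                          seed: int | None = None) -> dict[str, float]:
    """Standard errors of the derived growth quantities.

    The two timepoints are assumed independent.  ``delta`` (default) uses
    first-order propagation: for the ratio R = V2/V1,

        SE_R = R * sqrt(cv1^2 + cv2^2),

    which is also the SE of the relative increase R - 1, and for the
    doubling time t_d = dt ln2 / ln R,

        SE_t = dt * ln 2 / (ln R)^2 * sqrt(cv1^2 + cv2^2).

    ``bootstrap`` resamples V1, V2 from independent normals (seeded,
    reproducible); non-positive draws are rejected, so it is meant for the
    small-CV regime where they are rare.
    """
    if v1_se < 0 or v2_se < 0:
        raise InvalidInputError("standard errors must be >= 0")
    if v1 <= 0 or v2 <= 0:
        raise InvalidInputError("biovolumes must be > 0")
    cv2sum = (v1_se / v1) ** 2 + (v2_se / v2) ** 2
    r = v2 / v1
    out: dict[str, float] = {}
    if method == "delta":
        out["fold_change_se"] = r * np.sqrt(cv2sum)
        out["increase_factor_se"] = out["fold_change_se"]
        if delta_t_days is not None and r > 1:
            out["doubling_time_se"] = (delta_t_days * np.log(2.0) / np.log(r) ** 2
                                       * np.sqrt(cv2sum) / days_per_month)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        b1 = rng.normal(v1, v1_se, size=n_boot)
        b2 = rng.normal(v2, v2_se, size=n_boot)
        keep = (b1 > 0) & (b2 > 0)
        b1, b2 = b1[keep], b2[keep]
        if b1.size < 2:
            raise InvalidInputError("bootstrap degenerate: too few positive draws")
        ratios = b2 / b1
        out["fold_change_se"] = float(ratios.std(ddof=1))
        out["increase_factor_se"] = out["fold_change_se"]
        if delta_t_days is not None:
            grow = ratios > 1
            if grow.sum() >= 2:
                td = delta_t_days * np.log(2.0) / np.log(ratios[grow]) / days_per_month
                out["doubling_time_se"] = float(td.std(ddof=1))
    else:
        raise InvalidInputError(f"unknown propagation method {method!r}")
    out["dry_weight_1_se"] = dry_weight(v1_se)
    out["dry_weight_2_se"] = dry_weight(v2_se)
    return {k: float(v) for k, v in out.items()}


class GrowthModel:
    """Two-timepoint exponential-growth model for one group's biovolume.

    Parameters
    ----------
    v1, v2 : float
        Group biovolumes (um^3/ml slurry) at the start and end of incubation.
    delta_t_days : float
        Elapsed time between the two samples, days.
    v1_se, v2_se : float
        Replicate-based standard errors (0 if unknown).
    group_id : str
    mode : {'full', 'reproduce'}
        ``reproduce`` rounds v1, v2 to 2 significant figures before deriving
        ratios, mimicking arithmetic on printed intermediate values.
    dry_weight_factor : float, g dry weight per ml biovolume.
    """

    def __init__(self, v1: float, v2: float, delta_t_days: float,
                 v1_se: float = 0.0, v2_se: float = 0.0, group_id: str = "group",
                 mode: str = "full",
                 dry_weight_factor: float = DRY_WEIGHT_G_PER_ML_BIOVOLUME,
                 days_per_month: float = DAYS_PER_MONTH,
                 propagation: str = "delta", n_boot: int = 10_000,
                 seed: int | None = None):
        if mode not in ("full", "reproduce"):
            raise InvalidInputError("mode must be 'full' or 'reproduce'")
        self.v1_raw, self.v2_raw = float(v1), float(v2)
        self.v1_se, self.v2_se = float(v1_se), float(v2_se)
        self.delta_t_days = float(delta_t_days)
        self.group_id = group_id
        self.mode = mode
        self.dry_weight_factor = dry_weight_factor
        self.days_per_month = days_per_month
        self.propagation = propagation
        self.n_boot = n_boot
        self.seed = seed

    @classmethod
    def from_estimates(cls, total1: tuple[float, float], fraction1: tuple[float, float],
                       total2: tuple[float, float], fraction2: tuple[float, float],
                       delta_t_days: float, **kwargs) -> "GrowthModel":
        """Build from (total biovolume, SE) and (fraction, SE) at each timepoint.

        Group biovolume V = total * fraction with product-rule SE
        V * sqrt(cv_total^2 + cv_fraction^2); a NaN input SE is treated as 0.
        """
        def prod(t, f):
            (tm, ts), (fm, fs) = t, f
            v = group_biovolume(tm, fm)
            ts = 0.0 if ts is None or np.isnan(ts) else ts
            fs = 0.0 if fs is None or np.isnan(fs) else fs
            if v == 0:
                return 0.0, 0.0
            se = v * np.sqrt((ts / tm) ** 2 + (fs / fm) ** 2)
            return v, float(se)

        v1, s1 = prod(total1, fraction1)
        v2, s2 = prod(total2, fraction2)
        return cls(v1, v2, delta_t_days, v1_se=s1, v2_se=s2, **kwargs)

    def fit(self) -> "GrowthResults":
        v1, v2 = self.v1_raw, self.v2_raw
        if self.mode == "reproduce":
            v1, v2 = round_sig(v1, 2), round_sig(v2, 2)
        inc = increase_factor(v1, v2)
        fc = inc + 1.0  # keeps the results invariant fold = increase + 1 exact
        td = (doubling_time(v1, v2, self.delta_t_days, self.days_per_month)
              if v2 > v1 else float("nan"))
        ses = propagate_uncertainty(v1, self.v1_se, v2, self.v2_se,
                                    self.delta_t_days, self.days_per_month,
                                    method=self.propagation, n_boot=self.n_boot,
                                    seed=self.seed)
        return GrowthResults(
            group_id=self.group_id, mode=self.mode,
            v1=v1, v1_se=self.v1_se, v2=v2, v2_se=self.v2_se,
            delta_t_days=self.delta_t_days,
            increase_factor=inc, increase_factor_se=ses.get("increase_factor_se", np.nan),
            fold_change=fc, fold_change_se=ses.get("fold_change_se", np.nan),
            doubling_time_months=td,
            doubling_time_months_se=ses.get("doubling_time_se", np.nan),
            dry_weight_1=dry_weight(v1, self.dry_weight_factor),
            dry_weight_1_se=dry_weight(self.v1_se, self.dry_weight_factor),
            dry_weight_2=dry_weight(v2, self.dry_weight_factor),
            dry_weight_2_se=dry_weight(self.v2_se, self.dry_weight_factor),
        )


@dataclass
class GrowthResults:
    """Derived growth quantities for one group, with propagated SEs.

    ``increase_factor`` is (V2-V1)/V1; ``fold_change`` is V2/V1 and always
    equals ``increase_factor + 1``; dry weights are g/l slurry.
    """

    group_id: str
    mode: str
    v1: float
    v1_se: float
    v2: float
    v2_se: float
    delta_t_days: float
    increase_factor: float
    increase_factor_se: float
    fold_change: float
    fold_change_se: float
    doubling_time_months: float
    doubling_time_months_se: float
    dry_weight_1: float
    dry_weight_1_se: float
    dry_weight_2: float
    dry_weight_2_se: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([self.__dict__])

    def summary(self) -> str:
        from .io import format_mean_se

        sig = round_sig
        if self.mode == "reproduce":
            inc, td = round(self.increase_factor, 1), round(self.doubling_time_months, 1)
            dw1, dw2 = round(self.dry_weight_1, 1), round(self.dry_weight_2, 1)
        else:
            inc, td = self.increase_factor, self.doubling_time_months
            dw1, dw2 = self.dry_weight_1, self.dry_weight_2
        lines = [
            f"Growth of {self.group_id} over {self.delta_t_days:g} days ({self.mode} mode)",
            f"  biovolume:      {format_mean_se(sig(self.v1, 2), self.v1_se)} -> "
            f"{format_mean_se(sig(self.v2, 2), self.v2_se)} um^3/ml slurry",
            f"  increase:       {inc:g} times  (fold change {self.fold_change:.3g})",
            f"  doubling time:  {td:g} months",
            f"  dry weight:     {dw1:g} -> {dw2:g} g/l slurry",
        ]
        return "\n".join(lines)
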