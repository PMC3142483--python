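"""16S rRNA clone-library composition and concordance with CARD-FISH.

A clone library's group percentage is simply 100 * clones-in-group /
clones-sequenced.  The concordance check flags groups seen by only one of
the two methods and, for a group FISH estimates at frequency f that is
absent among n sequenced clones, reports the probability of that absence
under multinomial sampling, (1 - f)^n — small values mean the absence is
evidence against the FISH estimate rather than sampling luck.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import InvalidInputError, MappingError

__all__ = ["CloneLibrary", "composition", "absence_probability", "fish_concordance"]


@dataclass
class CloneLibrary:
    """Clone counts per phylogenetic group for one domain's library."""

    domain: str
    clones_obtained: int
    clones_sequenced: int
    group_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.clones_sequenced <= 0:
            raise InvalidInputError("clones_sequenced must be > 0")
        if self.clones_sequenced > self.clones_obtained:
            raise InvalidInputError("clones_sequenced cannot exceed clones_obtained")
        if any(v < 0 for v in self.group_counts.values()):
            raise InvalidInputError("group counts must be >= 0")
        total = sum(self.group_counts.values())
        if total != self.clones_sequenced:
            raise InvalidInputError(
                f"group counts sum to {total}, not clones_sequenced={self.clones_sequenced}")


def composition(lib: CloneLibrary) -> dict[str, float]:
    """Percentage of each group: 100 * count / clones_sequenced."""
    if not lib.group_counts:
        raise InvalidInputError("empty clone library")
    return {g: 100.0 * n / lib.clones_sequenced for g, n in lib.group_counts.items()}


def absence_probability(fish_fraction: float, n_clones: int) -> float:
    """P(0 clones of a group at true frequency f among n clones) = (1-f)^n."""
    if not 0.0 <= fish_fraction <= 1.0:
        raise InvalidInputError("fraction must lie in [0, 1]")
    if n_clones < 0:
        raise InvalidInputError("n_clones must be >= 0")
    return (1.0 - fish_fraction) ** n_clones


def fish_concordance(lib: CloneLibrary,
                     fish_fractions: Mapping[str, float | None],
                     label_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Cross-check clone-library composition against FISH group fractions.

    Parameters
    ----------
    lib : CloneLibrary
    fish_fractions : mapping group -> fraction in [0,1], or None for a probe
        below its detection limit.
    label_map : mapping FISH label -> clone-library label (e.g. the ANME-2
        probe to the 'ANME-2a' clade); identity by default.

    Returns a frame with one row per group, its source(s), the library
    percentage, the FISH percentage, a status flag (``concordant``,
    ``library_only``, ``fish_only``, ``both_absent``) and, for groups FISH
    detects but the library misses, the multinomial absence probability.
    """
    label_map = dict(label_map or {})
    lib_pct = composition(lib)
    mapped = {label_map.get(g, g): f for g, f in fish_fractions.items()}
    groups = sorted(set(lib_pct) | set(mapped))
    if label_map and not (set(lib_pct) & set(mapped)):
        raise MappingError("no shared group labels after applying label_map")
    rows = []
    for g in groups:
        in_lib = lib_pct.get(g, 0.0) > 0
        f = mapped.get(g)
        fish_detected = f is not None and f > 0
        if in_lib and fish_detected:
            status = "concordant"
        elif in_lib:
            status = "library_only"
        elif fish_detected:
            status = "fish_only"
        else:
            status = "both_absent"
        p_absent = (absence_probability(f, lib.clones_sequenced)
                    if fish_detected and not in_lib else float("nan"))
        rows.append(dict(group=g, library_pct=lib_pct.get(g, 0.0),
                         fish_pct=(100.0 * f if f is not None else float("nan")),
                         status=status, absence_probability=p_absent))
    return pd.DataFrame(rows)
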