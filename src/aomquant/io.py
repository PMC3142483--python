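"""Schema-validated readers/writers and report formatting.

Canonical interchange is tab-separated text with a header line (UTF-8, '.'
decimal separator); comma-separated files are accepted on read.  Writers are
atomic: output appears under its final name only after the full table has
been written, so invalid input never leaves a partial file behind.

Count table schema (one row per field, object type and size class)::

    sample_id  replicate_id  field_id  object_type  diameter_class_um  count

``object_type`` is ``single_cell`` or ``aggregate``; ``diameter_class_um`` is
empty for single cells and the integer class label (um) for aggregates.
Probe tables add ``probe_id`` and carry paired ``probe_count``/``dapi_count``
columns counted in the same fields.
"""

from __future__ import annotations

import math
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataIntegrityError, SchemaError

__all__ = [
    "COUNT_COLUMNS",
    "PROBE_COLUMNS",
    "read_counts_table",
    "write_counts_table",
    "read_probe_table",
    "write_probe_table",
    "read_clone_tables",
    "write_clone_tables",
    "format_mean_se",
    "write_tsv",
]

COUNT_COLUMNS = [
    "sample_id",
    "replicate_id",
    "field_id",
    "object_type",
    "diameter_class_um",
    "count",
]

PROBE_COLUMNS = [
    "sample_id",
    "probe_id",
    "replicate_id",
    "field_id",
    "object_type",
    "diameter_class_um",
    "probe_count",
    "dapi_count",
]

OBJECT_TYPES = ("single_cell", "aggregate")


# ---------------------------------------------------------------------------
# atomic writing

def _atomic_to_csv(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, **kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Atomically write any tidy frame as TSV."""
    _atomic_to_csv(df, path, sep="\t", index=index)


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype={"sample_id": str, "replicate_id": str,
                                             "field_id": str, "probe_id": str})


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def _check_counts_column(df: pd.DataFrame, col: str) -> None:
    vals = df[col]
    bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
        raise SchemaError(f"column '{col}': invalid (negative/missing/non-integer) "
                          f"value at file row {row}")


def _check_classes(df: pd.DataFrame) -> None:
    bad_type = ~df["object_type"].isin(OBJECT_TYPES)
    if bad_type.any():
        row = int(bad_type.idxmax()) + 2
        raise SchemaError(f"unknown object_type at file row {row}")
    agg = df["object_type"] == "aggregate"
    d = df["diameter_class_um"]
    bad = agg & (d.isna() | (d <= 0))
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise SchemaError(f"aggregate row without positive diameter_class_um at file row {row}")


def _check_duplicates(df: pd.DataFrame, keys: list[str], what: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise SchemaError(f"duplicate {what} key at file row {row}")


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a DAPI count table; returns the (typed) frame."""
    _require_columns(df, COUNT_COLUMNS, "counts table")
    _check_counts_column(df, "count")
    _check_classes(df)
    _check_duplicates(
        df, ["sample_id", "replicate_id", "field_id", "object_type", "diameter_class_um"],
        "(sample, replicate, field, type, class)")
    out = df.copy()
    out["count"] = out["count"].astype(np.int64)
    return out


def validate_probe_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe/DAPI paired count table."""
    _require_columns(df, PROBE_COLUMNS, "probe counts table")
    _check_counts_column(df, "probe_count")
    _check_counts_column(df, "dapi_count")
    _check_classes(df)
    _check_duplicates(
        df,
        ["sample_id", "probe_id", "replicate_id", "field_id", "object_type", "diameter_class_um"],
        "(sample, probe, replicate, field, type, class)")
    over = df["probe_count"] > df["dapi_count"]
    if over.any():
        row = int(over.idxmax()) + 2
        raise DataIntegrityError(f"probe_count exceeds dapi_count at file row {row}")
    out = df.copy()
    out["probe_count"] = out["probe_count"].astype(np.int64)
    out["dapi_count"] = out["dapi_count"].astype(np.int64)
    return out


def read_counts_table(path: str | Path) -> pd.DataFrame:
    return validate_counts(_read_table(path))


def write_counts_table(df: pd.DataFrame, path: str | Path) -> None:
    write_tsv(validate_counts(df)[COUNT_COLUMNS], path)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    return validate_probe_counts(_read_table(path))


def write_probe_table(df: pd.DataFrame, path: str | Path) -> None:
    write_tsv(validate_probe_counts(df)[PROBE_COLUMNS], path)


# ---------------------------------------------------------------------------
# clone tables

def read_clone_tables(path: str | Path):
    """Read clone-library tables.

    Format: '#' metadata lines of the form
    ``# <domain> clones_obtained=56 clones_sequenced=50`` followed by a TSV
    with columns ``domain, group, count``.  Returns a list of
    :class:`~aomquant.clones.CloneLibrary`.
    """
    from .clones import CloneLibrary

    meta: dict[str, dict[str, int]] = {}
    rows = []
    with open(path) as fh:
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if not parts:
                    continue
                dom = parts[0]
                kv = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
                meta[dom] = {k: int(v) for k, v in kv.items()}
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                _require_columns(pd.DataFrame(columns=header), ["domain", "group", "count"],
                                 "clone table")
                continue
            rows.append(dict(zip(header, fields)))
    if not rows:
        raise SchemaError("clone table has no data rows")
    df = pd.DataFrame(rows)
    df["count"] = df["count"].astype(int)
    libs = []
    for dom, sub in df.groupby("domain", sort=False):
        counts = dict(zip(sub["group"], sub["count"]))
        m = meta.get(dom, {})
        sequenced = m.get("clones_sequenced", int(sub["count"].sum()))
        obtained = m.get("clones_obtained", sequenced)
        libs.append(CloneLibrary(domain=dom, clones_obtained=obtained,
                                 clones_sequenced=sequenced, group_counts=counts))
    return libs


def write_clone_tables(libs, path: str | Path) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            for lib in libs:
                fh.write(f"# {lib.domain} clones_obtained={lib.clones_obtained} "
                         f"clones_sequenced={lib.clones_sequenced}\n")
            fh.write("domain\tgroup\tcount\n")
            for lib in libs:
                for group, n in lib.group_counts.items():
                    fh.write(f"{lib.domain}\t{group}\t{n}\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# report formatting

BELOW_DETECTION = "Below detection limit"


def format_mean_se(mean: float, se: float | None = None) -> str:
    """Render ``mean ± se`` in the report's scientific style.

    >>> format_mean_se(1.28e9, 6e7)
    '(1.28 ± 0.06)*10^9'

    The mantissa is printed with two decimals; the SE shares the mean's
    exponent.  ``se=None`` or NaN renders the mean alone.
    """
    if mean == 0:
        return "0"
    exp = int(math.floor(math.log10(abs(mean))))
    mant = mean / 10**exp
    if se is None or (isinstance(se, float) and math.isnan(se)):
        return f"{mant:.2f}*10^{exp}"
    return f"({mant:.2f} ± {se / 10**exp:.2f})*10^{exp}"


def write_manifest(path: str | Path, params: dict) -> None:
    """Echo all scientific parameters of a run into a YAML manifest.

    Deliberately timestamp-free so that reruns are byte-identical.
    """
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            yaml.safe_dump(params, fh, sort_keys=True)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
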