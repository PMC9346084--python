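"""Readers and writers for the package's tabular dialects.

Two plain-text formats are used throughout:

* a survival CSV — one row per rearing tube with its experimental factor
  levels and the binomial outcome (``n_alive`` of ``n_total``);
* a base-fraction TSV — long format, one row per (sample, position, base)
  with the fraction of reads supporting that base and the total coverage,
  accompanied by an optional JSON sidecar describing each sample's role
  (individual vs year-labelled pool), the reference length and excluded
  regions.

All files are UTF-8 with "." as the decimal separator and no thousands
separators.  Readers validate strictly and raise named errors; writers
emit a canonical form (fixed column order, rows sorted, fixed float formatting)
so that ``write(read(x))`` is byte-stable for canonical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, TableParseError
from .mitotypes import BASES, BaseFractionTable, SampleInfo

# ---------------------------------------------------------------------------
# Survival tables
# ---------------------------------------------------------------------------

#: Allowed levels per experimental factor.  "NA" marks factors that do not
#: apply to a given experiment (e.g. clutch outside the parental design).
FACTOR_LEVELS: dict[str, set[str]] = {
    "experiment": {"additive", "parental", "juvenile", "microbiome"},
    "regime": {"T_SFB", "T_VCH"},
    "population": {"SFB84", "VCH97", "VCH08"},
    "cross_status": {"own", "crossed"},
    "clutch": {"1", "2", "NA"},
    "parental_treatment": {"control", "mother", "father", "NA"},
    "phase1_regime": {"T_SFB", "T_VCH", "NA"},
    "microbiome": {"SFB", "VCH", "LAB", "NA"},
}

SURVIVAL_COLUMNS = [
    *FACTOR_LEVELS.keys(), "family_id", "tube_id", "n_total", "n_alive",
]


def validate_survival_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a survival table in memory; returns a normalized copy."""
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survival table missing columns: {missing}")
    df = df[SURVIVAL_COLUMNS].copy()
    for col in FACTOR_LEVELS:
        df[col] = df[col].astype(str)
        bad = set(df[col]) - FACTOR_LEVELS[col]
        if bad:
            raise SchemaError(f"unknown {col} level(s): {sorted(bad)}")
    df["family_id"] = df["family_id"].astype(str)
    df["tube_id"] = df["tube_id"].astype(str)
    for col in ("n_total", "n_alive"):
        vals = pd.to_numeric(df[col], errors="coerce")
        nonint = vals.isna() | (vals != np.floor(vals))
        if nonint.any():
            row = int(np.argmax(nonint.to_numpy()))
            raise TableParseError(f"non-integer {col} at row {row}")
        df[col] = vals.astype(int)
    if (df["n_total"] <= 0).any():
        row = int(np.argmax((df["n_total"] <= 0).to_numpy()))
        raise SchemaError(f"n_total must be positive (row {row})")
    bad = (df["n_alive"] < 0) | (df["n_alive"] > df["n_total"])
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise SchemaError(f"n_alive outside [0, n_total] at row {row}")
    dup = df.duplicated(subset=["experiment", "tube_id"])
    if dup.any():
        row = int(np.argmax(dup.to_numpy()))
        raise SchemaError(
            f"duplicate (experiment, tube_id) at row {row}: "
            f"{df.loc[df.index[row], 'tube_id']!r}"
        )
    return df.reset_index(drop=True)


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tube-level survival CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty (no header)") from exc
    return validate_survival_frame(df)


def write_survival_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a survival table in canonical form (sorted by experiment and
    tube id, fixed column order)."""
    df = validate_survival_frame(df)
    df = df.sort_values(["experiment", "tube_id"], kind="stable")
    df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Base-fraction tables
# ---------------------------------------------------------------------------

BASE_FRACTION_COLUMNS = ["sample", "position", "base", "fraction", "coverage"]


def read_base_fraction_table(
    path: str | Path, meta_path: str | Path | None = None
) -> BaseFractionTable:
    """Read a long-format base-fraction TSV (plus optional JSON sidecar).

    The sidecar (default ``<path>.meta.json``) carries the reference
    length, excluded regions and per-sample roles; without it, every
    sample is treated as an individual and no region is excluded.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty (no header)") from exc
    missing = [c for c in BASE_FRACTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"base-fraction table missing columns: {missing}")
    if len(df):
        bad = ~df["base"].isin(BASES)
        if bad.any():
            raise SchemaError(f"invalid base at row {int(np.argmax(bad.to_numpy()))}")
        for col, kind in (("position", int), ("coverage", float), ("fraction", float)):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = int(np.argmax(vals.isna().to_numpy()))
                raise TableParseError(f"unparseable {col} at row {row}")
            df[col] = vals.astype(kind)
        if ((df["fraction"] < 0) | (df["fraction"] > 1)).any():
            raise TableParseError("fraction outside [0, 1]")
        dup = df.duplicated(subset=["sample", "position", "base"])
        if dup.any():
            row = int(np.argmax(dup.to_numpy()))
            raise SchemaError(f"duplicate (sample, position, base) at row {row}")
        wide = df.pivot_table(
            index=["sample", "position"], columns="base", values="fraction",
            fill_value=0.0, aggfunc="first",
        )
        for b in BASES:
            if b not in wide.columns:
                wide[b] = 0.0
        wide = wide[list(BASES)]
        cov = df.groupby(["sample", "position"])["coverage"].first()
        if df.groupby(["sample", "position"])["coverage"].nunique().gt(1).any():
            raise SchemaError("inconsistent coverage within a (sample, position)")
        wide["coverage"] = cov
    else:
        wide = pd.DataFrame(
            columns=[*BASES, "coverage"],
            index=pd.MultiIndex.from_arrays([[], []], names=["sample", "position"]),
        )

    ref_len, regions, samples = None, (), {}
    mpath = Path(meta_path) if meta_path else path.with_name(path.name + ".meta.json")
    if mpath.exists():
        meta = json.loads(mpath.read_text())
        unknown = set(meta) - {"reference_length", "excluded_regions", "samples"}
        if unknown:
            raise SchemaError(f"unknown sidecar keys: {sorted(unknown)}")
        ref_len = meta.get("reference_length")
        regions = tuple(tuple(r) for r in meta.get("excluded_regions", []))
        samples = {
            name: SampleInfo(d["kind"], d.get("year"), d.get("replicate", 1))
            for name, d in meta.get("samples", {}).items()
        }
    return BaseFractionTable(wide, ref_len, regions, samples)


def write_base_fraction_table(
    table: BaseFractionTable, path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write the long-format TSV (rows with fraction 0 are omitted) and
    its JSON sidecar.  Fractions use twelve significant digits so that
    read/write round trips preserve values well below 1e-9."""
    path = Path(path)
    rows = []
    for (sample, position), rec in table.frac.sort_index().iterrows():
        for b in BASES:
            if rec[b] > 0:
                rows.append((sample, int(position), b,
                             f"{rec[b]:.12g}", f"{rec['coverage']:.12g}"))
    out = pd.DataFrame(rows, columns=BASE_FRACTION_COLUMNS)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")

    meta = {
        "reference_length": table.reference_length,
        "excluded_regions": [list(r) for r in table.excluded_regions],
        "samples": {
            name: {"kind": si.kind, "year": si.year, "replicate": si.replicate}
            for name, si in sorted(table.samples.items())
        },
    }
    mpath = Path(meta_path) if meta_path else path.with_name(path.name + ".meta.json")
    mpath.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
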