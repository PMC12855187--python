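"""Table readers/writers with explicit dialects and strict validation.

All tabular artifacts are plain TSV (samples as rows, header row).  Cohort
tables carry ``sample_id`` (index), ``group`` and optional ``dapsa``
columns; concentration tables are samples x metabolites; bucket tables
round-trip through :meth:`psametab.spectra.BucketTable.to_tsv` with their
boundary metadata header lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_cohort", "write_cohort",
    "read_concentrations", "write_concentrations",
    "file_checksum", "write_manifest",
]


def _read_tsv(path, sep: str = "\t", decimal: str = ".") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, decimal=decimal, index_col=0, dtype=str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample ids: {dupes}")
    return df


def _to_numeric(df: pd.DataFrame, path, decimal: str = ".") -> pd.DataFrame:
    if decimal != ".":
        df = df.apply(lambda col: col.str.replace(decimal, ".", regex=False))
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(out.isna().to_numpy() & df.notna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {df.iat[r, c]!r} "
            "(declare the dialect if this file uses comma decimals)")
    return out


def read_concentrations(path, sep: str = "\t", decimal: str = ".") -> pd.DataFrame:
    """Read a samples x metabolites table; strict numeric validation."""
    return _to_numeric(_read_tsv(path, sep, decimal), path, decimal)


def write_concentrations(conc: pd.DataFrame, path) -> None:
    conc.to_csv(path, sep="\t", index_label="sample_id")


def read_cohort(path, sep: str = "\t", decimal: str = ".") -> pd.DataFrame:
    """Read a cohort table (group labels, optional dapsa scores)."""
    df = _read_tsv(path, sep, decimal)
    if "group" not in df.columns:
        raise ValueError(f"{path}: cohort table requires a 'group' column")
    out = df.copy()
    if "dapsa" in df.columns:
        out["dapsa"] = pd.to_numeric(df["dapsa"], errors="coerce")
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index_label="sample_id")


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir, entries: dict, extra: dict | None = None) -> Path:
    """Write a manifest listing every artifact with its checksum."""
    outdir = Path(outdir)
    manifest = {
        "files": {name: {"path": str(Path(p).name),
                         "sha256": file_checksum(p)}
                  for name, p in entries.items()},
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
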