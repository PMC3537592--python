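"""Delimited-table readers/writers and run manifests.

Plain text only: TSV or CSV, delimiter inferred from the extension (override
available), decimal points (no locale commas).  Every subcommand of the CLI
writes a JSON manifest next to its results recording the configuration, seed,
input checksums and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["read_table", "load_cohort", "write_table", "write_manifest", "sha256sum"]

_KINDS = ("metabolites", "trait", "covariates", "pairs")


def _delimiter(path: Path, override: Optional[str]) -> str:
    if override:
        return override
    if path.suffix.lower() == ".csv":
        return ","
    return "\t"


def read_table(
    path: Union[str, Path],
    kind: str,
    delimiter: Optional[str] = None,
) -> pd.DataFrame:
    """Read and schema-validate one input table.

    kinds
    -----
    metabolites / covariates
        First column sample ID (index), remaining columns numeric.
    trait
        Two columns: sample ID and a numeric trait.
    pairs
        Two string columns naming metabolite pairs; no numeric validation.
    """
    if kind not in _KINDS:
        raise ValidationError(f"unknown table kind {kind!r}; expected one of {_KINDS}")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    sep = _delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no data columns after the sample-ID column")
    df.index = df.index.astype(str)
    df.index.name = "sample_id"

    if kind == "pairs":
        if df.shape[1] != 1:
            raise ValidationError(
                f"{path}: a pairs file needs exactly two columns, "
                f"got {df.shape[1] + 1}"
            )
        return df

    if df.index.has_duplicates:
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(
            f"{path}: duplicate sample ID(s): {', '.join(map(str, dup[:5]))}"
        )
    non_numeric = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = df.index[bad][0]
            non_numeric.append(f"column {col!r} row {row!r}")
        df[col] = coerced
    if non_numeric:
        raise ValidationError(
            f"{path}: non-numeric cell(s) at " + "; ".join(non_numeric[:5])
        )
    if kind == "trait" and df.shape[1] != 1:
        raise ValidationError(
            f"{path}: a trait file needs exactly two columns (sample_id, trait), "
            f"got {df.shape[1] + 1}"
        )
    return df


def read_pairs(path: Union[str, Path], delimiter: Optional[str] = None) -> list:
    df = read_table(path, "pairs", delimiter)
    return [(str(idx), str(row.iloc[0])) for idx, row in df.iterrows()]


def load_cohort(
    metabolites_path: Union[str, Path],
    trait_path: Union[str, Path],
    covariates_path: Optional[Union[str, Path]] = None,
    delimiter: Optional[str] = None,
) -> CohortTable:
    """Read the input tables and intersect them on sample ID."""
    met = read_table(metabolites_path, "metabolites", delimiter)
    trait_df = read_table(trait_path, "trait", delimiter)
    trait = trait_df.iloc[:, 0]
    cov = (
        read_table(covariates_path, "covariates", delimiter)
        if covariates_path
        else None
    )
    return CohortTable.from_aligned(met, trait, cov)


def write_table(df: pd.DataFrame, path: Union[str, Path], index: bool = False):
    path = Path(path)
    sep = _delimiter(path, None)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=index)
    logger.info("wrote %d row(s) to %s", len(df), path)


def sha256sum(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path: Union[str, Path],
    subcommand: str,
    config: dict,
    inputs: Optional[dict] = None,
):
    """JSON provenance record written alongside a result file."""
    from . import __version__

    out_path = Path(out_path)
    manifest = {
        "tool": "pgain",
        "version": __version__,
        "subcommand": subcommand,
        "config": _jsonable(config),
        "inputs": {
            name: {"path": str(p), "sha256": sha256sum(p)}
            for name, p in (inputs or {}).items()
            if p is not None
        },
    }
    manifest_path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("manifest: %s", manifest_path)
    return manifest_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
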