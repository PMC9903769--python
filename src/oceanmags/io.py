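"""Tab-separated table readers and writers for every pipeline schema.

All intermediates are TSV with a mandatory header, decimal point, and no
thousands separators.  Each schema declares its columns, dtypes, and primary
key; reading validates the header, coerces types, rejects duplicated primary
keys, and reports unparseable rows with their line numbers.  A permissive
mode downgrades row errors to warnings and drops the offending rows.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("oceanmags")

ENV_PARAMETERS = ["sst", "salinity", "silicate", "nitrate", "phosphate", "iron", "si_no3"]


class SchemaError(ValueError):
    """Header or column-type mismatch against a declared schema."""


class IntegrityError(ValueError):
    """Duplicate primary keys or dangling references between tables."""


#: schema name -> (column -> dtype, primary-key columns)
SCHEMAS: dict[str, tuple[dict[str, type], tuple[str, ...]]] = {
    "genomes": (
        {
            "genome_id": str,
            "length": np.int64,
            "completion": float,
            "redundancy": float,
            "lineage": str,
            "source": str,
            "is_phytoplankton": bool,
        },
        ("genome_id",),
    ),
    "pairs": (
        {
            "genome_a": str,
            "genome_b": str,
            "ani": float,
            "aligned_fraction_smaller": float,
        },
        ("genome_a", "genome_b"),
    ),
    "metagenomes": (
        {
            "metagenome_id": str,
            "station_id": str,
            "depth_layer": str,
            "size_fraction": str,
            "total_reads": np.int64,
            "subset_labels": str,
        },
        ("metagenome_id",),
    ),
    "recruitment": (
        {
            "genome_id": str,
            "metagenome_id": str,
            "recruited_reads": np.int64,
            "breadth": float,
            "mean_coverage": float,
        },
        ("genome_id", "metagenome_id"),
    ),
    "gene_annotations": (
        {
            "gene_id": str,
            "genome_id": str,
            "og_id": str,
            "og_known": bool,
            "agnostos_cluster": str,
            "retro_flag": bool,
        },
        ("gene_id",),
    ),
    "marker_hits": (
        {
            "genome_id": str,
            "marker_id": str,
            "best_hit_identity": float,
        },
        ("genome_id", "marker_id"),
    ),
    "station_env": (
        {"station_id": str, **{p: float for p in ENV_PARAMETERS}},
        ("station_id",),
    ),
    "env_grid": (
        {
            "lat": float,
            "lon": float,
            "ocean": bool,
            **{p: float for p in ENV_PARAMETERS},
        },
        ("lat", "lon"),
    ),
}

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _coerce_bool(series: pd.Series, column: str, path: Path) -> pd.Series:
    vals = series.astype(str).str.strip().str.lower().map(_BOOL_MAP)
    if vals.isna().any():
        bad = series[vals.isna()].index[0] + 2  # +1 header, +1 zero-based
        raise SchemaError(f"{path}:{bad}: cannot parse boolean in column {column!r}")
    return vals.astype(bool)


def read_table(path: str | Path, schema: str, permissive: bool = False) -> pd.DataFrame:
    """Read a TSV against a named schema.

    Parameters
    ----------
    path : path to the TSV file with a header line.
    schema : one of the keys of :data:`SCHEMAS`.
    permissive : when true, rows failing type coercion are dropped with a
        warning instead of raising; header and primary-key errors always raise.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    columns, pkey = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)} for schema {schema!r}")

    out = pd.DataFrame(index=df.index)
    bad_rows: set[int] = set()
    for col, dtype in columns.items():
        raw = df[col]
        if dtype is str:
            out[col] = raw.astype(str)
        elif dtype is bool:
            out[col] = _coerce_bool(raw, col, path)
        else:
            coerced = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
            failed = coerced.isna() & (raw.str.strip() != "")
            empty = raw.str.strip() == ""
            rows = sorted((failed | empty).pipe(lambda s: s[s].index))
            if rows:
                lines = [r + 2 for r in rows]
                msg = f"{path}: unparseable {col!r} values at lines {lines[:10]}"
                if not permissive:
                    raise SchemaError(msg)
                warnings.warn(msg)
                bad_rows.update(rows)
            if dtype is np.int64:
                frac = coerced.dropna() % 1
                if (frac != 0).any():
                    r = int(frac[frac != 0].index[0]) + 2
                    msg = f"{path}:{r}: non-integer value in integer column {col!r}"
                    if not permissive:
                        raise SchemaError(msg)
                    warnings.warn(msg)
                    bad_rows.update(frac[frac != 0].index)
                out[col] = coerced.fillna(0).astype(np.int64)
            else:
                out[col] = coerced.astype(float)

    if bad_rows:
        out = out.drop(index=sorted(bad_rows)).reset_index(drop=True)

    if schema == "pairs":
        key = out[["genome_a", "genome_b"]].apply(lambda r: tuple(sorted(r)), axis=1)
        dup = key.duplicated()
    else:
        dup = out.duplicated(subset=list(pkey))
    if dup.any():
        first = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise IntegrityError(
            f"{path}:{first}: duplicate primary key {pkey} in schema {schema!r}"
        )
    return out.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    """Write a TSV; when a schema is given the column order is normalized."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if schema is not None:
        columns, _ = SCHEMAS[schema]
        df = df[list(columns)]
    df.to_csv(path, sep="\t", index=False)
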