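"""Reading and writing the flat TSV formats used throughout.

One sumstats dialect (METAL/LDSC-adjacent): tab-separated with a header
SNP CHR POS EA OA EAF BETA SE P N [INFO].  Readers are tolerant to column
reordering and header case; writers emit P in scientific notation with at
least three significant digits.  Matrices are written as labeled square TSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "read_ld_scores",
    "write_ld_scores",
    "read_matrix",
    "write_matrix",
]

_MANDATORY = ["SNP", "EA", "OA", "BETA", "SE"]
_CANONICAL = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "INFO"]


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Load and validate a summary-statistics TSV.

    Headers are case-insensitive and may appear in any order.  P is
    recomputed from BETA/SE (normal law) when absent.  Rows failing
    validation (SE <= 0, P outside (0, 1]) are dropped and logged with their
    line numbers; duplicate (CHR, POS, EA, OA) keys raise an error.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for c in df.columns:
        cu = c.strip().upper()
        if cu in _CANONICAL:
            rename[c] = cu
    df = df.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")

    se = df["SE"].to_numpy(float)
    bad = ~np.isfinite(se) | (se <= 0)
    if "P" in df.columns:
        p = df["P"].to_numpy(float)
        bad |= ~np.isfinite(p) | (p <= 0) | (p > 1)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        lines = (np.flatnonzero(bad) + 2).tolist()
        logger.warning("%s: dropped %d invalid rows (file lines %s)", path, bad.sum(), lines)
        df = df.loc[~bad].reset_index(drop=True)

    if "P" not in df.columns:
        z = df["BETA"].to_numpy(float) / df["SE"].to_numpy(float)
        df["P"] = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)

    key_cols = [c for c in ("CHR", "POS", "EA", "OA") if c in df.columns]
    if {"CHR", "POS"} <= set(key_cols) and df.duplicated(subset=key_cols).any():
        raise ValueError(f"{path}: duplicate (CHR, POS, EA, OA) keys")
    if df.duplicated(subset=["SNP"]).any():
        raise ValueError(f"{path}: duplicate SNP ids")

    order = [c for c in _CANONICAL if c in df.columns]
    extra = [c for c in df.columns if c not in order]
    return df[order + extra]


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write a sumstats TSV; P in scientific notation, floats at full precision."""
    out = df.copy()
    if "P" in out.columns:
        out["P"] = out["P"].map(lambda v: f"{v:.6e}")
    float_cols = out.select_dtypes(include=[np.floating]).columns
    for c in float_cols:
        out[c] = out[c].map(lambda v: f"{v:.17g}")
    out.to_csv(path, sep="\t", index=False)


def write_ld_scores(snp_ids, ld_scores, path: str | Path) -> None:
    pd.DataFrame({"SNP": snp_ids, "L2": np.asarray(ld_scores, float)}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_ld_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().upper() for c in df.columns]
    if not {"SNP", "L2"} <= set(df.columns):
        raise ValueError(f"{path}: LD score file needs SNP and L2 columns")
    return df[["SNP", "L2"]]


def write_matrix(m: np.ndarray, labels, path: str | Path) -> None:
    """Labeled square-matrix TSV (row index + column header)."""
    pd.DataFrame(np.asarray(m, float), index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
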