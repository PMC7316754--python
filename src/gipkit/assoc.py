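"""Covariate-adjusted single-SNP association scans and variant QC.

The scan is ordinary least squares on genotype dosage: phenotype and dosage
are residualized on [intercept | covariates] and the per-SNP slope, its
standard error (df = n - C - 2) and a two-sided P-value are reported.  Binary
traits are analyzed on the 0/1 (or standardized) scale by linear regression,
which keeps the observed-scale heritability algebra intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import CohortData

logger = logging.getLogger(__name__)

__all__ = ["QCThresholds", "qc_filter", "standardize", "gwas_scan"]

#: canonical summary-statistics columns exchanged between all stages
SUMSTATS_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

# switch from the t law to the normal approximation at this residual df
_NORMAL_DF = 100


@dataclass(frozen=True)
class QCThresholds:
    """Strict lower bounds applied to variants (a variant survives iff >)."""

    maf_min: float = 0.0
    info_min: float = 0.0
    call_rate_min: float = 0.0

    def __post_init__(self) -> None:
        for name in ("maf_min", "info_min", "call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def qc_filter(
    variants: pd.DataFrame, thr: QCThresholds
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter a variant table on MAF / INFO / call rate, strictly.

    Returns the surviving rows and a log of counts per failed criterion.
    Missing INFO or call-rate columns are treated as passing (and logged).
    """
    if variants.empty:
        logger.warning("qc_filter: empty variant table")
        return variants.copy(), {"input": 0, "pass": 0}
    if "MAF" not in variants.columns:
        raise ValueError("variant table lacks a MAF column")

    keep = variants["MAF"].to_numpy(float) > thr.maf_min
    log = {"input": len(variants), "fail_maf": int((~keep).sum())}
    for col, bound, key in (
        ("INFO", thr.info_min, "fail_info"),
        ("CALL_RATE", thr.call_rate_min, "fail_call_rate"),
    ):
        if col in variants.columns:
            ok = variants[col].to_numpy(float) > bound
            log[key] = int((keep & ~ok).sum())
            keep &= ok
        else:
            logger.info("qc_filter: no %s column, treated as pass", col)
    out = variants.loc[keep].copy()
    log["pass"] = len(out)
    return out, log


def standardize(values) -> np.ndarray:
    """Zero-mean, unit-variance (n-1 denominator) copy of a vector."""
    v = np.asarray(values, float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("standardize expects a vector of length >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        name = getattr(values, "name", None)
        raise ValueError(f"zero variance in column {name!r}" if name else "zero variance")
    return (v - v.mean()) / sd


def _residualize(y: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Residual of y (vector or matrix of columns) on an orthonormal basis q."""
    return y - q @ (q.T @ y)


def gwas_scan(
    cohort: CohortData,
    phenotype: str | np.ndarray,
    covariates: list[str] | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS association scan, vectorized across all SNPs.

    Parameters
    ----------
    phenotype : column name in ``cohort.traits`` or a length-n vector.
    covariates : column names in ``cohort.covariates``, an (n, C) array, or
        None.  An intercept is always included.

    Returns a summary-statistics DataFrame with columns
    SNP CHR POS EA OA EAF BETA SE P N (monomorphic SNPs get BETA=0, SE=inf,
    P=1 and MONOMORPHIC=True).
    """
    x = cohort.dosages
    n = x.shape[0]
    if isinstance(phenotype, str):
        if cohort.traits is None or phenotype not in cohort.traits:
            raise ValueError(f"phenotype {phenotype!r} not found in cohort traits")
        y = cohort.traits[phenotype].to_numpy(float)
    else:
        y = np.asarray(phenotype, float)
    if y.shape != (n,):
        raise ValueError("phenotype not row-aligned with dosages")

    if covariates is None:
        c = np.empty((n, 0))
    elif isinstance(covariates, (list, tuple)):
        c = cohort.covariates[list(covariates)].to_numpy(float)
    else:
        c = np.asarray(covariates, float)
    design = np.column_stack([np.ones(n), c])
    q, r = np.linalg.qr(design)
    if np.abs(np.diag(r)).min() < 1e-10 * np.abs(np.diag(r)).max():
        raise ValueError("covariate matrix is rank deficient")
    n_cov = c.shape[1]
    df = n - n_cov - 2
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")

    y_res = _residualize(y, q)
    x_res = _residualize(x, q)

    sxx = np.einsum("ij,ij->j", x_res, x_res)
    mono = sxx <= 1e-12
    sxx_safe = np.where(mono, 1.0, sxx)
    sxy = x_res.T @ y_res
    beta = sxy / sxx_safe
    syy = float(y_res @ y_res)
    ssr = np.maximum(syy - beta**2 * sxx_safe, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ssr / df / sxx_safe)
    degenerate = (se <= 0) & ~mono
    se_safe = np.where(se > 0, se, np.inf)
    tstat = beta / se_safe
    if df >= _NORMAL_DF:
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    beta = np.where(mono, 0.0, beta)
    se_out = np.where(mono | degenerate, np.inf, se)
    p = np.where(mono | degenerate, 1.0, p)
    if degenerate.any():
        logger.warning("gwas_scan: %d SNPs with zero residual variance", degenerate.sum())

    out = cohort.variant_meta[["SNP", "CHR", "POS", "EA", "OA"]].copy().reset_index(drop=True)
    out["EAF"] = x.mean(axis=0) / 2.0
    out["BETA"] = beta
    out["SE"] = se_out
    out["P"] = p
    out["N"] = n
    if mono.any() or degenerate.any():
        out["MONOMORPHIC"] = mono | degenerate
    return out
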