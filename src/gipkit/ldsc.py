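"""Simplified LD Score regression.

Univariate fits regress per-SNP association chi-square statistics on LD
scores: E[chi2_j] = N h2 l_j / M + a, so the slope estimates SNP-based
heritability on the analyzed scale and the free intercept a absorbs residual
confounding.  Bivariate fits regress z1_j z2_j on l_j to estimate genetic
covariance; with fully overlapping cohorts the cross-intercept is expected to
approach the phenotypic correlation.  Standard errors come from a
delete-one-block jackknife over contiguous SNP blocks, and the T-trait
genetic covariance matrix is assembled from all fits on the SAME blocks so a
joint jackknife covariance of its unique entries is available.

Weighting is a fixed two-pass scheme: pass 1 uses heteroskedasticity weights
1 / (2 l_j^2); pass 2 re-weights by the pass-1 predicted mean,
1 / (2 (a1 + N est1 l_j / M)^2 l_j).  The published software's weighting has
unstated constants; this scheme is documented and tested against a noiseless
oracle instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "LdScoreRegression",
    "LdscFit",
    "GeneticCovEstimate",
    "ld_scores_empirical",
    "ldsc_univariate",
    "ldsc_bivariate",
    "build_cov_matrix",
    "liability_h2",
]

_DEFAULT_BLOCKS = 200
# floor on the squared pass-2 predicted mean, guards bivariate fits near zero
_WEIGHT_FLOOR = 1e-2


def ld_scores_empirical(
    dosages: np.ndarray,
    variant_meta: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> np.ndarray:
    """Per-SNP LD scores from sample dosage correlations.

    l_j = 1 + sum over k != j within ``window_bp`` of the small-sample
    adjusted r2: r2 - (1 - r2) / (n - 2).  The self term contributes exactly
    1.  Monomorphic SNPs get l_j = 1 (logged).
    """
    n, m = dosages.shape
    if n < 3:
        raise ValueError("need n >= 3 to adjust r2")
    sd = dosages.std(axis=0, ddof=1)
    mono = sd <= 0
    if mono.any():
        logger.warning("ld_scores_empirical: %d monomorphic SNPs get l=1", mono.sum())
    x = (dosages - dosages.mean(axis=0)) / np.where(mono, 1.0, sd)
    x[:, mono] = 0.0

    chrom = variant_meta["CHR"].to_numpy()
    pos = variant_meta["POS"].to_numpy()
    l = np.ones(m)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        xc = x[:, idx]
        r = (xc.T @ xc) / (n - 1)
        r2 = r**2
        adj = r2 - (1.0 - r2) / (n - 2)
        dpos = np.abs(pos[idx][:, None] - pos[idx][None, :])
        mask = (dpos <= window_bp) & ~np.eye(len(idx), dtype=bool)
        sub_mono = mono[idx]
        mask[:, sub_mono] = False
        mask[sub_mono, :] = False
        l[idx] = 1.0 + np.where(mask, adj, 0.0).sum(axis=1)
    l[mono] = 1.0
    return l


@dataclass
class LdscFit:
    """Results of one LD Score regression fit.

    ``est`` is the slope-derived quantity: observed-scale h2 (univariate) or
    genetic covariance (bivariate).  Negative or >1 heritability estimates
    are reported and flagged, never truncated, so downstream Monte Carlo
    sampling sees honest noise.
    """

    est: float
    intercept: float
    est_se: float
    intercept_se: float
    n_blocks: int
    m: int
    n_eff: float
    kind: str  # "h2" or "cov"
    delete_values: np.ndarray = field(repr=False)  # (n_blocks, 2): est, intercept
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind == "h2" and not -0.5 <= self.est <= 1.5:
            self.flags.append(f"h2_obs={self.est:.3f} outside [-0.5, 1.5] guardrail")

    def summary(self) -> str:
        label = "h2_obs" if self.kind == "h2" else "gen_cov"
        lines = [
            "LD Score regression",
            f"  SNPs (M): {self.m}   effective N: {self.n_eff:.0f}   jackknife blocks: {self.n_blocks}",
            f"  {label}: {self.est:.4f} (SE {self.est_se:.4f})",
            f"  intercept: {self.intercept:.4f} (SE {self.intercept_se:.4f})",
        ]
        for f in self.flags:
            lines.append(f"  flag: {f}")
        return "\n".join(lines)


class LdScoreRegression:
    """Model object: regression of per-SNP statistics on LD scores.

    Parameters
    ----------
    y : per-SNP chi-square (univariate) or z1*z2 product (bivariate).
    ld_scores : aligned per-SNP LD scores.
    n_eff : sample size N (univariate) or sqrt(N1 N2) (bivariate).
    m : number of SNPs the polygenic signal is spread over (default len(y)).
    n_blocks : jackknife blocks, clipped to [2, M/2].
    kind : "h2" or "cov" -- controls labeling/guardrails only.
    """

    def __init__(self, y, ld_scores, n_eff, m=None, n_blocks=_DEFAULT_BLOCKS, kind="h2"):
        self.y = np.asarray(y, float)
        self.l = np.asarray(ld_scores, float)
        if self.y.shape != self.l.shape or self.y.ndim != 1:
            raise ValueError("y and ld_scores must be aligned vectors")
        if np.ptp(self.l) <= 1e-12:
            raise ValueError("LD scores have zero variance; slope not identifiable")
        self.n_eff = float(n_eff)
        self.m = int(m) if m is not None else self.y.size
        n_blocks = int(min(n_blocks, self.y.size // 2))
        if n_blocks < 2:
            raise ValueError("need at least 2 jackknife blocks (and >= 4 SNPs)")
        if n_blocks > self.y.size:
            raise ValueError("more jackknife blocks than SNPs")
        self.n_blocks = n_blocks
        self.kind = kind

    def _wls(self, w):
        """Weighted fit of y on [1, l]; returns (intercept, slope)."""
        x = np.column_stack([np.ones_like(self.l), self.l])
        xtwx = x.T @ (w[:, None] * x)
        xtwy = x.T @ (w * self.y)
        return np.linalg.solve(xtwx, xtwy)

    def fit(self) -> LdscFit:
        # pass 1: heteroskedasticity weights from the LD scores alone
        w1 = 1.0 / (2.0 * self.l**2)
        a1, b1 = self._wls(w1)
        # pass 2: weights from the pass-1 predicted per-SNP mean
        pred = a1 + b1 * self.l
        w2 = 1.0 / (2.0 * np.maximum(pred**2, _WEIGHT_FLOOR) * self.l)

        x = np.column_stack([np.ones_like(self.l), self.l])
        xtwx_full = x.T @ (w2[:, None] * x)
        xtwy_full = x.T @ (w2 * self.y)
        coef = np.linalg.solve(xtwx_full, xtwy_full)
        scale = self.m / self.n_eff

        # delete-one-block jackknife with pass-2 weights held fixed
        bounds = np.linspace(0, self.y.size, self.n_blocks + 1).astype(int)
        deletes = np.empty((self.n_blocks, 2))
        for b in range(self.n_blocks):
            s = slice(bounds[b], bounds[b + 1])
            xb = x[s]
            wb = w2[s]
            xtwx_b = xb.T @ (wb[:, None] * xb)
            xtwy_b = xb.T @ (wb * self.y[s])
            cb = np.linalg.solve(xtwx_full - xtwx_b, xtwy_full - xtwy_b)
            deletes[b] = (cb[1] * scale, cb[0])
        mean_del = deletes.mean(axis=0)
        fac = (self.n_blocks - 1) / self.n_blocks
        se = np.sqrt(fac * ((deletes - mean_del) ** 2).sum(axis=0))

        return LdscFit(
            est=float(coef[1] * scale),
            intercept=float(coef[0]),
            est_se=float(se[0]),
            intercept_se=float(se[1]),
            n_blocks=self.n_blocks,
            m=self.m,
            n_eff=self.n_eff,
            kind=self.kind,
            delete_values=deletes,
        )


def _align_ld(ss: pd.DataFrame, ld) -> np.ndarray:
    if isinstance(ld, pd.DataFrame):
        cols = {c.upper(): c for c in ld.columns}
        merged = ss[["SNP"]].merge(
            ld.rename(columns={cols["SNP"]: "SNP", cols["L2"]: "L2"}),
            on="SNP",
            how="left",
        )
        if merged["L2"].isna().any():
            raise ValueError("LD scores missing for some SNPs in the sumstats")
        return merged["L2"].to_numpy(float)
    ld = np.asarray(ld, float)
    if ld.shape[0] != len(ss):
        raise ValueError("LD score vector not aligned with sumstats")
    return ld


def ldsc_univariate(
    ss: pd.DataFrame, ld_scores, m: int | None = None, n_blocks: int = _DEFAULT_BLOCKS
) -> LdscFit:
    """Heritability fit: chi2_j = (BETA/SE)^2 regressed on l_j."""
    l = _align_ld(ss, ld_scores)
    z = ss["BETA"].to_numpy(float) / ss["SE"].to_numpy(float)
    n_eff = float(ss["N"].mean())
    return LdScoreRegression(z**2, l, n_eff, m=m, n_blocks=n_blocks, kind="h2").fit()


def align_alleles(ss1: pd.DataFrame, ss2: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two sumstats on SNP, aligning ss2's effect allele to ss1's.

    Exact (EA, OA) match keeps the sign; a swap flips the sign of z2 (and
    EAF); any other allele pair is dropped with a log message.  Requires at
    least 50% SNP overlap relative to the smaller table.
    """
    merged = ss1.merge(ss2, on="SNP", suffixes=("_1", "_2"))
    if len(merged) < 0.5 * min(len(ss1), len(ss2)):
        raise ValueError("less than 50% SNP overlap between sumstats tables")
    same = (merged["EA_1"] == merged["EA_2"]) & (merged["OA_1"] == merged["OA_2"])
    swap = (merged["EA_1"] == merged["OA_2"]) & (merged["OA_1"] == merged["EA_2"])
    bad = ~(same | swap)
    if bad.any():
        logger.warning("align_alleles: dropping %d allele-mismatched SNPs", bad.sum())
        merged = merged.loc[~bad].copy()
        same, swap = same[~bad], swap[~bad]
    merged["SIGN_2"] = np.where(swap, -1.0, 1.0)
    return merged


def ldsc_bivariate(
    ss1: pd.DataFrame,
    ss2: pd.DataFrame,
    ld_scores,
    m: int | None = None,
    n_blocks: int = _DEFAULT_BLOCKS,
) -> LdscFit:
    """Genetic covariance fit: z1_j z2_j regressed on l_j.

    The free intercept absorbs sample overlap (for fully overlapping cohorts
    its expectation is roughly the phenotypic correlation).
    """
    merged = align_alleles(ss1, ss2)
    l = _align_ld(merged.rename(columns={"SNP": "SNP"}), ld_scores)
    z1 = merged["BETA_1"].to_numpy(float) / merged["SE_1"].to_numpy(float)
    z2 = merged["SIGN_2"].to_numpy() * merged["BETA_2"].to_numpy(float) / merged[
        "SE_2"
    ].to_numpy(float)
    n_eff = float(np.sqrt(merged["N_1"].mean() * merged["N_2"].mean()))
    return LdScoreRegression(z1 * z2, l, n_eff, m=m, n_blocks=n_blocks, kind="cov").fit()


def vech_indices(t: int) -> list[tuple[int, int]]:
    """Column-major lower-triangle (half-vectorization) index order."""
    return [(i, j) for j in range(t) for i in range(j, t)]


@dataclass
class GeneticCovEstimate:
    """T x T genetic covariance matrix with joint jackknife covariance.

    ``J`` is the jackknife sampling covariance of the T(T+1)/2 unique C_G
    entries in column-major lower-triangle (vech) order.
    """

    C_G: np.ndarray
    intercepts: np.ndarray
    J: np.ndarray
    trait_names: tuple[str, ...]
    m: int
    n_blocks: int
    fits: dict = field(default_factory=dict, repr=False)

    @property
    def n_traits(self) -> int:
        return self.C_G.shape[0]

    @property
    def r_g(self) -> np.ndarray:
        d = np.sqrt(np.abs(np.diag(self.C_G)))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.C_G / np.outer(d, d)
        off = r[~np.eye(self.n_traits, dtype=bool)]
        if np.any(np.abs(off) > 1.05):
            logger.warning("genetic correlations exceed the [-1.05, 1.05] noise band")
        return r

    def entry_se(self) -> np.ndarray:
        """Jackknife SE of each C_G entry, as a symmetric T x T matrix."""
        t = self.n_traits
        se = np.zeros((t, t))
        for k, (i, j) in enumerate(vech_indices(t)):
            se[i, j] = se[j, i] = np.sqrt(self.J[k, k])
        return se

    def summary(self) -> str:
        names = self.trait_names
        lines = [f"Genetic covariance matrix ({self.n_traits} traits, M={self.m})"]
        se = self.entry_se()
        for i, nm in enumerate(names):
            row = "  ".join(
                f"{self.C_G[i, j]:+.4f}({se[i, j]:.4f})" for j in range(self.n_traits)
            )
            lines.append(f"  {nm:>20s}  {row}")
        lines.append("  intercepts diag: " + ", ".join(f"{v:.3f}" for v in np.diag(self.intercepts)))
        return "\n".join(lines)


def build_cov_matrix(
    tables: list[pd.DataFrame],
    ld_scores,
    m: int | None = None,
    n_blocks: int = _DEFAULT_BLOCKS,
    trait_names: list[str] | None = None,
    allow_fewer: bool = False,
) -> GeneticCovEstimate:
    """All univariate + pairwise bivariate fits on shared jackknife blocks.

    The SNP set is intersected across all tables first so every fit sees the
    same SNPs in the same order; the joint jackknife covariance J of the
    unique C_G entries is assembled from the leave-one-block-out replicates.
    """
    t = len(tables)
    if t < 3 and not allow_fewer:
        raise ValueError("the decomposition is intended for three or more traits")
    names = tuple(trait_names) if trait_names else tuple(f"trait{i + 1}" for i in range(t))

    common = tables[0][["SNP"]]
    for tab in tables[1:]:
        common = common.merge(tab[["SNP"]], on="SNP")
    if common.empty:
        raise ValueError("no SNPs shared by all traits")
    tabs = [
        common.merge(tab, on="SNP", how="left").reset_index(drop=True) for tab in tables
    ]
    l = _align_ld(tabs[0], ld_scores)
    m_eff = int(m) if m is not None else len(common)

    c_g = np.zeros((t, t))
    intercepts = np.zeros((t, t))
    fits: dict = {}
    for i in range(t):
        try:
            fit = ldsc_univariate(tabs[i], l, m=m_eff, n_blocks=n_blocks)
        except Exception as exc:  # pragma: no cover - re-raise with context
            raise RuntimeError(f"univariate LDSC failed for {names[i]}: {exc}") from exc
        c_g[i, i] = fit.est
        intercepts[i, i] = fit.intercept
        fits[(i, i)] = fit
    for i in range(t):
        for j in range(i + 1, t):
            try:
                fit = ldsc_bivariate(tabs[i], tabs[j], l, m=m_eff, n_blocks=n_blocks)
            except Exception as exc:
                raise RuntimeError(
                    f"bivariate LDSC failed for pair ({names[i]}, {names[j]}): {exc}"
                ) from exc
            c_g[i, j] = c_g[j, i] = fit.est
            intercepts[i, j] = intercepts[j, i] = fit.intercept
            fits[(i, j)] = fit

    order = vech_indices(t)
    n_b = fits[(0, 0)].n_blocks
    deletes = np.column_stack(
        [fits[(min(i, j), max(i, j)) if i != j else (i, i)].delete_values[:, 0] for i, j in order]
    )
    mean_del = deletes.mean(axis=0)
    dev = deletes - mean_del
    j_cov = (n_b - 1) / n_b * (dev.T @ dev)

    return GeneticCovEstimate(
        C_G=c_g,
        intercepts=intercepts,
        J=j_cov,
        trait_names=names,
        m=m_eff,
        n_blocks=n_b,
        fits=fits,
    )


def liability_h2(h2_obs: float, k_population: float, p_sample: float | None = None) -> float:
    """Observed-scale to liability-scale heritability for a binary trait.

    h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) phi(z)^2), z = Phi^-1(1 - K).
    With P = K (a population cohort) this reduces to
    h2_obs * K (1-K) / phi(z)^2.
    """
    k = float(k_population)
    p = k if p_sample is None else float(p_sample)
    if not (0.0 < k < 1.0 and 0.0 < p < 1.0):
        raise ValueError("prevalences must lie strictly inside (0, 1)")
    z = stats.norm.isf(k)
    return h2_obs * k**2 * (1.0 - k) ** 2 / (p * (1.0 - p) * stats.norm.pdf(z) ** 2)
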