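"""Genetically independent phenotypes (GIPs).

A GIP is a linear combination of standardized traits whose weights are the
eigenvectors of the genetic covariance matrix estimated from GWAS summary
statistics.  GIPs are mutually genetically uncorrelated; the first GIP
captures the largest share of total genetic variance, with later GIPs
explaining progressively less.  The decomposition mirrors principal component
analysis, except that the genetic -- not the phenotypic -- covariance matrix
is decomposed, so the components are independent on the genetic rather than
the phenotypic level.

`GipDecomposition` is the model object (built from a
:class:`~gipkit.ldsc.GeneticCovEstimate` or a raw matrix); its ``fit``
returns :class:`GipResults`, which carries the loadings, eigenvalues, Monte
Carlo confidence intervals, explained-variance tables and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc
from .ldsc import GeneticCovEstimate, vech_indices
from .simdata import CohortData

logger = logging.getLogger(__name__)

__all__ = [
    "GipDecomposition",
    "GipResults",
    "PhenoCorrMatrix",
    "gip_decompose",
    "explained_variance",
    "monte_carlo_loading_ci",
    "gip_scores",
    "gip_gwas_individual",
    "gip_gwas_summary",
    "predict_gip_pheno_corr",
    "gip_h2",
    "sample_pheno_corr",
]

_TIE_TOL = 1e-12
_SYM_TOL = 1e-8


def _fix_sign(a: np.ndarray) -> np.ndarray:
    """Per column: loading sum positive; if ~0, largest-|entry| positive."""
    a = a.copy()
    for k in range(a.shape[1]):
        s = a[:, k].sum()
        if abs(s) < _TIE_TOL:
            s = a[np.argmax(np.abs(a[:, k])), k]
        if s < 0:
            a[:, k] = -a[:, k]
    return a


def _ordered_eigh(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with descending eigenvalues and fixed conventions.

    Ties (|d-lambda| < 1e-12) are broken by descending lexicographic order of
    the absolute loadings, so a scalar matrix yields identity loadings.
    """
    w, v = np.linalg.eigh(c)
    order = np.argsort(-w, kind="stable")
    w, v = w[order], v[:, order]
    v = _fix_sign(v)
    # resolve ordering inside tied eigenvalue groups
    start = 0
    while start < len(w):
        stop = start + 1
        while stop < len(w) and abs(w[stop] - w[start]) < _TIE_TOL:
            stop += 1
        if stop - start > 1:
            cols = sorted(
                range(start, stop), key=lambda k: tuple(np.round(-np.abs(v[:, k]), 9))
            )
            v[:, start:stop] = v[:, cols]
        start = stop
    return w, v


class GipDecomposition:
    """Model: eigendecomposition of a genetic covariance matrix.

    Parameters
    ----------
    est : GeneticCovEstimate, or a symmetric (T, T) array.
    trait_names : required when a raw array is given.
    jackknife_cov : sampling covariance of vech(C_G); enables Monte Carlo
        loading confidence intervals at ``fit`` time.
    allow_two_traits : override the T >= 3 requirement for toy problems.
    """

    def __init__(
        self,
        est: GeneticCovEstimate | np.ndarray,
        trait_names: list[str] | None = None,
        jackknife_cov: np.ndarray | None = None,
        allow_two_traits: bool = False,
    ):
        if isinstance(est, GeneticCovEstimate):
            c_g = est.C_G
            names = est.trait_names
            j = est.J if jackknife_cov is None else jackknife_cov
        else:
            c_g = np.asarray(est, float)
            names = tuple(trait_names) if trait_names else tuple(
                f"trait{i + 1}" for i in range(c_g.shape[0])
            )
            j = jackknife_cov
        t = c_g.shape[0]
        if c_g.shape != (t, t):
            raise ValueError("genetic covariance matrix must be square")
        if np.abs(c_g - c_g.T).max() > _SYM_TOL:
            raise ValueError("genetic covariance matrix is asymmetric beyond 1e-8")
        if t < 3 and not allow_two_traits:
            raise ValueError("at least three traits required (allow_two_traits overrides)")
        if len(names) != t:
            raise ValueError("need one name per trait")
        self.C_G = (c_g + c_g.T) / 2.0
        self.trait_names = tuple(names)
        self.J = None if j is None else np.asarray(j, float)

    def fit(self, ci_draws: int = 1000, seed: int | None = None) -> "GipResults":
        """Decompose; if a jackknife covariance is present and ``ci_draws`` > 0,
        attach Monte Carlo 95% confidence intervals to the loadings."""
        w, v = _ordered_eigh(self.C_G)
        flags = []
        if w.min() < 0:
            flags.append(f"negative eigenvalue {w.min():.3e} (noise in C_G)")
        res = GipResults(
            loadings=v,
            eigenvalues=w,
            C_G=self.C_G,
            trait_names=self.trait_names,
            J=self.J,
            flags=flags,
        )
        if self.J is not None and ci_draws:
            res.loading_cis = monte_carlo_loading_ci(res, self.J, ci_draws, seed)
        return res


@dataclass
class GipResults:
    """Fitted GIP decomposition.

    ``loadings`` columns are the orthogonal transformation coefficients a_k
    of GIP k (unit norm, mutually orthogonal); ``eigenvalues`` are the
    genetic variances of the GIPs, descending.
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray
    C_G: np.ndarray
    trait_names: tuple[str, ...]
    J: np.ndarray | None = None
    loading_cis: np.ndarray | None = None  # (T, T, 2): 2.5% and 97.5%
    flags: list[str] = field(default_factory=list)

    @property
    def n_traits(self) -> int:
        return self.loadings.shape[0]

    @property
    def gip_names(self) -> tuple[str, ...]:
        return tuple(f"GIP{k + 1}" for k in range(self.n_traits))

    @property
    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=self.trait_names, columns=self.gip_names)

    @property
    def explained_total(self) -> np.ndarray:
        """Fraction of total genetic variance per GIP: lambda_k / sum(lambda)."""
        total = self.eigenvalues.sum()
        if total <= 0:
            raise ValueError("no genetic signal: eigenvalue sum <= 0")
        return self.eigenvalues / total

    @property
    def explained_per_trait(self) -> np.ndarray:
        """Share of each trait's genetic variance captured by each GIP."""
        diag = np.diag(self.C_G)
        if np.any(diag <= 0):
            raise ValueError("explained_per_trait undefined for traits with h2 <= 0")
        return (self.loadings**2 * self.eigenvalues[None, :]) / diag[:, None]

    def conf_int(self) -> np.ndarray:
        if self.loading_cis is None:
            raise ValueError("no confidence intervals; fit with ci_draws > 0 and J")
        return self.loading_cis

    def scores(self, traits: pd.DataFrame) -> pd.DataFrame:
        return gip_scores(traits, self)

    def h2(self, c_p: np.ndarray) -> np.ndarray:
        return gip_h2(self, c_p)

    def predict_pheno_corr(self, c_p: np.ndarray) -> "PhenoCorrMatrix":
        return predict_gip_pheno_corr(self, c_p)

    def summary(self) -> str:
        lines = [f"GIP decomposition of {self.n_traits} traits"]
        ev = self.explained_total
        for k, name in enumerate(self.gip_names):
            lines.append(
                f"  {name}: eigenvalue {self.eigenvalues[k]:+.5f}, "
                f"explains {100 * ev[k]:.1f}% of total genetic variance"
            )
        lines.append("  loadings (rows = traits):")
        lf = self.loadings_frame
        if self.loading_cis is not None:
            for t, nm in enumerate(self.trait_names):
                cells = [
                    f"{self.loadings[t, k]:+.3f} [{self.loading_cis[t, k, 0]:+.3f}, "
                    f"{self.loading_cis[t, k, 1]:+.3f}]"
                    for k in range(self.n_traits)
                ]
                lines.append(f"    {nm:>20s}  " + "  ".join(cells))
        else:
            for t, nm in enumerate(self.trait_names):
                lines.append(
                    f"    {nm:>20s}  "
                    + "  ".join(f"{v:+.4f}" for v in lf.iloc[t])
                )
        for f in self.flags:
            lines.append(f"  flag: {f}")
        return "\n".join(lines)


def gip_decompose(
    est: GeneticCovEstimate | np.ndarray,
    trait_names: list[str] | None = None,
    allow_two_traits: bool = False,
) -> GipResults:
    """Point-estimate decomposition (no confidence intervals)."""
    return GipDecomposition(
        est, trait_names=trait_names, allow_two_traits=allow_two_traits
    ).fit(ci_draws=0)


def explained_variance(res: GipResults) -> tuple[np.ndarray, np.ndarray]:
    """(explained_total, explained_per_trait) tables of a fitted model."""
    return res.explained_total, res.explained_per_trait


def _nearest_psd(j: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh((j + j.T) / 2.0)
    if w.min() < -1e-12:
        logger.warning("jackknife covariance not PSD; clipping eigenvalues at 0")
    return (v * np.clip(w, 0.0, None)) @ v.T


def _greedy_match(a_ref: np.ndarray, a_new: np.ndarray) -> np.ndarray:
    """Reorder/sign-flip a_new's columns to best match a_ref (max |inner|)."""
    t = a_ref.shape[1]
    scores = np.abs(a_ref.T @ a_new)  # rows: ref cols, cols: new cols
    perm = np.full(t, -1)
    used_ref, used_new = set(), set()
    flat = np.argsort(-scores, axis=None)
    for idx in flat:
        i, j = divmod(idx, t)
        if i in used_ref or j in used_new:
            continue
        perm[i] = j
        used_ref.add(i)
        used_new.add(j)
        if len(used_ref) == t:
            break
    out = a_new[:, perm]
    signs = np.sign(np.einsum("ij,ij->j", a_ref, out))
    signs[signs == 0] = 1.0
    return out * signs


def monte_carlo_loading_ci(
    res: GipResults, j_cov: np.ndarray, n_draws: int = 1000, seed: int | None = None
) -> np.ndarray:
    """Monte Carlo 95% confidence intervals for the loadings.

    vech(C_G*) is drawn from MVN(vech(C_G), J); each draw is symmetrized and
    eigendecomposed, the draw's columns are matched to the point-estimate
    columns greedily by maximal |inner product| (sign-flipped positive), and
    the 2.5/97.5 loading percentiles across draws form the intervals.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    t = res.n_traits
    order = vech_indices(t)
    if j_cov.shape != (len(order), len(order)):
        raise ValueError("jackknife covariance not conformable with vech(C_G)")
    j_psd = _nearest_psd(j_cov)
    rng = np.random.default_rng(seed)
    mean = np.array([res.C_G[i, jj] for i, jj in order])
    draws = rng.multivariate_normal(mean, j_psd, size=n_draws, method="eigh")

    samples = np.empty((n_draws, t, t))
    for d in range(n_draws):
        c = np.zeros((t, t))
        for v, (i, jj) in zip(draws[d], order):
            c[i, jj] = c[jj, i] = v
        w, vecs = np.linalg.eigh(c)
        o = np.argsort(-w)
        samples[d] = _greedy_match(res.loadings, vecs[:, o])
    lo = np.percentile(samples, 2.5, axis=0)
    hi = np.percentile(samples, 97.5, axis=0)
    return np.stack([lo, hi], axis=-1)


def gip_scores(traits: pd.DataFrame, res: GipResults) -> pd.DataFrame:
    """GIP phenotypes: standardized traits weighted by the fitted loadings.

    Loadings are never refitted on the cohort being scored; replication
    cohorts use the discovery coefficients unchanged.
    """
    if tuple(traits.columns) != res.trait_names:
        raise ValueError(
            f"trait columns {tuple(traits.columns)} do not match model {res.trait_names}"
        )
    y = np.column_stack([assoc.standardize(traits[c]) for c in traits.columns])
    return pd.DataFrame(y @ res.loadings, columns=res.gip_names, index=traits.index)


def gip_gwas_individual(
    cohort: CohortData,
    res: GipResults,
    covariates: list[str] | np.ndarray | None = None,
) -> list[pd.DataFrame]:
    """GWAS of each GIP score column, with the same covariates as trait GWAS."""
    scores = gip_scores(cohort.traits, res)
    return [
        assoc.gwas_scan(cohort, scores[k].to_numpy(), covariates) for k in res.gip_names
    ]


def gip_gwas_summary(
    tables: list[pd.DataFrame],
    res: GipResults,
    c_p: np.ndarray,
    n_override: float | None = None,
) -> list[pd.DataFrame]:
    """GIP GWAS assembled from per-trait summary statistics alone.

    All trait effects must be on the standardized-phenotype scale of one
    fully overlapping cohort.  BETA_GIPk = sum_t A[t,k] BETA_t; the standard
    error propagates the estimation-error covariance approximation
    cov(beta_t, beta_s) = C_P[t,s] SE_t SE_s.
    """
    t = res.n_traits
    if len(tables) != t:
        raise ValueError("need one sumstats table per trait")
    c_p = np.asarray(c_p, float)

    common = tables[0][["SNP"]]
    for tab in tables[1:]:
        common = common.merge(tab[["SNP"]], on="SNP")
    dropped = max(len(tab) for tab in tables) - len(common)
    if dropped:
        logger.warning("gip_gwas_summary: dropping %d SNPs missing in some trait", dropped)
    tabs = [common.merge(tab, on="SNP", how="left").reset_index(drop=True) for tab in tables]

    n_mat = np.column_stack([tab["N"].to_numpy(float) for tab in tabs])
    if np.ptp(n_mat, axis=1).max() > 0.01 * n_mat.min():
        logger.warning("gip_gwas_summary: trait sample sizes differ by >1%%; using min N")
    n_use = n_mat.min(axis=1) if n_override is None else np.full(len(common), n_override)

    betas = np.column_stack([tab["BETA"].to_numpy(float) for tab in tabs])
    ses = np.column_stack([tab["SE"].to_numpy(float) for tab in tabs])
    out = []
    a = res.loadings
    for k in range(t):
        beta_k = betas @ a[:, k]
        # SE^2 = sum_{t,s} a_t a_s C_P[t,s] SE_t SE_s, vectorized over SNPs
        w = ses * a[:, k][None, :]
        var_k = np.einsum("jt,ts,js->j", w, c_p, w)
        se_k = np.sqrt(var_k)
        z = np.divide(beta_k, se_k, out=np.zeros_like(beta_k), where=se_k > 0)
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
        tab = tabs[0][["SNP", "CHR", "POS", "EA", "OA", "EAF"]].copy()
        tab["BETA"] = beta_k
        tab["SE"] = se_k
        tab["P"] = p
        tab["N"] = n_use
        out.append(tab)
    return out


@dataclass
class PhenoCorrMatrix:
    """Phenotypic correlations of traits plus predicted GIP correlations."""

    C_P: np.ndarray
    gip_corr: np.ndarray
    trait_gip_corr: np.ndarray
    trait_names: tuple[str, ...]
    gip_names: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, m in (("C_P", self.C_P), ("gip_corr", self.gip_corr)):
            if not np.allclose(np.diag(m), 1.0, atol=1e-8):
                raise ValueError(f"{name} must have unit diagonal")


def predict_gip_pheno_corr(res: GipResults, c_p: np.ndarray) -> PhenoCorrMatrix:
    """Predicted phenotypic correlations among GIPs and between traits and GIPs.

    cov(GIP_j, GIP_k) = a_j' C_P a_k; trait x GIP correlation is
    (C_P a_k)_t / sqrt(a_k' C_P a_k) for standardized traits.
    """
    c_p = np.asarray(c_p, float)
    if not np.allclose(c_p, c_p.T, atol=1e-8) or not np.allclose(np.diag(c_p), 1.0, atol=1e-8):
        raise ValueError("C_P must be a symmetric correlation matrix")
    if np.linalg.eigvalsh(c_p).min() < -1e-8:
        logger.warning("C_P is not positive semidefinite; proceeding")
    a = res.loadings
    gip_cov = a.T @ c_p @ a
    d = np.sqrt(np.diag(gip_cov))
    gip_corr = gip_cov / np.outer(d, d)
    trait_gip = (c_p @ a) / d[None, :]
    return PhenoCorrMatrix(
        C_P=c_p,
        gip_corr=gip_corr,
        trait_gip_corr=trait_gip,
        trait_names=res.trait_names,
        gip_names=res.gip_names,
    )


def gip_h2(res: GipResults, c_p: np.ndarray) -> np.ndarray:
    """Observed-scale h2 of each GIP: lambda_k / (a_k' C_P a_k)."""
    c_p = np.asarray(c_p, float)
    a = res.loadings
    pheno_var = np.einsum("tk,ts,sk->k", a, c_p, a)
    if np.any(pheno_var <= 0):
        raise ValueError("zero phenotypic variance for some GIP")
    return res.eigenvalues / pheno_var


def sample_pheno_corr(traits: pd.DataFrame) -> np.ndarray:
    """Sample phenotypic correlation matrix of the trait panel."""
    return np.corrcoef(traits.to_numpy(float), rowvar=False)
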