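"""Post-GWAS processing.

Genomic-control correction by the LD Score regression intercept, fixed-effects
inverse-variance meta-analysis, positional locus clumping (+/-250 kb around
the lead SNP) and the discovery-to-replication decision procedure.  P-values
are handled in log10 space internally so corrections survive P < 1e-300.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Locus",
    "ReplicationReport",
    "gc_correct",
    "ivw_meta",
    "clump",
    "replication_gate",
    "study_thresholds",
    "GENOME_WIDE_P",
    "LOCUS_HALF_WIDTH_BP",
]

#: conventional genome-wide significance level for a single phenotype
GENOME_WIDE_P = 5e-8
#: positional locus definition: lead SNP position +/- this many bases
LOCUS_HALF_WIDTH_BP = 250_000


def gc_correct(ss: pd.DataFrame, intercept: float) -> pd.DataFrame:
    """Divide association chi-squares by the LDSC intercept.

    chi2_GC = (BETA/SE)^2 / intercept; P_GC is the upper 1-df chi-square tail
    computed in log space; BETA is unchanged and SE_GC = SE * sqrt(intercept).
    """
    if intercept <= 0:
        raise ValueError("intercept must be positive")
    out = ss.copy()
    z2 = (out["BETA"].to_numpy(float) / out["SE"].to_numpy(float)) ** 2
    # 1-df chi-square upper tail via the normal law: sf(x) = 2 Phi(-sqrt(x)),
    # with norm.logsf staying accurate far beyond double underflow
    log10_pgc = (np.log(2.0) + stats.norm.logsf(np.sqrt(z2 / intercept))) / np.log(10.0)
    out["SE_GC"] = out["SE"] * np.sqrt(intercept)
    out["LOG10_P_GC"] = log10_pgc
    out["P_GC"] = np.power(10.0, np.maximum(log10_pgc, -300.0))
    return out


def ivw_meta(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effects inverse-variance-weighted meta-analysis.

    Records are matched on (CHR, POS); alleles are aligned to the first
    cohort carrying each SNP (EA/OA swap flips the effect sign and EAF;
    other allele pairs are dropped with a log message).  SNPs present in a
    subset of cohorts are combined over that subset, with N_meta summed over
    the contributing cohorts.
    """
    if not tables:
        raise ValueError("need at least one cohort")
    if len(tables) == 1:
        return tables[0].copy()

    stacked = pd.concat(
        [t.assign(_cohort=i) for i, t in enumerate(tables)], ignore_index=True
    )
    # reference alleles: first cohort carrying each (CHR, POS)
    ref = stacked.drop_duplicates(subset=["CHR", "POS"], keep="first")[
        ["CHR", "POS", "SNP", "EA", "OA"]
    ].rename(columns={"SNP": "_rsnp", "EA": "_rea", "OA": "_roa"})
    s = stacked.merge(ref, on=["CHR", "POS"], how="left")
    same = (s["EA"] == s["_rea"]) & (s["OA"] == s["_roa"])
    swap = (s["EA"] == s["_roa"]) & (s["OA"] == s["_rea"])
    bad = ~(same | swap)
    if bad.any():
        logger.warning("ivw_meta: dropped %d allele-mismatched records", int(bad.sum()))
        s = s.loc[~bad].copy()
        swap = swap[~bad]
    if s.empty:
        raise ValueError("no records to meta-analyze")
    sign = np.where(swap, -1.0, 1.0)
    s["_beta"] = sign * s["BETA"].to_numpy(float)
    s["_w"] = 1.0 / s["SE"].to_numpy(float) ** 2
    s["_wb"] = s["_w"] * s["_beta"]
    s["_n"] = s["N"].to_numpy(float)
    if "EAF" in s.columns:
        eaf = np.where(swap, 1.0 - s["EAF"].to_numpy(float), s["EAF"].to_numpy(float))
    else:
        eaf = np.full(len(s), np.nan)
    s["_eafn"] = eaf * s["_n"]

    g = s.groupby(["CHR", "POS"], sort=True)
    agg = g.agg(
        SNP=("_rsnp", "first"),
        EA=("_rea", "first"),
        OA=("_roa", "first"),
        _w=("_w", "sum"),
        _wb=("_wb", "sum"),
        N=("_n", "sum"),
        _eafn=("_eafn", "sum"),
    ).reset_index()
    beta = agg["_wb"] / agg["_w"]
    se = 1.0 / np.sqrt(agg["_w"])
    z = beta / se
    out = agg[["SNP", "CHR", "POS", "EA", "OA"]].copy()
    out["EAF"] = agg["_eafn"] / agg["N"]
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    out["N"] = agg["N"]
    return out.sort_values(["CHR", "POS"]).reset_index(drop=True)


@dataclass
class Locus:
    """A clumped association locus: lead SNP and its +/-250 kb window."""

    lead: pd.Series
    chrom: int
    start: int
    end: int
    n_members: int
    label: str = ""

    @property
    def lead_snp(self) -> str:
        return str(self.lead["SNP"])


def clump(
    ss: pd.DataFrame,
    p_col: str = "P",
    threshold: float = GENOME_WIDE_P,
    window_bp: int = LOCUS_HALF_WIDTH_BP,
    label: str = "",
) -> list[Locus]:
    """Greedy positional clumping.

    Repeatedly take the smallest-P SNP below ``threshold``, form a locus of
    all SNPs within +/- ``window_bp`` on its chromosome, remove them, and
    continue.  Ties in P are broken by (CHR, POS).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    work = ss.loc[ss[p_col] < threshold].sort_values(
        [p_col, "CHR", "POS"], kind="mergesort"
    )
    loci: list[Locus] = []
    while not work.empty:
        lead = work.iloc[0]
        chrom, pos = int(lead["CHR"]), int(lead["POS"])
        member = (work["CHR"] == chrom) & (np.abs(work["POS"] - pos) <= window_bp)
        loci.append(
            Locus(
                lead=lead,
                chrom=chrom,
                start=pos - window_bp,
                end=pos + window_bp,
                n_members=int(member.sum()),
                label=label,
            )
        )
        work = work.loc[~member]
    return loci


@dataclass
class ReplicationReport:
    """Per-locus discovery vs replication verdicts (study-table analogue)."""

    table: pd.DataFrame
    threshold: float
    alpha: float
    n_discovery_loci: int

    @property
    def n_replicated(self) -> int:
        return int((self.table["VERDICT"] == "replicated").sum())

    def summary(self) -> str:
        lines = [
            f"Replication of {self.n_discovery_loci} discovery loci "
            f"(threshold {self.threshold:.3g} = {self.alpha}/{self.n_discovery_loci})",
            f"  replicated: {self.n_replicated}",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"  {r['LABEL']:>6s} {r['SNP']:>16s} {int(r['CHR'])}:{int(r['POS'])} "
                f"P_disc={r['P_DISC']:.3g} P_meta={r['P_META']:.3g} -> {r['VERDICT']}"
            )
        return "\n".join(lines)


def replication_gate(
    discovery_loci: dict[str, list[Locus]],
    replication_meta: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> ReplicationReport:
    """Bonferroni replication decision across all discovery loci.

    The threshold is alpha divided by the TOTAL number of discovery loci
    across phenotypes.  A locus replicates iff its lead SNP's meta-analysis P
    is below that threshold AND the effect direction matches discovery.  A
    lead SNP absent from the replication meta-analysis is verdict "untested".
    """
    n_loci = sum(len(v) for v in discovery_loci.values())
    if n_loci == 0:
        raise ValueError("no discovery loci to replicate")
    threshold = alpha / n_loci

    rows = []
    for label, loci in discovery_loci.items():
        meta = replication_meta.get(label)
        for locus in loci:
            lead = locus.lead
            rec = {
                "LABEL": label,
                "SNP": lead["SNP"],
                "CHR": lead["CHR"],
                "POS": lead["POS"],
                "BETA_DISC": lead["BETA"],
                "SE_DISC": lead["SE"],
                "P_DISC": lead["P"],
                "P_GC_DISC": lead.get("P_GC", np.nan),
            }
            hit = None
            if meta is not None:
                match = meta.loc[(meta["CHR"] == lead["CHR"]) & (meta["POS"] == lead["POS"])]
                if len(match):
                    hit = match.iloc[0]
            if hit is None:
                logger.warning("replication_gate: lead %s untested", lead["SNP"])
                rec.update(
                    BETA_META=np.nan, SE_META=np.nan, P_META=np.nan, N_META=np.nan,
                    SIGN_CONSISTENT=False, VERDICT="untested",
                )
            else:
                flip = -1.0 if (hit["EA"], hit["OA"]) == (lead["OA"], lead["EA"]) else 1.0
                beta_meta = flip * hit["BETA"]
                sign_ok = np.sign(beta_meta) == np.sign(lead["BETA"])
                ok = bool(hit["P"] < threshold and sign_ok)
                rec.update(
                    BETA_META=beta_meta,
                    SE_META=hit["SE"],
                    P_META=hit["P"],
                    N_META=hit["N"],
                    SIGN_CONSISTENT=bool(sign_ok),
                    VERDICT="replicated" if ok else "not_replicated",
                )
            rec["THRESHOLD"] = threshold
            rows.append(rec)
    return ReplicationReport(
        table=pd.DataFrame(rows),
        threshold=threshold,
        alpha=alpha,
        n_discovery_loci=n_loci,
    )


def study_thresholds(
    n_phenotypes: int | None = None,
    base: float = GENOME_WIDE_P,
    alpha: float | None = None,
    n_tests: int | None = None,
) -> float:
    """Bonferroni thresholds.

    ``study_thresholds(n_phenotypes=4)`` gives the genome-wide study-level
    bound base / n; ``study_thresholds(alpha=0.05, n_tests=m)`` the generic
    alpha / m.
    """
    if alpha is not None or n_tests is not None:
        if alpha is None or n_tests is None or n_tests < 1:
            raise ValueError("generic mode needs alpha and n_tests >= 1")
        return alpha / n_tests
    if n_phenotypes is None or n_phenotypes < 1:
        raise ValueError("n_phenotypes must be >= 1")
    return base / n_phenotypes
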