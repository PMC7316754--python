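"""End-to-end study orchestration.

Runs the full discovery -> replication flow on simulated cohorts: simulate
genotypes and traits, per-trait GWAS, LD Score regression genetic covariance,
GIP decomposition (loadings frozen at the discovery stage), GIP GWAS,
genomic-control correction with each GIP's own LDSC intercept, locus
clumping, replication meta-analysis and the Bonferroni replication gate.
Every stochastic step draws its seed from one root seed recorded in the run
manifest, so a run is reproducible bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assoc, gip, io, ldsc, postgwas, simdata
from .config import StudyConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineResult"]


@dataclass
class PipelineResult:
    """Bundle of everything a study run produces."""

    config: StudyConfig
    cov_estimate: ldsc.GeneticCovEstimate
    gip_results: gip.GipResults
    trait_sumstats: dict[str, pd.DataFrame]
    gip_sumstats_gc: dict[str, pd.DataFrame]
    gip_intercepts: dict[str, float]
    discovery_loci: dict[str, list[postgwas.Locus]]
    replication_meta: dict[str, pd.DataFrame]
    replication: postgwas.ReplicationReport | None
    pheno_corr: np.ndarray
    manifest: dict = field(default_factory=dict)

    @property
    def n_discovery_loci(self) -> int:
        return sum(len(v) for v in self.discovery_loci.values())

    @property
    def n_replicated(self) -> int:
        return 0 if self.replication is None else self.replication.n_replicated


def _spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31 from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def _simulate_cohort(cfg: StudyConfig, n: int, geno_seed: int, trait_seed: int):
    cohort = simdata.make_genotypes(n, cfg.block_spec, geno_seed)
    return simdata.simulate_traits(
        cohort, cfg.architecture, trait_seed, fixed_effects=cfg.fixed_effects
    )


def _trait_gwas(cohort: simdata.CohortData) -> dict[str, pd.DataFrame]:
    """Per-trait scans on the standardized phenotype with age/sex covariates."""
    out = {}
    for name in cohort.traits.columns:
        y = assoc.standardize(cohort.traits[name])
        out[name] = assoc.gwas_scan(cohort, y, ["age", "sex"])
    return out


def run_pipeline(cfg: StudyConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full study flow; optionally write the report bundle."""
    t0 = time.time()
    n_rep = len(cfg.replication_n)
    seeds = _spawn_seeds(cfg.seed, 3 + 2 * n_rep)
    geno_seed, trait_seed, mc_seed = seeds[:3]
    rep_seeds = seeds[3:]
    stage = "simulate-discovery"
    try:
        discovery = _simulate_cohort(cfg, cfg.discovery_n, geno_seed, trait_seed)

        stage = "trait-gwas"
        trait_ss = _trait_gwas(discovery)
        names = list(discovery.traits.columns)

        stage = "ld-scores"
        l2 = ldsc.ld_scores_empirical(
            discovery.dosages, discovery.variant_meta, cfg.ld_window_bp
        )

        stage = "ldsc-covariance"
        est = ldsc.build_cov_matrix(
            [trait_ss[n] for n in names],
            l2,
            m=cfg.block_spec.m,
            n_blocks=cfg.ldsc_blocks,
            trait_names=names,
        )

        stage = "gip-fit"
        res = gip.GipDecomposition(est).fit(ci_draws=cfg.gip_draws, seed=mc_seed)
        c_p = gip.sample_pheno_corr(discovery.traits)

        stage = "gip-gwas"
        gip_ss = gip.gip_gwas_individual(discovery, res, ["age", "sex"])

        stage = "gc-correct"
        intercepts, gip_gc = {}, {}
        for k, name in enumerate(res.gip_names):
            fit = ldsc.ldsc_univariate(
                gip_ss[k], l2, m=cfg.block_spec.m, n_blocks=cfg.ldsc_blocks
            )
            intercepts[name] = fit.intercept
            gip_gc[name] = postgwas.gc_correct(gip_ss[k], max(fit.intercept, 1e-3))

        stage = "clump"
        threshold = postgwas.study_thresholds(
            n_phenotypes=res.n_traits, base=cfg.base_threshold
        )
        loci = {
            name: postgwas.clump(gip_gc[name], "P_GC", threshold, label=name)
            for name in res.gip_names
        }

        stage = "replication"
        rep_meta: dict[str, pd.DataFrame] = {}
        if n_rep:
            rep_tables: dict[str, list[pd.DataFrame]] = {n: [] for n in res.gip_names}
            for i, n_ind in enumerate(cfg.replication_n):
                cohort = _simulate_cohort(cfg, n_ind, rep_seeds[2 * i], rep_seeds[2 * i + 1])
                # discovery loadings are frozen: scores only, never refitted
                rep_ss = gip.gip_gwas_individual(cohort, res, ["age", "sex"])
                for k, name in enumerate(res.gip_names):
                    rep_tables[name].append(rep_ss[k])
            rep_meta = {n: postgwas.ivw_meta(tabs) for n, tabs in rep_tables.items()}

        report = None
        if sum(len(v) for v in loci.values()) > 0 and rep_meta:
            report = postgwas.replication_gate(loci, rep_meta, cfg.alpha)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest = {
        "gipkit_version": __version__,
        "config": cfg.to_dict(),
        "seeds": {
            "root": cfg.seed,
            "genotypes": geno_seed,
            "traits": trait_seed,
            "monte_carlo": mc_seed,
            "replication": rep_seeds,
        },
        "thresholds": {
            "genome_wide_study": threshold,
            "replication": None if report is None else report.threshold,
        },
        "gip_intercepts": intercepts,
        "n_discovery_loci": sum(len(v) for v in loci.values()),
        "n_replicated": 0 if report is None else report.n_replicated,
        "runtime_s": round(time.time() - t0, 2),
    }

    result = PipelineResult(
        config=cfg,
        cov_estimate=est,
        gip_results=res,
        trait_sumstats=trait_ss,
        gip_sumstats_gc=gip_gc,
        gip_intercepts=intercepts,
        discovery_loci=loci,
        replication_meta=rep_meta,
        replication=report,
        pheno_corr=c_p,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _loci_table(loci: dict[str, list[postgwas.Locus]]) -> pd.DataFrame:
    rows = []
    for label, lst in loci.items():
        for locus in lst:
            lead = locus.lead
            rows.append(
                {
                    "GIP": label,
                    "SNP": lead["SNP"],
                    "CHR": lead["CHR"],
                    "POS": lead["POS"],
                    "EA": lead["EA"],
                    "OA": lead["OA"],
                    "EAF": lead.get("EAF", np.nan),
                    "BETA": lead["BETA"],
                    "SE": lead["SE"],
                    "P": lead["P"],
                    "P_GC": lead.get("P_GC", np.nan),
                    "N_MEMBERS": locus.n_members,
                    "START": locus.start,
                    "END": locus.end,
                }
            )
    cols = ["GIP", "SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "P_GC",
            "N_MEMBERS", "START", "END"]
    return pd.DataFrame(rows, columns=cols)


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    res = result.gip_results
    names = list(res.trait_names)

    lf = res.loadings_frame.copy()
    if res.loading_cis is not None:
        for k, g in enumerate(res.gip_names):
            lf[f"{g}_ci_lo"] = res.loading_cis[:, k, 0]
            lf[f"{g}_ci_hi"] = res.loading_cis[:, k, 1]
    lf.to_csv(out_dir / "loadings.tsv", sep="\t", float_format="%.10g")

    try:
        ev = pd.DataFrame(
            {"GIP": res.gip_names, "eigenvalue": res.eigenvalues,
             "explained_total": res.explained_total}
        )
    except ValueError:
        ev = pd.DataFrame(
            {"GIP": res.gip_names, "eigenvalue": res.eigenvalues,
             "explained_total": np.nan}
        )
    ev.to_csv(out_dir / "explained_variance.tsv", sep="\t", index=False,
              float_format="%.10g")

    io.write_matrix(result.cov_estimate.C_G, names, out_dir / "genetic_covariance.tsv")
    io.write_matrix(result.cov_estimate.intercepts, names, out_dir / "ldsc_intercepts.tsv")
    io.write_matrix(result.pheno_corr, names, out_dir / "pheno_corr.tsv")
    vech = ldsc.vech_indices(len(names))
    labels = [f"{names[i]}:{names[j]}" for i, j in vech]
    io.write_matrix(result.cov_estimate.J, labels, out_dir / "jackknife_cov.tsv")

    for name, tab in result.gip_sumstats_gc.items():
        io.write_sumstats(tab, out_dir / f"sumstats_{name}.tsv")
    for name, tab in result.replication_meta.items():
        io.write_sumstats(tab, out_dir / f"replication_meta_{name}.tsv")

    _loci_table(result.discovery_loci).to_csv(
        out_dir / "loci.tsv", sep="\t", index=False, float_format="%.6g"
    )
    if result.replication is not None:
        result.replication.table.to_csv(
            out_dir / "replication_report.tsv", sep="\t", index=False, float_format="%.6g"
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
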