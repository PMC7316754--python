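"""Shared fixtures: one moderate simulated study reused across test modules."""

from types import SimpleNamespace

import pytest

from gipkit import assoc, gip, ldsc, simdata


@pytest.fixture(scope="session")
def small_sim():
    """A 4-trait binary cohort with graded LD blocks, scanned and LDSC-fitted.

    n=3000, M=600 keeps this under a few seconds while leaving enough signal
    for recovery checks at 2-3 SE tolerances.
    """
    spec = simdata.BlockSpec.graded(60, 10, r_max=0.9)
    arch = simdata.TraitArchitecture.exchangeable(
        4, h2_liab=0.4, r_g=0.7, prevalence=0.15, env_corr=0.3
    )
    cohort = simdata.make_genotypes(3000, spec, seed=11)
    cohort = simdata.simulate_traits(cohort, arch, seed=12)
    names = list(cohort.traits.columns)
    tables = [
        assoc.gwas_scan(cohort, assoc.standardize(cohort.traits[t]), ["age", "sex"])
        for t in names
    ]
    l2 = ldsc.ld_scores_empirical(cohort.dosages, cohort.variant_meta)
    est = ldsc.build_cov_matrix(tables, l2, m=spec.m, n_blocks=60, trait_names=names)
    res = gip.GipDecomposition(est).fit(ci_draws=0)
    return SimpleNamespace(
        spec=spec,
        arch=arch,
        cohort=cohort,
        trait_tables=tables,
        ld_scores=l2,
        est=est,
        gip=res,
        pheno_corr=gip.sample_pheno_corr(cohort.traits),
    )
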