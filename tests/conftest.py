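"""Shared fixtures: the synthetic filtering fixture, planted family pedigrees,
and a large null-cohort study reused by calibration tests.

Everything is generated programmatically at session start from fixed seeds;
nothing is read from outside the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from rarefam import assoc
from rarefam.syndata import (
    CohortConfig,
    generate_filter_fixture,
    simulate_cohort,
    two_multicase_families,
)


def per_gene_null_pvalues(cohort, gene_names, n_pcs_scores=None):
    """Per-gene p-values (enrichment, SKAT) for a simulated cohort.

    Applies the same per-gene marker pipeline as the full runner (rare-MAF
    selection, LD pruning) but skips GC/permutation, which the calibration
    tests study separately.
    """
    gm = cohort.markers["gene"].to_numpy()
    y = cohort.y.astype(float)
    p_enr, p_skat = [], []
    for g in gene_names:
        idx = np.flatnonzero(gm == g)
        sub, maf = assoc.orient_minor(cohort.dosages[:, idx])
        sub = sub[:, (maf > 0) & (maf < 0.01)]
        if sub.shape[1] == 0:
            continue
        sub = sub[:, assoc.ld_prune(sub, None, 0.1)]
        p_enr.append(assoc.enrichment_test(assoc.burden_score(sub), y, n_pcs_scores).p)
        p_skat.append(assoc.skat_test(sub, y, n_pcs_scores).p)
    return np.asarray(p_enr), np.asarray(p_skat)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The packaged-table filtering fixture written to a temp dir."""
    outdir = tmp_path_factory.mktemp("filter_fixture")
    return generate_filter_fixture(seed=7, outdir=str(outdir))


@pytest.fixture(scope="session")
def families():
    """Planted pedigrees for the two emulated multicase families."""
    pedigrees, meta = two_multicase_families(seed=3)
    return pedigrees, meta


@pytest.fixture(scope="session")
def null_study():
    """8000 null genes from four independent homogeneous cohorts (n=3000).

    Scaled down from the study's 8.6k-sample cohort only in sample count;
    the rare-variant MAF spectrum and marker counts per gene follow the
    package defaults. Used for type-I error and genomic-control calibration.
    """
    all_enr, all_skat = [], []
    for seed in range(4):
        cfg = CohortConfig(
            n_cases=1500,
            n_controls=1500,
            n_genes=2000,
            markers_per_gene=20,
            n_background=0,
            ld_block_size=4,
            ld_copy_prob=0.9,
            seed=seed,
        )
        cohort, _ = simulate_cohort(cfg)
        pe, ps = per_gene_null_pvalues(cohort, cfg.gene_names())
        all_enr.append(pe)
        all_skat.append(ps)
    return {
        "enrichment": np.concatenate(all_enr),
        "skat": np.concatenate(all_skat),
        "first_cohort_enrichment": all_enr[0],
    }
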