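"""Shared fixtures: packaged amplicon design and reusable simulated runs."""

from __future__ import annotations

import numpy as np
import pytest

from hapmeth import pipeline, simdata


@pytest.fixture(scope="session")
def fr_design():
    """Packaged intron-enhancer amplicon: (reference, sites, catalog, truth)."""
    return simdata.fr_apopt1_klc1_like()


@pytest.fixture(scope="session")
def clean_sim(fr_design):
    """Small noise-free simulation: no errors, failures or duplicates."""
    amp, sites, catalog, truth = fr_design
    rng = np.random.default_rng(11)
    subjects = simdata.make_cohort(
        5, 5, simdata.DEFAULT_HAPLOTYPE_FREQS, rng=rng
    )
    params = simdata.SimParams(
        conversion_efficiency=1.0,
        molecule_failure_rate=0.0,
        sequencing_error_rate=0.0,
        duplication_rate=0.0,
        reads_per_subject=12,
        rng_seed=11,
    )
    reads, truth2, sheet = simdata.simulate_reads(
        subjects, amp, sites, catalog, truth, params, rng
    )
    return subjects, reads, truth2, sheet


@pytest.fixture(scope="session")
def small_run():
    """One small full-pipeline run shared by pipeline-level tests."""
    cfg = {"seed": 7, "n_cases": 6, "n_controls": 6, "reads_per_subject": 24}
    return pipeline.run_pipeline(cfg)


@pytest.fixture(scope="session")
def recovery_run():
    """Study-scale run for parameter-recovery checks: >= 40 subjects carrying
    each haplotype, default read depth and noise rates."""
    cfg = {"seed": 5, "n_cases": 48, "n_controls": 48}
    return pipeline.run_pipeline(cfg)
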