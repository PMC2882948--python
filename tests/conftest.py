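"""Shared fixtures: small deterministic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pinesnp import simdata


@pytest.fixture(scope="session")
def small_pedigree():
    """3 families: two with both parents genotyped, one with a single parent."""
    config = simdata.SimConfig(
        n_snps=40, family_spec=((2, 4), (2, 3), (1, 5)), seed=11
    )
    return config, simdata.simulate_pedigree(config)


@pytest.fixture(scope="session")
def small_genotypes(small_pedigree):
    config, pedigree = small_pedigree
    freqs = config.draw_freqs(simdata.stream_rng(config.seed, "genotypes"))
    gm, truth = simdata.simulate_genotypes(
        pedigree, freqs, seed=config.seed, n_panel=50
    )
    return pedigree, gm, truth


@pytest.fixture(scope="session")
def clean_assay():
    """Artifact-free low-noise assay: classification must be perfect."""
    return simdata.simulate_assay(
        n_samples=60,
        composition={"polymorphic": 30, "monomorphic": 10},
        seed=21,
    )
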