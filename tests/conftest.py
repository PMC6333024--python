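"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from gsbreeder import simdata


@pytest.fixture(scope="session")
def pedigree():
    return simdata.simulate_pedigree(seed=0)


@pytest.fixture(scope="session")
def clean_panel(pedigree):
    """Default population, 800 markers, no missingness or artefacts."""
    return simdata.simulate_genotypes(
        pedigree,
        n_markers=800,
        missing_rate=0.0,
        invariant_fraction=0.0,
        low_callrate_fraction=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def messy_panel(pedigree):
    """Default population with missing calls, false SNPs and bad markers."""
    return simdata.simulate_genotypes(pedigree, n_markers=1000, seed=2)


def simulate_corrected_phenotype(panel, h2, n_qtl, seed):
    """Breeding values from panel QTL plus i.i.d. noise, one value per individual.

    A direct stand-in for the LMM's corrected phenotypes, used where the
    test targets the genomic stages rather than the phenotypic model.
    Returns (phenotype Series, true breeding values).
    """
    rng = np.random.default_rng(seed)
    W = panel.genotypes
    if np.isnan(W).any():
        raise ValueError("use a clean panel for direct phenotype simulation")
    seg = np.nonzero(W.std(axis=0) > 0)[0]
    n_qtl = min(n_qtl, seg.size)
    qtl = rng.choice(seg, n_qtl, replace=False)
    bv = W[:, qtl] @ rng.standard_normal(n_qtl)
    bv = bv - bv.mean()
    if h2 > 0 and bv.std() > 0:
        bv = bv * np.sqrt(h2) / bv.std()
    else:
        bv = bv * 0.0
    noise_sd = np.sqrt(1.0 - h2) if h2 < 1 else 0.0
    y = bv + rng.normal(0.0, noise_sd, size=bv.size)
    return pd.Series(y, index=panel.individual_ids), bv
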