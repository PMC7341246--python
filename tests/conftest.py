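"""Shared fixtures: small builders plus session-scoped simulated cohorts.

The two heavy simulations (gene-drop cohort with IBD truth; constant-Ne
Wright-Fisher population) are built once per session and shared between the
module tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from herdgen.genio import GenotypeDataset, SnpInfo
from herdgen.simulate import ChromosomeSpec, SimConfig, gene_drop_genotypes, sim_pedigree


def build_dataset(calls, chrom=None, bp=None, samples=None, spacing=50_000):
    """GenotypeDataset from a raw call matrix with auto-generated map."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chrom = chrom if chrom is not None else [1] * m
    bp = bp if bp is not None else [(j + 1) * spacing for j in range(m)]
    samples = samples if samples is not None else [f"i{k}" for k in range(n)]
    snps = [SnpInfo(f"s{j}", int(chrom[j]), int(bp[j])) for j in range(m)]
    return GenotypeDataset(samples=samples, snps=snps, calls=calls)


@pytest.fixture(scope="session")
def cohort_with_truth():
    """42-animal close-kin cohort over 29 autosomes with exact IBD truth."""
    cfg = SimConfig(
        seed=2024,
        n_founders=44,
        n_generations=3,
        mating="close_kin",
        close_kin_prob=0.25,
        chrom=ChromosomeSpec(n_chrom=29, length_bp=90_000_000),
    )
    ped = sim_pedigree(cfg)
    ds, truth = gene_drop_genotypes(ped, cfg)
    last = list(ped.df[ped.df["generation"] == 3]["animal"])[:42]
    idx = [ds.samples.index(a) for a in last]
    return ds.subset(sample_idx=idx), truth, last, ped


@pytest.fixture(scope="session")
def wf_population():
    """Constant-Ne=100 Wright-Fisher sample: 50 diploids, 20 x 30 Mb."""
    from herdgen.simulate import sim_constant_ne_population

    cfg = SimConfig(
        seed=77,
        ne=100,
        sample_size=50,
        drift_generations=300,
        chrom=ChromosomeSpec(n_chrom=20, length_bp=30_000_000),
    )
    return sim_constant_ne_population(cfg)


@pytest.fixture
def toy_pedigree():
    """Five animals: two founders, two full sibs, one full-sib-mating child."""
    from herdgen.animal_model import PedigreeTable

    return PedigreeTable(
        pd.DataFrame(
            {
                "animal": ["a", "b", "c", "d", "e"],
                "sire": ["0", "0", "a", "a", "c"],
                "dam": ["0", "0", "b", "b", "d"],
            }
        )
    )
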