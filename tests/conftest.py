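"""Shared fixtures: small synthetic genomes and an end-to-end sample simulator.

All fixed-seed material uses seed 0; simulations are scaled to a 3-kb
mitochondrial genome so that full-coverage pileups stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from ccfmtdna.genome import CircularGenome
from ccfmtdna.heteroplasmy import build_pileup, call_all
from ccfmtdna.synthdata import (HeteroplasmyPlan, make_cfdna_fragments,
                                make_genomes)

SEED = 0


def next_base(b: str) -> str:
    """Deterministic alternate allele: the next base in ACGT order."""
    return "ACGT"[("ACGT".index(b) + 1) % 4]


def make_plans(genome: CircularGenome, positions, allele_fraction=0.05,
               tissue="kidney") -> list[HeteroplasmyPlan]:
    return [
        HeteroplasmyPlan(tissue, p, genome.sequence[p],
                         next_base(genome.sequence[p]), allele_fraction)
        for p in positions
    ]


def simulate_call_set(mt, nuclear, plans, tissue, n_fragments=20000,
                      error_rate=0.001, seed=SEED):
    """Simulate one sample's cfDNA and return its heteroplasmy call set."""
    records = make_cfdna_fragments(mt, nuclear, n_fragments=n_fragments,
                                   mt_fraction=1.0, plans=plans,
                                   error_rate=error_rate, seed=seed)
    pileup = build_pileup(records, mt)
    return call_all(pileup, tissue=tissue)


@pytest.fixture(scope="session")
def small_genomes():
    """A 3-kb circular mt genome and a 10-kb nuclear genome, no NUMTs."""
    return make_genomes(3000, 10000, seed=SEED)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
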