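"""Shared fixtures: synthetic genomes with planted element copies.

The heavyweight planted-genome pipelines are session-scoped so the search
runs once and is reused by mining, annotation, copy-number and acceptance
tests.
"""

from __future__ import annotations

import pytest

from mitescope import synthetic_data as syn
from mitescope.member_mining import search_members


@pytest.fixture(scope="session")
def model():
    """The 260 bp Stowaway-like consensus fixture (33 bp TIRs, TA TSD)."""
    return syn.make_consensus_fixture(seed=42)


@pytest.fixture(scope="session")
def small_planted(model):
    """200 kb genome, 20 genes, 30 exact copies (mutation rate 0)."""
    genome = syn.generate_genome(200_000, 0.6, seed=1)
    genome, genes = syn.generate_gene_models(genome, 20, seed=2)
    res = syn.plant_elements(genome, genes, model, 30,
                             mutation_rate=0.0, seed=3)
    return genome, res


@pytest.fixture(scope="session")
def planted_2mb(model):
    """2 Mb genome, 100 genes, 200 exact copies (mutation rate 0)."""
    genome = syn.generate_genome(2_000_000, 0.6, seed=11)
    genome, genes = syn.generate_gene_models(genome, 100, seed=12)
    return syn.plant_elements(genome, genes, model, 200,
                              mutation_rate=0.0, seed=13)


@pytest.fixture(scope="session")
def hits_2mb(model, planted_2mb):
    return search_members(model.consensus, planted_2mb.genome)


@pytest.fixture(scope="session")
def planted_2mb_mut(model):
    """Same study conditions as planted_2mb but 10% per-base substitutions."""
    genome = syn.generate_genome(2_000_000, 0.6, seed=11)
    genome, genes = syn.generate_gene_models(genome, 100, seed=12)
    return syn.plant_elements(genome, genes, model, 200,
                              mutation_rate=0.10, seed=14)


@pytest.fixture(scope="session")
def hits_2mb_mut(model, planted_2mb_mut):
    return search_members(model.consensus, planted_2mb_mut.genome)
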