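"""Shared toy-library fixtures: one 8-gene design chain built per session."""

import pytest

from promoswap import ElementLayout, golden_gate
from promoswap.fixtures import (
    ReadSimConfig,
    ToyGenomeSpec,
    build_toy_genome,
    make_basic_plasmid,
    make_promoter_parts,
    make_vector,
    simulate_reads,
)
from promoswap.pipeline import design_library


@pytest.fixture(scope="session")
def toy_genome():
    return build_toy_genome(ToyGenomeSpec(n_genes=8, seed=7))


@pytest.fixture(scope="session")
def toy_designs(toy_genome):
    genome, anns = toy_genome
    designs, failures = design_library(genome, anns)
    assert not failures
    return designs


@pytest.fixture(scope="session")
def toy_vector():
    return make_vector(seed=23, layout=ElementLayout())


@pytest.fixture(scope="session")
def toy_parts():
    return make_promoter_parts(6, seed=11)


@pytest.fixture(scope="session")
def toy_pool(toy_designs, toy_vector, toy_parts):
    basics = [
        make_basic_plasmid(d.element, d.arms, toy_vector)
        for d in toy_designs.values()
    ]
    return golden_gate(basics, toy_parts, include_deletion=True)


@pytest.fixture(scope="session")
def uniform_reads(toy_pool):
    cfg = ReadSimConfig(
        abundance={p.id: 1.0 for p in toy_pool.products},
        n_reads=1120,  # 20x the 56 constructs
        seed=101,
    )
    return simulate_reads(toy_pool, cfg)
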