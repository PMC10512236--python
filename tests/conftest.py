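"""Shared fixtures: one small synthetic study reused across test modules.

All data is generated at test time from the simulator; nothing is read
from disk except what the fixtures themselves write.
"""

from __future__ import annotations

import dataclasses

import pytest

from tyhybrid.hybrid import MaskSpec, build_hybrid_reference, hard_mask
from tyhybrid.simulate import (
    FamilySpec,
    SimConfig,
    generate_genomes,
    make_sample_sheet,
    simulate_counts,
    simulate_reads,
)


def small_families() -> dict:
    return {
        "Ty1": FamilySpec(parents=("p1", "p2"), n_full=2, n_solo=1,
                          internal_len=2600, ltr_len=334, mean=600.0),
        "Ty5": FamilySpec(parents=("p2",), n_full=1, n_solo=0,
                          internal_len=2600, ltr_len=334, gagless=True,
                          mean=200.0),
    }


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=17, n_genes=10, gene_len=600,
                     families=small_families())


@pytest.fixture(scope="session")
def genomes(sim_config):
    return generate_genomes(sim_config)


def _build_reference(genomes, dialect):
    masked = {
        tag: hard_mask(
            genomes.assemblies[tag],
            MaskSpec.from_te_annotations(genomes.te_records[tag]),
        )
        for tag in ("p1", "p2")
    }
    return build_hybrid_reference(
        masked["p1"], masked["p2"], genomes.combined_ty_library(), dialect,
        parent1_features=genomes.gene_features["p1"],
        parent2_features=genomes.gene_features["p2"],
    )


@pytest.fixture(scope="session")
def separate_ref(genomes):
    return _build_reference(genomes, "separate")


@pytest.fixture(scope="session")
def three_prime_ref(genomes):
    return _build_reference(genomes, "three_prime")


@pytest.fixture(scope="session")
def five_prime_ref(genomes):
    return _build_reference(genomes, "five_prime")


@dataclasses.dataclass
class SimRun:
    config: SimConfig
    genomes: object
    reference: object
    samples: object
    sim_counts: object
    reads: object


@pytest.fixture(scope="session")
def ds2_run(tmp_path_factory, sim_config, genomes, separate_ref) -> SimRun:
    """A reverse-stranded paired-end study: 3 parent1 + 3 parent2 + 3 hybrid."""
    out = tmp_path_factory.mktemp("ds2")
    samples = make_sample_sheet(sim_config)
    sim_counts = simulate_counts(sim_config, genomes, samples)
    reads = simulate_reads(sim_config, separate_ref, sim_counts.counts,
                           genomes, out, dialect="separate")
    return SimRun(sim_config, genomes, separate_ref, samples, sim_counts, reads)


@pytest.fixture(scope="session")
def ds1_run(tmp_path_factory, sim_config, genomes, three_prime_ref) -> SimRun:
    """A 3'-end paired-end study on the internal+3'LTR reference."""
    out = tmp_path_factory.mktemp("ds1")
    samples = make_sample_sheet(sim_config, library="three_prime_PE")
    sim_counts = simulate_counts(sim_config, genomes, samples)
    reads = simulate_reads(sim_config, three_prime_ref, sim_counts.counts,
                           genomes, out, dialect="three_prime")
    return SimRun(sim_config, genomes, three_prime_ref, samples, sim_counts,
                  reads)


@pytest.fixture(scope="session")
def rpf_run(tmp_path_factory, sim_config, genomes, five_prime_ref) -> SimRun:
    """Single-end ribosome-protected fragments on the 5'LTR+internal layout."""
    out = tmp_path_factory.mktemp("rpf")
    samples = make_sample_sheet(sim_config, groups=("p1", "hybrid"),
                                library="rpf_SE")
    sim_counts = simulate_counts(sim_config, genomes, samples)
    reads = simulate_reads(sim_config, five_prime_ref, sim_counts.counts,
                           genomes, out, dialect="five_prime", library="rpf_SE")
    return SimRun(sim_config, genomes, five_prime_ref, samples, sim_counts,
                  reads)
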