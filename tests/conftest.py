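import numpy as np
import pytest

from pulloop.annotations_io import GeneRecord, GenomeAnnotation
from pulloop.susd_typer import default_profile
from pulloop.synthetic_data import SimConfig, simulate_genomes


def contig_from_spec(specs, genome_id="T"):
    """Compact contig builder for hand-worked examples.

    Each spec is a dict with optional keys: role ('susC'/'susD'/'susE'),
    fam (one CAZy token), ko, strand (default '+'), start/end (default
    consecutive 1 kb genes).
    """
    genes = []
    cursor = 1
    for i, spec in enumerate(specs):
        start = spec.get("start", cursor)
        end = spec.get("end", start + 999)
        genes.append(
            GeneRecord(
                genome_id=genome_id,
                contig_id="c1",
                gene_index=i,
                start=start,
                end=end,
                strand=spec.get("strand", "+"),
                locus_tag=f"{genome_id}_{i:04d}",
                cazy_families=frozenset([spec["fam"]] if "fam" in spec else []),
                k_numbers=frozenset([spec["ko"]] if "ko" in spec else []),
                sus_role=spec.get("role", "none"),
            )
        )
        cursor = end + 101
    return GenomeAnnotation(genome_id=genome_id, contigs={"c1": genes})


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def small_cohort():
    """Five simulated genomes with full truth; shared across tests."""
    config = SimConfig(seed=11, n_genomes=5)
    annotations, truth = simulate_genomes(config)
    return config, annotations, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
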