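import numpy as np
import pytest

from introscan.alignment import GenomeAlignment, seq_to_array
from introscan.simulate import Centromere, SimulationConfig, simulate_dataset


def make_alignment(seqs: dict[str, str], chrom: str = "chr1",
                   space: str = "trimmed") -> GenomeAlignment:
    """Build a one-chromosome alignment from literal sequences."""
    arr = np.stack([seq_to_array(s) for s in seqs.values()])
    return GenomeAlignment(list(seqs), {chrom: arr}, coordinate_space=space)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study-like scenario: 2 Mbp mat chromosome with a
    1.2 Mbp elevated central region and a 1 Mbp introgression tract."""
    return SimulationConfig(
        seed=11,
        chromosome_lengths={"LGI": 2_000_000, "LGII": 300_000},
        central_region=(400_000, 1_600_000),
        tract=(500_000, 1_500_000),
        centromere=Centromere(1_700_000, 1_800_000),
        n_genes=40,
        n_autosome_genes=10,
        gene_length_codons=100,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_trimmed(small_dataset):
    from introscan.alignment import remove_gap_columns

    return remove_gap_columns(small_dataset.alignment)


@pytest.fixture(scope="session")
def tiny_sim_overrides() -> dict:
    """Fast simulation block for pipeline-level tests."""
    return {
        "chromosome_lengths": {"LGI": 1_000_000},
        "central_region": [300_000, 800_000],
        "tract": [400_000, 700_000],
        "centromere": {"start": 850_000, "end": 900_000},
        "n_genes": 10,
        "n_autosome_genes": 0,
        "gene_length_codons": 100,
    }
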