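import numpy as np
import pytest

from corepart import LocusAlignment, SimConfig, simulate_locus, simulate_tree

FLAT_PROFILE = {
    "core": 1.0, "flank1": 1.0, "flank2": 1.0,
    "flank3": 1.0, "flank4": 1.0, "flank5": 1.0,
}


@pytest.fixture
def small_alignment() -> LocusAlignment:
    return LocusAlignment(
        "uce-1",
        ["t1", "t2", "t3", "t4"],
        ["ACGTACGT", "ACGTACGA", "GCTTACGT", "GCTAACGA"],
    )


@pytest.fixture
def yule_tree():
    """Seeded 6-taxon ultrametric tree reused across tests."""
    return simulate_tree(6, seed=11, tree_height=0.15)


def flat_config(**overrides) -> SimConfig:
    """Simulation config with a rate-homogeneous profile (no core/flank
    structure) unless overridden."""
    defaults = dict(
        n_taxa=6,
        locus_length_range=(400, 400),
        tree_height=0.15,
        flank_rate_profile=dict(FLAT_PROFILE),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def write_fasta(path, aln: LocusAlignment) -> None:
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.seqs):
            fh.write(f">{taxon}\n{seq}\n")
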