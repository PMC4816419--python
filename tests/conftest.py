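import pytest

from asplice.aligner import AlignParams, KmerIndex, align_pairs
from asplice.simgen import SimParams, generate_dataset
from asplice.splicefinder import JunctionParams, call_junctions


def clean_sim_params(**overrides) -> SimParams:
    """A small noise-free single-library experiment with every event active."""
    kwargs = dict(
        n_genes=40, n_chromosomes=1, chrom_length=170_000,
        intron_length=(50, 2000), depth=40.0,
        error_rate=0.0, adapter_rate=0.0, n_rate=0.0,
        n_varieties=1, timepoints=("24h",), event_active_prob=1.0,
        seed=7,
    )
    kwargs.update(overrides)
    return SimParams(**kwargs)


@pytest.fixture(scope="session")
def small_sim():
    return generate_dataset(clean_sim_params())


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Alignment and junction calls for the small clean simulation."""
    pairs = small_sim.libraries["V1_24h"]
    index = KmerIndex(small_sim.chrom_seqs, 32)
    alignments, ium = align_pairs(pairs, index, AlignParams())
    jparams = JunctionParams(max_intron=small_sim.params.intron_length[1])
    index9 = KmerIndex(small_sim.chrom_seqs, jparams.anchor)
    junctions = call_junctions(ium, index9, jparams)
    return {
        "sim": small_sim, "index": index, "index9": index9,
        "alignments": alignments, "ium": ium, "junctions": junctions,
        "jparams": jparams,
    }
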