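import numpy as np
import pytest

import tedetect as td


@pytest.fixture(scope="session")
def config() -> td.PipelineConfig:
    return td.PipelineConfig()


@pytest.fixture(scope="session")
def library() -> list[td.TEConsensus]:
    return td.default_te_library()


@pytest.fixture(scope="session")
def library_index(library) -> td.TELibraryIndex:
    return td.TELibraryIndex(library)


@pytest.fixture(scope="session")
def tiny_sample() -> td.SimulatedSample:
    """A small but complete simulated sample shared across fast tests
    (500 kb genome, 2 INSIDER + 25 OUTSIDER insertions, 60x reads)."""
    recipe = td.desk_recipe(seed=3, scale=40, genome_length=500_000)
    return td.simulate_sample(recipe)


@pytest.fixture(scope="session")
def desk_sample() -> td.SimulatedSample:
    """The scaled benchmark sample: 2 Mb genome, 10 INSIDER + 100 OUTSIDER
    insertions, 10x/45x/5x depth mix, 2% read error."""
    return td.simulate_sample(td.desk_recipe(seed=1))


@pytest.fixture(scope="session")
def desk_calls(desk_sample, config):
    """Both detection tracks run on the desk benchmark sample."""
    s = desk_sample
    ref = {s.base.id: s.base}
    asm = {s.assembly.id: s.assembly}
    insider = td.call_insider(ref, asm, s.library, s.genome_alignment, config)
    outsider = td.call_outsider(asm, s.reads, s.library, s.alignments, config)
    return insider, outsider


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))
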