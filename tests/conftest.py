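import numpy as np
import pytest

from advdsrna.model import GenomeModel, TranscriptionUnit, build_genome
from advdsrna.sim_reads import SimConfig


@pytest.fixture(scope="session")
def minimal_model() -> GenomeModel:
    return build_genome("minimal")


@pytest.fixture(scope="session")
def ad5_model() -> GenomeModel:
    return build_genome("ad5_like")


@pytest.fixture
def small_cfg() -> SimConfig:
    return SimConfig(seed=7, n_molecules=2000, n_reads=4000)


def single_intron_model(splice_eff: float) -> GenomeModel:
    """One top-strand unit with one intron; no antisense partner, no read-through."""
    unit = TranscriptionUnit(
        unit_id="U1",
        strand="+",
        exons=((100, 1100), (1600, 2600)),
        polya_site=2600,
        expression_weight=1.0,
        intron_splice_eff=(splice_eff,),
        polya_readthrough_prob=0.0,
    )
    return GenomeModel(genome_id="single_intron", length=3000, units=(unit,))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
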