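import numpy as np
import pytest

from orthopeaks import synthetic_data as sd
from orthopeaks.chain_lift import ChainAlignment
from orthopeaks.genome_model import GenomeInterval, Peak


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_chain():
    """Single 1000 bp block mapping chrT onto chrQ one-to-one."""
    return ChainAlignment(
        score=100, t_name="chrT", t_size=1000, t_strand="+", t_start=0, t_end=1000,
        q_name="chrQ", q_size=1000, q_strand="+", q_start=0, q_end=1000,
        blocks=[(1000, 0, 0)], chain_id=1,
    )


@pytest.fixture
def gapped_chain():
    """Blocks (100, dt=50, dq=0)(100): target span 250, query span 200."""
    return ChainAlignment(
        score=100, t_name="chrT", t_size=1000, t_strand="+", t_start=0, t_end=250,
        q_name="chrQ", q_size=1000, q_strand="+", q_start=0, q_end=200,
        blocks=[(100, 50, 0), (100, 0, 0)], chain_id=1,
    )


@pytest.fixture(scope="session")
def small_genome():
    """A small two-species genome pair shared by slower tests."""
    cfg = sd.SyntheticConfig(
        n_chromosomes=2, chrom_length=4_000_000, n_genes=300,
        tf_panel={"GATA1": sd.TFConfig(n_peaks=200, n_gain=100)},
        cooccupancy=sd.CoOccupancyConfig(n_triple=60, n_pair=90, n_single=120),
    )
    rng = np.random.default_rng(777)
    genome = sd.generate_genome_pair(cfg, rng)
    return cfg, genome, rng


def make_peak(chrom, start, end, summit=None, score=0.0, factor=""):
    summit = (start + end) // 2 if summit is None else summit
    return Peak(GenomeInterval(chrom, start, end), summit, score, factor=factor)


def lift_base_oracle(chain, start, end):
    """Brute force: map each base independently; return (fraction, span)."""
    images = [chain.map_base(t) for t in range(start, end)]
    images = [q for q in images if q is not None]
    if not images:
        return 0.0, None
    return len(images) / (end - start), (min(images), max(images) + 1)
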