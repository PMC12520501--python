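import numpy as np
import pytest

from hemimeth import simulate as sim


@pytest.fixture(scope="session")
def small_genome():
    cfg = sim.GenomeConfig(
        chrom_lengths={"chr1": 30_000, "chr2": 20_000}, spike_in_length=2_000
    )
    return sim.make_genome(cfg, seed=11)


@pytest.fixture(scope="session")
def small_chromatin(small_genome):
    return sim.simulate_chromatin(small_genome, sim.ChromatinConfig(), seed=12)


@pytest.fixture(scope="session")
def flat_chromatin(small_genome):
    """All-euchromatic chromatin (uniform region class)."""
    return sim.simulate_chromatin(
        small_genome, sim.ChromatinConfig(het_fraction=0.0), seed=13
    )


def uniform_replication_params(q=0.4, e=0.8, d=0.0, *, e_ccg=None, **kw):
    """Replication-mode parameters identical across regions."""
    e_ccg = e if e_ccg is None else e_ccg
    return sim.MethylationParams(
        contexts={
            "CG": sim.ContextParams((q, q), (e, e), d),
            "CWG": sim.ContextParams((q, q), (e, e), d),
            "CWWG": sim.ContextParams((q, q), (e, e), d),
            "CCG": sim.ContextParams((q, q), (e_ccg, e_ccg), d),
        },
        mode="replication",
        **kw,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
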