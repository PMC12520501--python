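"""Shared study conditions for the analysis scripts.

One synthetic Arabidopsis-like scenario is used throughout: a 400-kb
genome plus an unmethylated spike-in, pericentromere-like heterochromatic
blocks carrying high H3K9me2, phased nucleosomes, and two hpBS-seq-like
samples — a wildtype with efficient CG/CWG maintenance and a MET1-loss
line with CG maintenance knocked out.
"""

from pathlib import Path

import pandas as pd

from hemimeth import dyads as dy
from hemimeth import simulate as sim

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7
N_MOLECULES = 50_000  # ~19x mean dyad coverage on a 400-kb genome

GENOME_CFG = sim.GenomeConfig(
    chrom_lengths={"chr1": 400_000}, spike_in_length=5_000
)
CHROMATIN_CFG = sim.ChromatinConfig()

OBS = sim.ObservationParams(
    conversion_rate=0.995, overconversion_rate=0.002, miss_rate=0.02, seed=SEED
)


def wildtype_params() -> sim.MethylationParams:
    p = sim.default_params()
    p.lineage_spread = 0.5
    return p


def met1_params() -> sim.MethylationParams:
    """MET1 loss: CG (and CCG-pathway) maintenance and parental CG marks gone."""
    return sim.MethylationParams(
        contexts={
            "CG": sim.ContextParams((0.01, 0.02), (0.05, 0.05), 0.002),
            "CWG": sim.ContextParams((0.04, 0.50), (0.87, 0.60), 0.005),
            "CWWG": sim.ContextParams((0.01, 0.10), (0.05, 0.05), 0.02),
            "CCG": sim.ContextParams((0.01, 0.02), (0.05, 0.05), 0.002),
        },
        mode="replication",
        nucleosome_shield=0.7,
        lineage_spread=0.5,
    )


def build_scenario():
    genome = sim.make_genome(GENOME_CFG, seed=SEED)
    chromatin = sim.simulate_chromatin(genome, CHROMATIN_CFG, seed=SEED + 1)
    sites, csg = dy.find_dyads(genome)
    return genome, chromatin, sites, csg


def sample_calls(genome, chromatin, params, seed_offset=0):
    pop = sim.simulate_population(
        genome, chromatin, params, N_MOLECULES, seed=SEED + 10 + seed_offset
    )
    obs = sim.ObservationParams(
        conversion_rate=OBS.conversion_rate,
        overconversion_rate=OBS.overconversion_rate,
        miss_rate=OBS.miss_rate,
        seed=SEED + 20 + seed_offset,
    )
    calls = sim.emit_call_table(pop, obs)
    return pop, calls


def write(df: pd.DataFrame, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    print(f"  wrote {path.relative_to(RESULTS.parent)}")
    return path
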