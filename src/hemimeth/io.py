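"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA via Biopython; call tables, dyad counts, BED and bedGraph as TSV
through pandas.  All writers accept a plain or ``.gz`` path.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CALL_COLUMNS = ["molecule_id", "chrom", "pos", "strand", "state"]


def write_fasta(genome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, spike_in_chrom: str | None = None):
    from .simulate import GenomeSequence

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSequence(sequences=seqs, spike_in_chrom=spike_in_chrom)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"state": str})
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call table lacks columns: {sorted(missing)}")
    return df


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, comment="#", names=list(names))


def write_bed(df: pd.DataFrame, path, cols=("chrom", "start", "end")) -> None:
    df[list(cols)].to_csv(path, sep="\t", index=False, header=False)


def write_dyad_bed(dyads: pd.DataFrame, path) -> None:
    """Dyad sites as BED4: the interval spans both member cytosines."""
    df = dyads.assign(end=dyads["partner_pos"] + 1)
    write_bed(df, path, cols=("chrom", "pos", "end", "context"))


def read_bedgraph(path) -> pd.DataFrame:
    return read_bed(path, names=("chrom", "start", "end", "value"))


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"]))


def read_centers_bed(path) -> dict:
    """Nucleosome centers from a BED of center intervals (midpoint taken)."""
    import numpy as np

    df = read_bed(path)
    out = {}
    for chrom, grp in df.groupby("chrom"):
        mid = ((grp["start"] + grp["end"]) // 2).to_numpy()
        out[chrom] = np.sort(mid)
    return out


def load_config(path) -> dict:
    """Generator configuration from a YAML file (keys mirror the dataclasses)."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def params_from_config(cfg: dict):
    """Build (GenomeConfig, ChromatinConfig, MethylationParams, ObservationParams)."""
    from . import simulate as sim

    genome = sim.GenomeConfig(**cfg.get("genome", {}))
    chromatin = sim.ChromatinConfig(**cfg.get("chromatin", {}))
    meth_cfg = cfg.get("methylation")
    if meth_cfg is None:
        meth = sim.default_params()
    else:
        contexts = {
            name: sim.ContextParams(
                site_meth_prob=tuple(c["site_meth_prob"]),
                maintenance_eff=tuple(c["maintenance_eff"]),
                de_novo_rate=c.get("de_novo_rate", 0.0),
            )
            for name, c in meth_cfg["contexts"].items()
        }
        meth = sim.MethylationParams(
            contexts=contexts,
            mode=meth_cfg.get("mode", "replication"),
            nucleosome_shield=meth_cfg.get("nucleosome_shield", 1.0),
        )
    obs = sim.ObservationParams(**cfg.get("observation", {}))
    return genome, chromatin, meth, obs


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
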