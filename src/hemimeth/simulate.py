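"""Synthetic hairpin-bisulfite methylome generator.

Emulates the biology the downstream analyses assume: a population of
double-stranded DNA molecules whose cytosine dyads acquire methylation
through DNA replication (nascent strand born unmethylated), probabilistic
maintenance methylation (context- and region-class-specific efficiency,
attenuated under nucleosomes), and *de novo* deposition; observation adds
bisulfite conversion failure and missing calls.  A spike-in chromosome
(lambda analog) is always truly unmethylated so the conversion-rate
estimator can be tested against its own inversion.

Two generators are provided:

* the molecule-level model (:func:`simulate_population` +
  :func:`emit_call_table`), the ground-truth path for the dyad caller,
  strand-concordance and nucleosome-profile analyses;
* a count-level sampler (:func:`simulate_binned_dyads`) that draws
  per-dyad status counts directly from the full/hemi/unme probabilities
  the molecule model implies, for bin-scale calibration studies (thousands
  of 1-kb bins) where simulating individual molecules adds nothing.

All stages are deterministic for a fixed seed; per-stage generators are
derived from a single seed via ``numpy`` spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dyads import find_dyads

EU, HET = 0, 1
REGION_NAMES = {EU: "euchromatic", HET: "heterochromatic"}

#: nucleosome half-footprint in bp (147-bp core)
NUC_HALF = 73

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# genome


@dataclass
class GenomeSequence:
    """Chromosome sequences plus an optional unmethylated spike-in."""

    sequences: dict[str, str]
    spike_in_chrom: str | None = None

    def __post_init__(self):
        for chrom, seq in self.sequences.items():
            if set(seq.upper()) - set("ACGT"):
                raise ValueError(f"chromosome {chrom} contains non-ACGT characters")
        if self.spike_in_chrom is not None and self.spike_in_chrom not in self.sequences:
            raise ValueError("spike_in_chrom is not one of the chromosome names")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def main_chroms(self) -> list[str]:
        return [c for c in self.sequences if c != self.spike_in_chrom]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class GenomeConfig:
    """Parameters for i.i.d. weighted base sampling.

    ``base_weights`` set the per-position base distribution, hence the
    expected motif densities in closed form (e.g. the per-position CG-dyad
    density is ``p_C * p_G``).
    """

    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 200_000})
    base_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}
    )
    spike_in_length: int = 0
    spike_in_name: str = "lambda_spike"


def make_genome(config: GenomeConfig, seed: int) -> GenomeSequence:
    """Sample a genome by i.i.d. weighted base draws; append spike-in if asked."""
    w = np.array([config.base_weights.get(b, 0.0) for b in "ACGT"], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("base weights must be non-negative with positive sum")
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    lengths = dict(config.chrom_lengths)
    if config.spike_in_length:
        if config.spike_in_length < 1000:
            raise ValueError("spike-in length must be at least 1 kb")
        lengths[config.spike_in_name] = config.spike_in_length
    for chrom, length in lengths.items():
        if length < 1000:
            raise ValueError(f"chromosome {chrom} length {length} below 1 kb minimum")
        idx = rng.choice(4, size=length, p=p)
        seqs[chrom] = _BASES[idx].tobytes().decode("ascii")
    spike = config.spike_in_name if config.spike_in_length else None
    return GenomeSequence(sequences=seqs, spike_in_chrom=spike)


# ---------------------------------------------------------------------------
# chromatin


@dataclass
class ChromatinState:
    """Per-bin H3K9me2 and region class, plus nucleosome center positions."""

    bin_size: int
    h3k9me2: dict[str, np.ndarray]
    region_class: dict[str, np.ndarray]  # int8 arrays of EU/HET per bin
    nucleosome_centers: dict[str, np.ndarray]

    def region_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        bins = np.asarray(pos) // self.bin_size
        classes = self.region_class.get(chrom)
        if classes is None:
            return np.zeros(len(np.atleast_1d(bins)), dtype=np.int8)
        return classes[np.clip(bins, 0, len(classes) - 1)]

    def track_frame(self) -> pd.DataFrame:
        """H3K9me2 enrichment as a binned track DataFrame."""
        rows = []
        for chrom, vals in self.h3k9me2.items():
            starts = np.arange(len(vals)) * self.bin_size
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": starts + self.bin_size,
                        "value": vals,
                        "blacklisted": False,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class ChromatinConfig:
    bin_size: int = 1000
    het_fraction: float = 0.4
    het_block_bins: int = 50
    eu_h3k9me2_scale: float = 0.06  # exponential mean, mostly below the 0.1 cutoff
    het_h3k9me2_offset: float = 5.0
    het_h3k9me2_scale: float = 4.0
    nuc_spacing: int = 180
    nuc_jitter: int = 10


def simulate_chromatin(
    genome: GenomeSequence, config: ChromatinConfig, seed: int
) -> ChromatinState:
    """Assign contiguous heterochromatic blocks, H3K9me2 levels and nucleosomes.

    Heterochromatic bins draw H3K9me2 from an offset exponential (high
    values), euchromatic bins from a low exponential; nucleosome centers
    are laid down at ``nuc_spacing`` plus integer jitter in
    ``[-nuc_jitter, +nuc_jitter]``.
    """
    if config.bin_size <= 0:
        raise ValueError("bin size must be positive")
    if config.nuc_spacing <= 2 * NUC_HALF:
        raise ValueError("nucleosome spacing must exceed the 147-bp footprint")
    if not 0 <= config.het_fraction <= 1:
        raise ValueError("het_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h3k9me2, region_class, centers = {}, {}, {}
    for chrom in genome.main_chroms:
        length = len(genome.sequences[chrom])
        n_bins = -(-length // config.bin_size)
        # contiguous blocks, marked heterochromatic until the bin quota is met
        n_blocks = -(-n_bins // config.het_block_bins)
        quota = int(round(config.het_fraction * n_bins))
        classes = np.zeros(n_bins, dtype=np.int8)
        for b in rng.permutation(n_blocks):
            if quota <= 0:
                break
            lo_b = b * config.het_block_bins
            hi_b = min(lo_b + min(config.het_block_bins, quota), n_bins)
            quota -= hi_b - lo_b
            classes[lo_b:hi_b] = HET
        vals = rng.exponential(config.eu_h3k9me2_scale, size=n_bins)
        het_vals = config.het_h3k9me2_offset + rng.exponential(
            config.het_h3k9me2_scale, size=n_bins
        )
        vals = np.where(classes == HET, het_vals, vals)
        region_class[chrom] = classes
        h3k9me2[chrom] = vals

        pos = np.arange(config.nuc_spacing // 2, length, config.nuc_spacing)
        if config.nuc_jitter:
            pos = pos + rng.integers(
                -config.nuc_jitter, config.nuc_jitter + 1, size=pos.size
            )
        pos = np.unique(np.clip(pos, 0, length - 1))
        centers[chrom] = pos
    return ChromatinState(
        bin_size=config.bin_size,
        h3k9me2=h3k9me2,
        region_class=region_class,
        nucleosome_centers=centers,
    )


def occupancy_arrays(
    chromatin: ChromatinState, genome: GenomeSequence
) -> dict[str, np.ndarray]:
    """Boolean per-base nucleosome occupancy (within 73 bp of a center)."""
    occ = {}
    for chrom in genome.main_chroms:
        length = len(genome.sequences[chrom])
        a = np.zeros(length, dtype=bool)
        for c in chromatin.nucleosome_centers.get(chrom, ()):
            a[max(0, c - NUC_HALF) : c + NUC_HALF + 1] = True
        occ[chrom] = a
    return occ


# ---------------------------------------------------------------------------
# methylation parameters


@dataclass
class ContextParams:
    """Per-context methylation parameters, split by region class (eu, het)."""

    site_meth_prob: tuple[float, float]  # q: parental-strand 5mC probability
    maintenance_eff: tuple[float, float]  # E: hemi -> full conversion probability
    de_novo_rate: float = 0.0  # d: per-strand de novo probability

    def validate(self, name):
        for v in (*self.site_meth_prob, *self.maintenance_eff, self.de_novo_rate):
            if not 0 <= v <= 1:
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")


@dataclass
class MethylationParams:
    """Replication-coupled methylation model parameters.

    ``mode="replication"``: per molecule a template strand is chosen
    uniformly; template cytosines carry 5mC with probability ``q``; each
    dyad whose template member is methylated has its nascent member
    methylated with probability ``E * (s if under a nucleosome else 1)``;
    remaining unmethylated cytosines gain de novo 5mC with probability
    ``d``.  ``mode="independent"`` methylates every cytosine independently
    with probability ``q`` (the stochastic null).
    """

    contexts: dict[str, ContextParams]
    mode: str = "replication"
    nucleosome_shield: float = 1.0  # multiplies E under a nucleosome
    #: same-strand parental correlation: per molecule the template strand's
    #: q is scaled by 1-spread or 1+spread (methylation-poor vs -rich
    #: lineage), modelling that a parental strand inherited its marks as a
    #: unit through earlier replication rounds.  0 disables the factor.
    lineage_spread: float = 0.0

    def __post_init__(self):
        if self.mode not in ("replication", "independent"):
            raise ValueError("mode must be 'replication' or 'independent'")
        if not 0 <= self.nucleosome_shield <= 1:
            raise ValueError("nucleosome_shield must be in [0, 1]")
        if not 0 <= self.lineage_spread <= 1:
            raise ValueError("lineage_spread must be in [0, 1]")
        for name, cp in self.contexts.items():
            cp.validate(name)

    def q_table(self):
        return _param_table(self.contexts, lambda cp: cp.site_meth_prob)

    def e_table(self):
        return _param_table(self.contexts, lambda cp: cp.maintenance_eff)

    def d_table(self):
        return _param_table(self.contexts, lambda cp: (cp.de_novo_rate,) * 2)


_CTX_CODE = {"CG": 0, "CWG": 1, "CWWG": 2, "CCG": 3, "other": 4}


def _param_table(contexts, getter):
    tab = np.zeros((5, 2))
    for name, cp in contexts.items():
        tab[_CTX_CODE[name]] = getter(cp)
    return tab


def default_params() -> MethylationParams:
    """Col-0-like defaults: efficient CG/CWG maintenance, stochastic CWWG.

    Parental methylation probabilities put most 5mC in heterochromatin
    (pericentromere-like blocks); maintenance is high for CG, slightly
    lower for CWG, weaker for CCG, and essentially absent for CWWG whose
    full-methylation arises from independent de novo events.
    """
    return MethylationParams(
        contexts={
            "CG": ContextParams((0.15, 0.85), (0.93, 0.88), 0.005),
            "CWG": ContextParams((0.04, 0.50), (0.87, 0.80), 0.005),
            "CWWG": ContextParams((0.01, 0.10), (0.05, 0.05), 0.02),
            # CSG maintenance through the CHG pathway is inefficient after
            # replication, so the CCG-dyad efficiency sits well below CG/CWG
            "CCG": ContextParams((0.04, 0.50), (0.20, 0.30), 0.005),
        },
        mode="replication",
        nucleosome_shield=0.7,
    )


def independent_params(q: float | dict[str, float]) -> MethylationParams:
    """Stochastic-null parameters: every cytosine i.i.d. methylated."""
    if not isinstance(q, dict):
        q = {name: q for name in ("CG", "CWG", "CWWG", "CCG")}
    return MethylationParams(
        contexts={
            name: ContextParams((qq, qq), (0.0, 0.0), 0.0) for name, qq in q.items()
        },
        mode="independent",
    )


# ---------------------------------------------------------------------------
# molecule population


@dataclass
class MoleculeSet:
    """Ground-truth molecule population.

    ``molecules``: one row per molecule (``molecule_id, chrom, start, end,
    template_strand``); ``truth``: one row per simulated cytosine on either
    strand of a molecule (``molecule_id, chrom, pos, strand, context,
    meth``).  Only dyad-member cytosines are modelled on the main
    chromosomes (the analyses consume nothing else); on the spike-in every
    cytosine of both strands is carried, always unmethylated.
    """

    molecules: pd.DataFrame
    truth: pd.DataFrame


@dataclass
class _ChromSites:
    cyt_pos: np.ndarray
    cyt_strand: np.ndarray  # 0 = W, 1 = C
    cyt_ctx: np.ndarray
    dyad_pos: np.ndarray
    dyad_partner: np.ndarray
    dyad_ctx: np.ndarray
    dyad_w_idx: np.ndarray  # indices into the cytosine arrays
    dyad_c_idx: np.ndarray


def _chrom_sites(genome: GenomeSequence) -> dict[str, _ChromSites]:
    dyads, _ = find_dyads(genome)
    out = {}
    for chrom in genome.chrom_names:
        if chrom == genome.spike_in_chrom:
            arr = np.frombuffer(
                genome.sequences[chrom].upper().encode(), dtype=np.uint8
            )
            w_pos = np.flatnonzero(arr == ord("C"))
            c_pos = np.flatnonzero(arr == ord("G"))
            pos = np.concatenate([w_pos, c_pos])
            strand = np.concatenate(
                [np.zeros(w_pos.size, np.int8), np.ones(c_pos.size, np.int8)]
            )
            order = np.lexsort((strand, pos))
            out[chrom] = _ChromSites(
                cyt_pos=pos[order],
                cyt_strand=strand[order],
                cyt_ctx=np.full(pos.size, _CTX_CODE["other"], np.int8),
                dyad_pos=np.empty(0, np.int64),
                dyad_partner=np.empty(0, np.int64),
                dyad_ctx=np.empty(0, np.int8),
                dyad_w_idx=np.empty(0, np.int64),
                dyad_c_idx=np.empty(0, np.int64),
            )
            continue
        d = dyads[dyads["chrom"] == chrom]
        w_ctx = d["w_ctx"].map(_CTX_CODE).to_numpy(np.int8)
        c_ctx = d["c_ctx"].map(_CTX_CODE).to_numpy(np.int8)
        members = pd.DataFrame(
            {
                "pos": np.concatenate([d["pos"].to_numpy(), d["partner_pos"].to_numpy()]),
                "strand": np.concatenate(
                    [np.zeros(len(d), np.int8), np.ones(len(d), np.int8)]
                ),
                "ctx": np.concatenate([w_ctx, c_ctx]),
            }
        )
        cyts = members.drop_duplicates(["pos", "strand"]).sort_values(
            ["pos", "strand"], kind="stable"
        )
        # a shared cytosine (CSG C3) must carry one context; CG wins by
        # construction since member contexts agree wherever they overlap
        key = cyts["pos"].to_numpy() * 2 + cyts["strand"].to_numpy()
        w_key = d["pos"].to_numpy() * 2 + 0
        c_key = d["partner_pos"].to_numpy() * 2 + 1
        out[chrom] = _ChromSites(
            cyt_pos=cyts["pos"].to_numpy(np.int64),
            cyt_strand=cyts["strand"].to_numpy(np.int8),
            cyt_ctx=cyts["ctx"].to_numpy(np.int8),
            dyad_pos=d["pos"].to_numpy(np.int64),
            dyad_partner=d["partner_pos"].to_numpy(np.int64),
            dyad_ctx=d["context"].map(_CTX_CODE).to_numpy(np.int8),
            dyad_w_idx=np.searchsorted(key, w_key),
            dyad_c_idx=np.searchsorted(key, c_key),
        )
    return out


def simulate_population(
    genome: GenomeSequence,
    chromatin: ChromatinState,
    params: MethylationParams,
    n_molecules: int,
    seed: int,
    *,
    fragment_length_range: tuple[int, int] = (100, 200),
) -> MoleculeSet:
    """Draw a population snapshot of double-stranded molecules.

    One replication + maintenance + de novo pass per molecule (the
    population-snapshot approximation of steady state).  Fragment lengths
    are uniform in ``fragment_length_range`` (sonication to 100-200 bp).
    In replication mode every maintenance-failure hemi dyad carries its
    5mC on the molecule's template strand.
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    lo, hi = fragment_length_range
    if not 0 < lo <= hi:
        raise ValueError("invalid fragment length range")

    rng = np.random.default_rng([seed, 0x5EED])
    sites = _chrom_sites(genome)
    q_tab, e_tab, d_tab = params.q_table(), params.e_table(), params.d_table()
    occ = occupancy_arrays(chromatin, genome)

    chroms = genome.chrom_names
    lengths = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_molecules, p=lengths / lengths.sum())
    frag_len = rng.integers(lo, hi + 1, size=n_molecules)
    frag_len = np.minimum(frag_len, lengths[chrom_idx].astype(np.int64))
    start = (rng.random(n_molecules) * (lengths[chrom_idx] - frag_len + 1)).astype(
        np.int64
    )
    end = start + frag_len
    template = rng.integers(0, 2, size=n_molecules).astype(np.int8)  # 0=W, 1=C

    mol_frames, truth_frames = [], []
    for ci, chrom in enumerate(chroms):
        mask = chrom_idx == ci
        if not mask.any():
            continue
        mol_ids = np.flatnonzero(mask)
        s, e = start[mask], end[mask]
        tmpl = template[mask]
        cs = sites[chrom]
        spike = chrom == genome.spike_in_chrom

        # cytosines per molecule (long form)
        lo_i = np.searchsorted(cs.cyt_pos, s, side="left")
        hi_i = np.searchsorted(cs.cyt_pos, e, side="left")
        n_per = hi_i - lo_i
        mol_row = np.repeat(np.arange(mol_ids.size), n_per)
        cyt_idx = _ranges(lo_i, hi_i)
        offsets = np.zeros(mol_ids.size + 1, dtype=np.int64)
        np.cumsum(n_per, out=offsets[1:])

        ctx = cs.cyt_ctx[cyt_idx]
        pos = cs.cyt_pos[cyt_idx]
        strand = cs.cyt_strand[cyt_idx]
        region = chromatin.region_at(chrom, pos) if not spike else np.zeros(
            pos.size, np.int8
        )

        if spike:
            state = np.zeros(pos.size, dtype=bool)
        elif params.mode == "independent":
            state = rng.random(pos.size) < q_tab[ctx, region]
        else:
            state = np.zeros(pos.size, dtype=bool)
            on_template = strand == tmpl[mol_row]
            q_eff = q_tab[ctx[on_template], region[on_template]]
            if params.lineage_spread > 0:
                rich = rng.random(mol_ids.size) < 0.5
                factor = np.where(
                    rich, 1 + params.lineage_spread, 1 - params.lineage_spread
                )
                q_eff = np.clip(q_eff * factor[mol_row[on_template]], 0, 1)
            state[on_template] = rng.random(int(on_template.sum())) < q_eff
            # maintenance per dyad fully inside the molecule
            dlo = np.searchsorted(cs.dyad_pos, s, side="left")
            dhi = np.searchsorted(cs.dyad_pos, e, side="left")
            dmol = np.repeat(np.arange(mol_ids.size), dhi - dlo)
            didx = _ranges(dlo, dhi)
            inside = cs.dyad_partner[didx] < e[dmol]
            dmol, didx = dmol[inside], didx[inside]
            w_row = offsets[dmol] + (cs.dyad_w_idx[didx] - lo_i[dmol])
            c_row = offsets[dmol] + (cs.dyad_c_idx[didx] - lo_i[dmol])
            w_is_template = tmpl[dmol] == 0
            t_row = np.where(w_is_template, w_row, c_row)
            n_row = np.where(w_is_template, c_row, w_row)
            d_region = chromatin.region_at(chrom, cs.dyad_pos[didx])
            eff = e_tab[cs.dyad_ctx[didx], d_region]
            occ_chrom = occ.get(chrom)
            if occ_chrom is not None and params.nucleosome_shield < 1:
                shielded = occ_chrom[pos[n_row]]
                eff = np.where(shielded, eff * params.nucleosome_shield, eff)
            success = state[t_row] & (rng.random(t_row.size) < eff)
            # OR-accumulate: a nascent cytosine can be maintained via more
            # than one dyad (the shared CSG C3)
            np.logical_or.at(state, n_row, success)
            # de novo on any still-unmethylated cytosine
            de_novo = rng.random(pos.size) < d_tab[ctx, region]
            state |= de_novo

        mol_frames.append(
            pd.DataFrame(
                {
                    "molecule_id": mol_ids,
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "template_strand": np.where(tmpl == 0, "W", "C"),
                }
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "molecule_id": mol_ids[mol_row],
                    "chrom": chrom,
                    "pos": pos,
                    "strand": np.where(strand == 0, "W", "C"),
                    "context": _ctx_names(ctx),
                    "meth": state,
                }
            )
        )

    molecules = pd.concat(mol_frames, ignore_index=True).sort_values("molecule_id")
    truth = pd.concat(truth_frames, ignore_index=True).sort_values(
        ["molecule_id", "chrom", "pos", "strand"], kind="stable"
    )
    return MoleculeSet(
        molecules=molecules.reset_index(drop=True), truth=truth.reset_index(drop=True)
    )


_CTX_NAME_ARR = np.array(["CG", "CWG", "CWWG", "CCG", "other"])


def _ctx_names(codes):
    return _CTX_NAME_ARR[codes]


def _ranges(lo, hi):
    """Concatenate arange(lo[i], hi[i]) for all i (vectorised)."""
    n = (hi - lo).astype(np.int64)
    g = np.flatnonzero(n > 0)
    if g.size == 0:
        return np.empty(0, dtype=np.int64)
    total = int(n.sum())
    delta = np.ones(total, dtype=np.int64)
    starts = np.zeros(g.size, dtype=np.int64)
    starts[1:] = np.cumsum(n[g])[:-1]
    delta[starts[0]] = lo[g[0]]
    delta[starts[1:]] = lo[g[1:]] - (hi[g[:-1]] - 1)
    return np.cumsum(delta)


# ---------------------------------------------------------------------------
# observation


@dataclass
class ObservationParams:
    """Bisulfite observation model.

    ``conversion_rate``: probability an unmethylated C reads converted (U);
    ``overconversion_rate``: probability a methylated C reads converted;
    ``miss_rate``: probability a call is missing.
    """

    conversion_rate: float = 0.995
    overconversion_rate: float = 0.002
    miss_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for v in (self.conversion_rate, self.overconversion_rate, self.miss_rate):
            if not 0 <= v <= 1:
                raise ValueError("observation rates must be in [0, 1]")


def emit_call_table(molecules: MoleculeSet, obs: ObservationParams) -> pd.DataFrame:
    """Observe the population: per-molecule cytosine call table.

    Columns ``molecule_id, chrom, pos, strand, state`` with state ``M``,
    ``U`` or ``.`` (missing).  Byte-identical across reruns for a fixed
    observation seed.
    """
    truth = molecules.truth
    if truth.empty:
        raise ValueError("molecule set is empty")
    rng = np.random.default_rng([obs.seed, 0x0B5])
    meth = truth["meth"].to_numpy()
    u = rng.random(len(truth))
    state = np.where(meth, "M", "U")
    # conversion failure: true U observed as M; overconversion: true M as U
    state = np.where(~meth & (u > obs.conversion_rate), "M", state)
    state = np.where(meth & (u < obs.overconversion_rate), "U", state)
    if obs.miss_rate:
        miss = rng.random(len(truth)) < obs.miss_rate
        state = np.where(miss, ".", state)
    out = truth[["molecule_id", "chrom", "pos", "strand"]].copy()
    out["state"] = state
    return out.sort_values(
        ["molecule_id", "chrom", "pos", "strand"], kind="stable"
    ).reset_index(drop=True)


def emit_unlinked_fragments(
    molecules: MoleculeSet, obs: ObservationParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split molecules into unlinked per-strand fragments (WGBS-like input for iSA).

    Each molecule yields two fragment records sharing ``(chrom, start,
    end)`` but carrying no molecule linkage; fragment order and ids are
    randomised by the observation seed.  Returns ``(fragments, calls)``
    where calls are per-fragment cytosine calls.
    """
    mols = molecules.molecules
    if mols.empty:
        raise ValueError("molecule set is empty")
    rng = np.random.default_rng([obs.seed, 0xF4A6])
    frags = pd.concat(
        [
            mols[["molecule_id", "chrom", "start", "end"]].assign(strand="W"),
            mols[["molecule_id", "chrom", "start", "end"]].assign(strand="C"),
        ],
        ignore_index=True,
    )
    frags = frags.iloc[rng.permutation(len(frags))].reset_index(drop=True)
    frags["frag_id"] = np.arange(len(frags), dtype=np.int64)

    calls = emit_call_table(molecules, obs)
    link = frags[["frag_id", "molecule_id", "strand"]]
    calls = calls.merge(link, on=["molecule_id", "strand"], how="inner")
    calls = calls[["frag_id", "chrom", "pos", "strand", "state"]]
    frags = frags[["frag_id", "chrom", "start", "end", "strand"]]
    return frags, calls.sort_values(["frag_id", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# count-level sampler


def simulate_binned_dyads(
    n_bins: int,
    dyads_per_bin: int,
    coverage: int,
    p_total,
    efficiency,
    rng,
    *,
    p_full=None,
    bin_size: int = 1000,
    context: str = "CG",
    motif: str | None = None,
    chrom: str = "sim",
) -> pd.DataFrame:
    """Sample per-dyad status counts directly at the 1-kb-bin scale.

    Per bin ``b`` with per-cytosine methylation probability ``p_total[b]``
    and maintenance efficiency ``y = efficiency[b]``, each dyad draws
    ``coverage`` molecules from the status distribution ``p_full = y *
    p_total``, ``p_hemi = 2 * (p_total - p_full)`` (split evenly between
    strands), ``p_unme = 1 - 2 * p_total + p_full``.  ``efficiency`` equal
    to ``p_total`` gives the fully stochastic (independent) null, for which
    the frequencies are the binomial ``q**2 / 2q(1-q) / (1-q)**2``.  An
    explicit ``p_full`` array (per bin) overrides ``y * p_total``.

    Consistency requires ``y >= max(0, 2 - 1/p_total)``; violations are
    clipped and would distort the intended curve, so keep ``p_total`` in a
    range the efficiency model supports.

    Returns a DyadCounts-style DataFrame compatible with
    :func:`hemimeth.binning.aggregate_bins`.
    """
    p = np.broadcast_to(np.asarray(p_total, dtype=float), (n_bins,))
    y = np.broadcast_to(np.asarray(efficiency, dtype=float), (n_bins,))
    if p_full is None:
        pf = y * p
    else:
        pf = np.broadcast_to(np.asarray(p_full, dtype=float), (n_bins,))
    pf = np.clip(pf, np.maximum(0.0, 2 * p - 1), p)
    ph = 2 * (p - pf)
    pu = 1 - pf - ph

    pf_d = np.repeat(pf, dyads_per_bin)
    ph_d = np.repeat(ph, dyads_per_bin)
    pu_d = np.repeat(pu, dyads_per_bin)
    n_dyads = n_bins * dyads_per_bin
    cov = np.broadcast_to(np.asarray(coverage), (n_dyads,))

    n_full = rng.binomial(cov, pf_d)
    rem = cov - n_full
    with np.errstate(divide="ignore", invalid="ignore"):
        ph_cond = np.where(pf_d < 1, ph_d / (1 - pf_d), 0.0)
    n_hemi = rng.binomial(rem, np.clip(ph_cond, 0, 1))
    n_hw = rng.binomial(n_hemi, 0.5)
    n_unme = rem - n_hemi

    step = max(1, bin_size // (dyads_per_bin + 1))
    within = (1 + np.arange(dyads_per_bin)) * step
    pos = (np.repeat(np.arange(n_bins), dyads_per_bin) * bin_size) + np.tile(
        within, n_bins
    )
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "partner_pos": pos + 1,
            "context": context,
            "motif": motif or context,
            "n_unme": n_unme,
            "n_hemi_watson": n_hw,
            "n_hemi_crick": n_hemi - n_hw,
            "n_full": n_full,
            "coverage": np.asarray(cov),
        }
    )
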