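"""Dyad-site discovery and per-molecule dyad-status calling.

A *dyad* is a pair of symmetric cytosines on opposite strands: CG (Watson
anchor ``pos``, Crick partner ``pos+1``), CWG (W = A/T; partner ``pos+2``),
CWWG (partner ``pos+3``), and CCG (partner ``pos+2``; its reverse complement
CGG is not itself CHG, so CCG dyads are tallied apart from CWG).  A CSG site
is the C{C/G}G trinucleotide that nests a CG dyad (C2-C3) next to a
CHG-context cytosine (C1).

Coordinates are 0-based; intervals are half-open.  A dyad's position for
binning purposes is its Watson anchor.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_A, _C, _G, _T = 65, 67, 71, 84

#: dyad contexts recognised by the caller
CONTEXTS = ("CG", "CWG", "CWWG", "CCG")

#: the four resolvable dyad statuses
STATUSES = ("unme", "hemi_watson", "hemi_crick", "full")

COUNT_COLS = ["n_unme", "n_hemi_watson", "n_hemi_crick", "n_full"]

SITE_COLS = ["chrom", "pos", "partner_pos", "context", "motif"]


def _seq_array(seq: str, chrom: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(arr, (_A, _C, _G, _T))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"non-ACGT character {seq[i]!r} at {chrom}:{i}; "
            "mask or remove ambiguous bases first"
        )
    return arr


def find_dyads(genome) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan Watson strands for every symmetric dyad and every CSG site.

    Parameters
    ----------
    genome
        A :class:`~hemimeth.simulate.GenomeSequence` or any object with a
        ``sequences`` mapping of chromosome name to sequence string.

    Returns
    -------
    dyads : DataFrame
        One row per dyad: ``chrom, pos, partner_pos, context, motif, w_ctx,
        c_ctx``.  ``motif`` is the Watson-strand sequence of the dyad
        (e.g. ``CTAG`` for the palindromic CWWG subcontext); ``w_ctx`` /
        ``c_ctx`` give the sequence context of the Watson and Crick member
        cytosines (they differ only for CCG dyads, whose Crick member sits
        in CG context).
    csg : DataFrame
        One row per CSG instance with the coordinates and strands of C1
        (CHG-context), C2 and C3 (the nested CG dyad).  Watson CGG
        occurrences are reported as mirrored sites with strand roles
        swapped so that C1 is always the CHG-context cytosine.

    Scanning the Watson strand suffices: CG/CWG/CWWG are palindromic, and
    the Crick-strand CCG case appears on Watson as CGG.  The spike-in
    (conversion-control) chromosome, if any, is excluded: it is not part
    of the methylome under analysis.
    """
    spike = getattr(genome, "spike_in_chrom", None)
    dyad_frames = []
    csg_frames = []
    for chrom, seq in genome.sequences.items():
        if chrom == spike:
            continue
        arr = _seq_array(seq, chrom)
        n = arr.size
        is_c = arr == _C
        is_g = arr == _G
        is_w = (arr == _A) | (arr == _T)

        # CG: C at p, G at p+1
        p = np.flatnonzero(is_c[: n - 1] & is_g[1:])
        dyad_frames.append(_dyad_block(chrom, p, 1, "CG", seq))
        # CWG: C at p, A/T at p+1, G at p+2
        p = np.flatnonzero(is_c[: n - 2] & is_w[1 : n - 1] & is_g[2:])
        dyad_frames.append(_dyad_block(chrom, p, 2, "CWG", seq))
        # CWWG
        p = np.flatnonzero(
            is_c[: n - 3] & is_w[1 : n - 2] & is_w[2 : n - 1] & is_g[3:]
        )
        dyad_frames.append(_dyad_block(chrom, p, 3, "CWWG", seq))
        # CCG on Watson: C1=(W,p), C2=(W,p+1), C3=(C,p+2)
        p_ccg = np.flatnonzero(is_c[: n - 2] & is_c[1 : n - 1] & is_g[2:])
        dyad_frames.append(
            _dyad_block(chrom, p_ccg, 2, "CCG", seq, w_ctx="CCG", c_ctx="CG")
        )
        # CCG on Crick appears as CGG on Watson: C1=(C,p+2), C2=(C,p+1), C3=(W,p)
        p_cgg = np.flatnonzero(is_c[: n - 2] & is_g[1 : n - 1] & is_g[2:])
        dyad_frames.append(
            _dyad_block(chrom, p_cgg, 2, "CCG", seq, w_ctx="CG", c_ctx="CCG")
        )

        csg_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "orientation": "W",
                    "c1_pos": p_ccg,
                    "c1_strand": "W",
                    "c2_pos": p_ccg + 1,
                    "c2_strand": "W",
                    "c3_pos": p_ccg + 2,
                    "c3_strand": "C",
                }
            )
        )
        csg_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "orientation": "C",
                    "c1_pos": p_cgg + 2,
                    "c1_strand": "C",
                    "c2_pos": p_cgg + 1,
                    "c2_strand": "C",
                    "c3_pos": p_cgg,
                    "c3_strand": "W",
                }
            )
        )

    dyads = pd.concat(dyad_frames, ignore_index=True)
    dyads = dyads.sort_values(["chrom", "pos", "context"], kind="stable")
    dyads = dyads.reset_index(drop=True)
    csg = pd.concat(csg_frames, ignore_index=True)
    csg = csg.sort_values(["chrom", "c3_pos"], kind="stable").reset_index(drop=True)
    return dyads, csg


def _dyad_block(chrom, pos, offset, context, seq, w_ctx=None, c_ctx=None):
    motifs = [seq[p : p + offset + 1].upper() for p in pos]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "partner_pos": np.asarray(pos, dtype=np.int64) + offset,
            "context": context,
            "motif": motifs,
            "w_ctx": w_ctx or context,
            "c_ctx": c_ctx or context,
        }
    )


def _dedupe_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate calls at one cytosine of one molecule.

    Identical duplicates are collapsed to one record; conflicting duplicates
    (e.g. disagreeing hairpin mates overlapping the same base) are treated
    as missing and dropped.
    """
    keys = ["molecule_id", "chrom", "pos", "strand"]
    calls = calls.drop_duplicates(keys + ["state"])
    conflict = calls.duplicated(keys, keep=False)
    n_conflict = int(conflict.sum())
    if n_conflict:
        logger.info("dropped %d conflicting duplicate calls", n_conflict)
    return calls[~conflict]


def call_dyads(
    calls: pd.DataFrame, dyads: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Pair per-strand cytosine calls into per-molecule dyad statuses.

    Parameters
    ----------
    calls : DataFrame
        Per-molecule cytosine call table with columns ``molecule_id, chrom,
        pos, strand, state`` where ``state`` is ``M``/``U``/``.``.
    dyads : DataFrame
        Site table from :func:`find_dyads`.

    Returns
    -------
    mol_calls : DataFrame
        One row per (molecule, dyad) with both member cytosines covered:
        ``molecule_id, chrom, pos, partner_pos, context, motif,
        watson_state, crick_state, status``.  ``status`` is ``unresolved``
        when either member call is missing.
    counts : DataFrame
        Per-site tallies over resolved molecules (``n_unme, n_hemi_watson,
        n_hemi_crick, n_full`` plus a ``coverage`` sum).
    tally : dict
        Bookkeeping: number of calls ignored because they fall on no dyad
        cytosine, and conflicting duplicates dropped.
    """
    n_in = len(calls)
    calls = calls[calls["state"].isin(("M", "U"))]
    n_missing = n_in - len(calls)
    calls = _dedupe_calls(calls)

    d = dyads.reset_index(names="dyad_id")
    w = calls.loc[calls["strand"] == "W", ["molecule_id", "chrom", "pos", "state"]]
    c = calls.loc[calls["strand"] == "C", ["molecule_id", "chrom", "pos", "state"]]
    w = w.merge(d[["dyad_id", "chrom", "pos"]], on=["chrom", "pos"], how="left")
    c = c.merge(
        d[["dyad_id", "chrom", "partner_pos"]].rename(columns={"partner_pos": "pos"}),
        on=["chrom", "pos"],
        how="left",
    )
    n_ignored = int(w["dyad_id"].isna().sum() + c["dyad_id"].isna().sum())
    if n_ignored:
        logger.info("%d calls fall on no dyad cytosine; ignored", n_ignored)
    w = w.dropna(subset=["dyad_id"])
    c = c.dropna(subset=["dyad_id"])

    pairs = w[["molecule_id", "dyad_id", "state"]].rename(
        columns={"state": "watson_state"}
    ).merge(
        c[["molecule_id", "dyad_id", "state"]].rename(
            columns={"state": "crick_state"}
        ),
        on=["molecule_id", "dyad_id"],
        how="outer",
    )
    pairs["dyad_id"] = pairs["dyad_id"].astype(np.int64)
    ws = pairs["watson_state"]
    cs = pairs["crick_state"]
    pairs["status"] = np.select(
        [
            (ws == "M") & (cs == "M"),
            (ws == "M") & (cs == "U"),
            (ws == "U") & (cs == "M"),
            (ws == "U") & (cs == "U"),
        ],
        ["full", "hemi_watson", "hemi_crick", "unme"],
        default="unresolved",
    )
    mol_calls = pairs.merge(d, on="dyad_id").sort_values(
        ["molecule_id", "chrom", "pos"], kind="stable"
    )
    mol_calls = mol_calls.reset_index(drop=True)

    resolved = mol_calls[mol_calls["status"] != "unresolved"]
    counts = (
        resolved.groupby(["dyad_id", "status"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(STATUSES), fill_value=0)
    )
    counts.columns = COUNT_COLS
    counts = counts.reset_index().merge(d[["dyad_id"] + SITE_COLS], on="dyad_id")
    counts["coverage"] = counts[COUNT_COLS].sum(axis=1)
    counts = counts[SITE_COLS + COUNT_COLS + ["coverage"]].sort_values(
        ["chrom", "pos", "context"], kind="stable"
    ).reset_index(drop=True)

    tally = {
        "n_calls": n_in,
        "n_missing_state": n_missing,
        "n_ignored_positions": n_ignored,
    }
    return mol_calls, counts, tally


def conversion_rate(calls: pd.DataFrame, spike_chrom: str) -> float:
    """Bisulfite conversion rate from a fully unmethylated spike-in.

    Every cytosine on the spike-in (lambda-like) chromosome is truly
    unmethylated, so the converted-call fraction among its cytosine calls
    estimates the conversion rate.
    """
    spike = calls[
        (calls["chrom"] == spike_chrom) & calls["state"].isin(("M", "U"))
    ]
    if spike.empty:
        raise ValueError(
            f"no resolved cytosine calls on spike-in chromosome {spike_chrom!r}"
        )
    return float((spike["state"] == "U").mean())


def isa_pair(
    fragments: pd.DataFrame,
    frag_calls: pd.DataFrame | None = None,
    *,
    n_permutations: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame | None, dict]:
    """In silico strand annealing: pair Watson/Crick fragments by coordinates.

    Watson and Crick strands read from the same double-stranded molecule
    share identical genomic coordinates after alignment, so fragments with
    identical ``(chrom, start, end)`` and opposite strands are re-paired
    into pseudo-molecules.  Excess fragments in a coordinate group (the
    random-fragmentation collisions) cannot be paired unambiguously and are
    dropped with a tally.

    The same-ends enrichment is the observed pair count over the random
    expectation, estimated by permuting fragment end coordinates within
    each chromosome ``n_permutations`` times and re-counting pairs.

    Returns ``(pairs, paired_calls, report)`` where ``pairs`` maps a new
    ``molecule_id`` to the two fragment ids, ``paired_calls`` is the call
    table relabelled by molecule (``None`` when ``frag_calls`` is None), and
    ``report`` carries pairing and enrichment tallies.
    """
    frags = fragments.reset_index(drop=True)
    obs_pairs = _coord_pairs(frags)
    if obs_pairs.empty:
        logger.warning("iSA found zero pairable fragments")

    rng = np.random.default_rng(seed)
    rand_counts = []
    for _ in range(n_permutations):
        perm = frags.copy()
        for chrom, idx in perm.groupby("chrom").groups.items():
            idx = np.asarray(idx)
            perm.loc[idx, "end"] = perm.loc[rng.permutation(idx), "end"].to_numpy()
        rand_counts.append(len(_coord_pairs(perm)))
    expected = float(np.mean(rand_counts)) if rand_counts else 0.0
    n_obs = len(obs_pairs)
    enrichment = np.inf if expected == 0 else n_obs / expected

    paired_calls = None
    if frag_calls is not None and not obs_pairs.empty:
        frag_to_mol = pd.concat(
            [
                obs_pairs[["molecule_id", "watson_frag"]].rename(
                    columns={"watson_frag": "frag_id"}
                ),
                obs_pairs[["molecule_id", "crick_frag"]].rename(
                    columns={"crick_frag": "frag_id"}
                ),
            ]
        )
        paired_calls = frag_calls.merge(frag_to_mol, on="frag_id", how="inner")
        paired_calls = paired_calls.drop(columns=["frag_id"])

    report = {
        "n_fragments": len(frags),
        "n_pairs": n_obs,
        "n_dropped": len(frags) - 2 * n_obs,
        "expected_random_pairs": expected,
        "enrichment": enrichment,
    }
    return obs_pairs, paired_calls, report


def _coord_pairs(frags: pd.DataFrame) -> pd.DataFrame:
    """Greedy one-to-one W/C matching within identical-coordinate groups."""
    w = frags[frags["strand"] == "W"]
    c = frags[frags["strand"] == "C"]
    key = ["chrom", "start", "end"]
    w = w.sort_values(key + ["frag_id"], kind="stable")
    c = c.sort_values(key + ["frag_id"], kind="stable")
    w = w.assign(rank=w.groupby(key).cumcount())
    c = c.assign(rank=c.groupby(key).cumcount())
    merged = w.merge(
        c, on=key + ["rank"], suffixes=("_w", "_c"), how="inner"
    )
    pairs = merged[["chrom", "start", "end", "frag_id_w", "frag_id_c"]].rename(
        columns={"frag_id_w": "watson_frag", "frag_id_c": "crick_frag"}
    )
    pairs = pairs.reset_index(drop=True)
    pairs.insert(0, "molecule_id", np.arange(len(pairs), dtype=np.int64))
    return pairs


def titrate_coverage(
    calls: pd.DataFrame,
    dyads: pd.DataFrame,
    target_covs,
    resolutions,
    *,
    seed: int = 0,
    min_cov_dyad: int = 1,
) -> pd.DataFrame:
    """Coverage-titration QC: stability of methylation levels under subsampling.

    Molecules are subsampled without replacement to hit each target mean
    resolved dyad coverage; at each resolution (a bin size in bp, or
    ``"dyad"``) the per-unit total methylation level of the subsample is
    divided by the full-depth level, restricted to units covered in both.
    Reports the median and IQR of those ratios per (coverage, resolution).
    """
    _, full_counts, _ = call_dyads(calls, dyads)
    achieved = float(full_counts["coverage"].mean())
    for t in target_covs:
        if t > achieved:
            raise ValueError(
                f"target coverage {t} exceeds achieved mean coverage {achieved:.2f}"
            )
    mol_ids = calls["molecule_id"].unique()
    rng = np.random.default_rng(seed)

    rows = []
    for target in target_covs:
        frac = target / achieved
        keep = rng.choice(
            mol_ids, size=int(round(frac * len(mol_ids))), replace=False
        )
        sub_calls = calls[calls["molecule_id"].isin(keep)]
        _, sub_counts, _ = call_dyads(sub_calls, dyads)
        for res in resolutions:
            ratios = _level_ratio(full_counts, sub_counts, res, min_cov_dyad)
            if ratios.size == 0:
                med = q25 = q75 = np.nan
            else:
                med = float(np.median(ratios))
                q25, q75 = (float(q) for q in np.quantile(ratios, [0.25, 0.75]))
            rows.append(
                {
                    "target_cov": target,
                    "resolution": res,
                    "n_units": int(ratios.size),
                    "median_ratio": med,
                    "q25": q25,
                    "q75": q75,
                }
            )
    return pd.DataFrame(rows)


def _level_ratio(full_counts, sub_counts, resolution, min_cov):
    def level(df):
        if resolution == "dyad":
            g = df[df["coverage"] >= min_cov].set_index(["chrom", "pos", "context"])
            num = 2 * g["n_full"] + g["n_hemi_watson"] + g["n_hemi_crick"]
            return num / (2.0 * g["coverage"])
        size = int(resolution)
        g = df.assign(bin=df["pos"] // size).groupby(["chrom", "bin"])
        num = 2 * g["n_full"].sum() + g["n_hemi_watson"].sum() + g["n_hemi_crick"].sum()
        return num / (2.0 * g["coverage"].sum())

    lf, ls = level(full_counts), level(sub_counts)
    joined = pd.concat({"full": lf, "sub": ls}, axis=1).dropna()
    joined = joined[joined["full"] > 0]
    return (joined["sub"] / joined["full"]).to_numpy()
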