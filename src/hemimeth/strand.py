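"""Single-molecule strand analyses.

Hemi-methylated dyads born of DNA replication carry their 5mC on the
template strand, so on one molecule neighbouring maintenance-failure hemi
dyads share a strand.  :func:`proximal_status` measures that concordance:
for every hemi-methylated focal dyad the nearest resolved neighbour dyad
on the same molecule is classified hemi-same / hemi-oppo / full / unme.

The CSG trinucleotide (C{C/G}G) places two consecutive cytosines (C1
CHG-context, C2 CG-context) on one strand and a third (C3, completing the
CG dyad with C2) on the other, so conditional correlations among the
three separate same-strand co-survival from dyad maintenance:
:func:`conditional_pearson` computes Pearson r for each cytosine pair
with the third cytosine's state fixed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECTRUM_STATES = ("hemi_same", "hemi_oppo", "full", "unme")


def proximal_status(
    mol_calls: pd.DataFrame,
    focal_context: str,
    neighbor_context: str,
    max_dist: int | None = None,
    *,
    tie_break: str = "left",
) -> pd.DataFrame:
    """Spectrum of the dyad most proximal to hemi-methylated focal dyads.

    For every hemi focal dyad on a molecule, the nearest resolved
    ``neighbor_context`` dyad on the same molecule (excluding the focal
    site itself) within ``max_dist`` bp is classified relative to the
    focal 5mC strand.  Equidistant left/right neighbours resolve to the
    left by default.  Returns a one-row-per-state frequency table.
    """
    df = mol_calls[mol_calls["status"] != "unresolved"]
    df = df.sort_values(["molecule_id", "chrom", "pos"], kind="stable")
    mol_codes, _ = pd.factorize(
        df["molecule_id"].astype(str) + ":" + df["chrom"].astype(str)
    )
    pos = df["pos"].to_numpy(np.int64)
    status = df["status"].to_numpy()
    ctx = df["context"].to_numpy()

    focal_mask = (ctx == focal_context) & (
        (status == "hemi_watson") | (status == "hemi_crick")
    )
    nb_mask = ctx == neighbor_context

    key = mol_codes.astype(np.int64) * (pos.max() + 2) + pos
    nb_key = key[nb_mask]
    nb_pos = pos[nb_mask]
    nb_status = status[nb_mask]
    nb_mol = mol_codes[nb_mask]

    f_idx = np.flatnonzero(focal_mask)
    ins = np.searchsorted(nb_key, key[f_idx])

    chosen = np.full(f_idx.size, -1, dtype=np.int64)
    f_mol = mol_codes[f_idx]
    f_pos = pos[f_idx]
    # candidate to the left / right in the neighbour array, skipping self
    left = ins - 1
    right = ins
    # right candidate may be the focal site itself when contexts coincide
    right_c = np.clip(right, None, max(nb_key.size - 1, 0))
    same_site = (right < nb_key.size) & (nb_key[right_c] == key[f_idx])
    right = np.where(same_site, right + 1, right)

    lv = (left >= 0) & (nb_mol[np.clip(left, 0, None)] == f_mol)
    rv = (right < nb_key.size) & (nb_mol[np.clip(right, None, nb_key.size - 1)] == f_mol)
    ld = np.where(lv, f_pos - nb_pos[np.clip(left, 0, None)], np.iinfo(np.int64).max)
    rd = np.where(
        rv, nb_pos[np.clip(right, None, nb_key.size - 1)] - f_pos, np.iinfo(np.int64).max
    )
    if max_dist is not None:
        lv &= ld <= max_dist
        rv &= rd <= max_dist
        ld = np.where(lv, ld, np.iinfo(np.int64).max)
        rd = np.where(rv, rd, np.iinfo(np.int64).max)
    if tie_break == "left":
        take_left = lv & (~rv | (ld <= rd))
    else:
        take_left = lv & (~rv | (ld < rd))
    chosen = np.where(take_left, left, np.where(rv, right, -1))

    ok = chosen >= 0
    if not ok.any():
        logger.warning("proximal_status: no qualifying pairs")
        return pd.DataFrame(
            {"state": SPECTRUM_STATES, "frequency": np.nan, "n_pairs": 0}
        )
    nb_st = nb_status[chosen[ok]]
    focal_st = status[f_idx[ok]]
    classified = np.select(
        [
            ((nb_st == "hemi_watson") | (nb_st == "hemi_crick")) & (nb_st == focal_st),
            (nb_st == "hemi_watson") | (nb_st == "hemi_crick"),
            nb_st == "full",
        ],
        ["hemi_same", "hemi_oppo", "full"],
        default="unme",
    )
    n = classified.size
    freqs = [(classified == s).sum() / n for s in SPECTRUM_STATES]
    return pd.DataFrame(
        {
            "state": SPECTRUM_STATES,
            "frequency": freqs,
            "n_pairs": n,
        }
    )


def csg_triplets(calls: pd.DataFrame, csg_sites: pd.DataFrame) -> pd.DataFrame:
    """Per-molecule (C1, C2, C3) state triplets at CSG sites.

    Only triplets with all three cytosines resolved (M/U) on the same
    molecule are retained.  ``calls`` is a per-molecule cytosine call
    table; ``csg_sites`` comes from :func:`hemimeth.dyads.find_dyads`.
    """
    resolved = calls[calls["state"].isin(("M", "U"))]
    sites = csg_sites.reset_index(names="csg_id")
    parts = []
    for k in ("c1", "c2", "c3"):
        m = resolved.merge(
            sites[["csg_id", "chrom", f"{k}_pos", f"{k}_strand"]].rename(
                columns={f"{k}_pos": "pos", f"{k}_strand": "strand"}
            ),
            on=["chrom", "pos", "strand"],
        )[["molecule_id", "csg_id", "state"]].rename(columns={"state": f"s{k[1]}"})
        parts.append(m)
    trip = parts[0].merge(parts[1], on=["molecule_id", "csg_id"]).merge(
        parts[2], on=["molecule_id", "csg_id"]
    )
    return trip.merge(
        sites[["csg_id", "chrom", "orientation", "c1_pos"]], on="csg_id"
    ).reset_index(drop=True)


def conditional_pearson(
    triplets: pd.DataFrame, *, min_n: int = 30
) -> pd.DataFrame:
    """Pearson r between two CSG cytosines with the third cytosine fixed.

    States are coded M=1, U=0; observations are pooled over (site x
    molecule).  The value is undefined (NaN) when either vector is
    constant or the conditioned subset is smaller than ``min_n``.
    Returns six rows: (pair, condition cytosine, condition state, r, n).
    """
    if triplets.empty:
        raise ValueError("no triplets supplied")
    s = {i: (triplets[f"s{i}"] == "M").to_numpy(float) for i in (1, 2, 3)}
    pairs = [((2, 3), 1), ((1, 3), 2), ((1, 2), 3)]
    rows = []
    for (a, b), c in pairs:
        for cond_state, cond_name in ((0.0, "U"), (1.0, "M")):
            m = s[c] == cond_state
            n = int(m.sum())
            r = np.nan
            if n >= min_n:
                va, vb = s[a][m], s[b][m]
                if va.std() > 0 and vb.std() > 0:
                    r = float(np.corrcoef(va, vb)[0, 1])
            rows.append(
                {
                    "pair": f"C{a}-C{b}",
                    "condition": f"C{c}={cond_name}",
                    "r": r,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
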