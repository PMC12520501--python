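"""Differentially methylated region calling between two samples.

Per 1-kb bin the per-dyad full- (fDMR) or hemi-methylation (hDMR)
frequencies over dyads shared by both samples are compared with a paired
two-sided t-test and a Mann-Whitney U test; Benjamini-Hochberg FDR is
applied across all tested bins of one (context, kind) family and a bin is
a DMR when both adjusted p-values fall below alpha (conjunction;
``combination="either"`` relaxes this).  Bins where the second sample has
lost methylation completely are additionally called when they hold more
than 10 shared dyads and the absolute frequency change exceeds 0.30.

Called DMRs are classified by the signs of the full- and hemi-methylation
deltas (mutant minus wildtype): Group 1 both decreased, Group 2 full down
/ hemi up, Group 3 full up / hemi down, Group 4 both increased.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dyads import COUNT_COLS


def call_dmrs(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    *,
    context: str | None = None,
    kind: str = "full",
    bin_size: int = 1000,
    alpha: float = 0.05,
    min_cov: int = 5,
    min_shared: int = 3,
    combination: str = "both",
    loss_min_dyads: int = 10,
    loss_min_delta: float = 0.30,
    paired_wilcoxon: bool = False,
) -> pd.DataFrame:
    """Call f/hDMRs of ``counts_b`` (e.g. mutant) against ``counts_a`` (wildtype).

    Returns one row per tested bin with raw and FDR-adjusted p-values,
    full- and hemi-methylation deltas, the DMR flag, the complete-loss
    flag, and the Group 1-4 label for called bins.  Bins with fewer than
    ``min_shared`` shared dyads are reported untested (NaN p-values).
    """
    if kind not in ("full", "hemi"):
        raise ValueError("kind must be 'full' or 'hemi'")
    if combination not in ("both", "either"):
        raise ValueError("combination must be 'both' or 'either'")

    a = _site_freqs(counts_a, context, min_cov)
    b = _site_freqs(counts_b, context, min_cov)
    m = a.merge(b, on=["chrom", "pos", "context"], suffixes=("_a", "_b"))
    if m.empty:
        return pd.DataFrame()
    m["bin"] = m["pos"] // bin_size

    rows = []
    for (chrom, bin_idx, ctx), grp in m.groupby(
        ["chrom", "bin", "context"], observed=True
    ):
        fa = grp[f"f_{kind}_a"].to_numpy()
        fb = grp[f"f_{kind}_b"].to_numpy()
        n = len(grp)
        delta_full = float(grp["f_full_b"].mean() - grp["f_full_a"].mean())
        delta_hemi = float(grp["f_hemi_b"].mean() - grp["f_hemi_a"].mean())
        delta = {"full": delta_full, "hemi": delta_hemi}[kind]
        p_t = p_u = np.nan
        if n >= min_shared:
            diff = fb - fa
            if np.ptp(diff) > 0 or diff.std() > 0:
                p_t = stats.ttest_rel(fb, fa).pvalue
            if paired_wilcoxon:
                if np.any(diff != 0):
                    p_u = stats.wilcoxon(fb, fa).pvalue
            elif np.ptp(np.concatenate([fa, fb])) > 0:
                p_u = stats.mannwhitneyu(fb, fa, alternative="two-sided").pvalue
        complete_loss = bool(
            (fb == 0).all() and n > loss_min_dyads and abs(delta) > loss_min_delta
        )
        rows.append(
            {
                "chrom": chrom,
                "start": int(bin_idx) * bin_size,
                "end": (int(bin_idx) + 1) * bin_size,
                "context": ctx,
                "kind": "fDMR" if kind == "full" else "hDMR",
                "n_shared_dyads": n,
                "p_ttest": p_t,
                "p_mwu": p_u,
                "delta_full": delta_full,
                "delta_hemi": delta_hemi,
                "complete_loss": complete_loss,
            }
        )
    out = pd.DataFrame(rows)

    out["q_ttest"] = _bh(out["p_ttest"])
    out["q_mwu"] = _bh(out["p_mwu"])
    sig_t = out["q_ttest"] < alpha
    sig_u = out["q_mwu"] < alpha
    if combination == "both":
        tested_sig = sig_t & sig_u
        # a zero-variance paired difference leaves the t-test undefined;
        # the decision then falls to the U test alone
        tested_sig |= out["p_ttest"].isna() & sig_u
    else:
        tested_sig = sig_t | sig_u
    out["is_dmr"] = (tested_sig.fillna(False) | out["complete_loss"]).astype(bool)
    out["group"] = [
        classify_groups(df, dh) if is_d else "unassigned"
        for df, dh, is_d in zip(out["delta_full"], out["delta_hemi"], out["is_dmr"])
    ]
    return out.sort_values(["chrom", "start", "context"]).reset_index(drop=True)


def _site_freqs(counts, context, min_cov):
    df = counts
    if context is not None:
        df = df[df["context"] == context]
    df = df.copy()
    cov = df[COUNT_COLS].sum(axis=1)
    df = df[cov >= min_cov]
    cov = cov[cov >= min_cov].astype(float)
    df["f_full"] = df["n_full"] / cov
    df["f_hemi"] = (df["n_hemi_watson"] + df["n_hemi_crick"]) / cov
    return df[["chrom", "pos", "context", "f_full", "f_hemi"]]


def _bh(p: pd.Series) -> pd.Series:
    q = pd.Series(np.nan, index=p.index)
    mask = p.notna()
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def classify_groups(delta_full: float, delta_hemi: float) -> str:
    """Group 1-4 label from the signs of the full/hemi deltas."""
    if delta_full == 0 or delta_hemi == 0 or np.isnan(delta_full) or np.isnan(delta_hemi):
        return "unassigned"
    if delta_full < 0:
        return "1" if delta_hemi < 0 else "2"
    return "3" if delta_hemi < 0 else "4"


def count_csg(genome, chrom: str, start: int, end: int) -> int:
    """Number of CSG (S = C/G) trinucleotides in [start, end) on the Watson strand.

    Counts CCG plus CGG occurrences (equivalently CCG on either strand);
    overlapping occurrences count individually.
    """
    seq = genome.sequences.get(chrom)
    if seq is None:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if start < 0 or end > len(seq) or start > end:
        raise ValueError(f"interval [{start}, {end}) outside {chrom}")
    window = seq[start:end].upper()
    return sum(
        1 for i in range(len(window) - 2) if window[i : i + 3] in ("CCG", "CGG")
    )


def annotate_csg(dmrs: pd.DataFrame, genome) -> pd.DataFrame:
    """Attach per-DMR CSG counts (clipped to chromosome bounds)."""
    out = dmrs.copy()
    out["csg_count"] = [
        count_csg(genome, c, s, min(e, len(genome.sequences[c])))
        for c, s, e in zip(out["chrom"], out["start"], out["end"])
    ]
    return out
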