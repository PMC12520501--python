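"""Stochastic full-methylation null and the Exp/Theo ratio curve.

If every cytosine were methylated independently with the bin's own
per-cytosine frequency ``p_total``, the expected full-methylation
frequency of a dyad would be ``p_total**2``.  The Exp/Theo ratio compares
the observed full-methylation frequency with that theoretical value,
grouped over bins of similar ``p_total`` to keep uneven methylation
distributions from mixing; ``log2`` of the ratio is 0 under pure
stochastic deposition and positive under specific maintenance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CURVE_COLS = [
    "context",
    "group_lo",
    "group_hi",
    "n_bins",
    "exp_full",
    "theo_full",
    "log2_ratio",
]


def default_group_edges(n_groups: int = 10, lo: float = 0.025, hi: float = 1.0):
    """Equal-width ``p_total`` groups over [lo, hi] (lo matches the 2.5% filter)."""
    return np.linspace(lo, hi, n_groups + 1)


def exp_theo_curve(
    bins: pd.DataFrame,
    context: str,
    group_edges=None,
    *,
    include_filtered: bool = False,
) -> pd.DataFrame:
    """Experimental vs theoretical full-methylation frequency per p_total group.

    Per bin the theoretical full frequency is ``p_total**2``; bins are
    grouped by ``p_total`` on ``group_edges`` and per group the
    experimental and theoretical values are dyad-count-weighted means.
    Groups with no bins or zero theoretical frequency are omitted.
    """
    edges = np.asarray(
        default_group_edges() if group_edges is None else group_edges, dtype=float
    )
    if (np.diff(edges) <= 0).any():
        raise ValueError("group edges must be strictly increasing")
    df = bins[bins["context"] == context]
    if not include_filtered and "filtered" in df:
        df = df[~df["filtered"].astype(bool)]
    if df.empty:
        return pd.DataFrame(columns=CURVE_COLS)

    p = df["p_total"].to_numpy(float)
    w = df["n_dyads"].to_numpy(float)
    exp_full = df["p_full"].to_numpy(float)
    theo_full = p**2
    grp = np.digitize(p, edges) - 1
    keep = (grp >= 0) & (grp < len(edges) - 1)

    rows = []
    for g in range(len(edges) - 1):
        m = keep & (grp == g)
        if not m.any():
            continue
        wg = w[m]
        theo = float(np.average(theo_full[m], weights=wg))
        if theo <= 0:
            continue
        exp = float(np.average(exp_full[m], weights=wg))
        rows.append(
            {
                "context": context,
                "group_lo": edges[g],
                "group_hi": edges[g + 1],
                "n_bins": int(m.sum()),
                "exp_full": exp,
                "theo_full": theo,
                "log2_ratio": np.log2(exp / theo) if exp > 0 else -np.inf,
            }
        )
    return pd.DataFrame(rows, columns=CURVE_COLS)
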