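"""Genomic-bin aggregation of dyad counts and ChIP-track preparation.

Per-dyad full/hemi frequencies are computed only at dyads with resolved
coverage >= ``min_cov`` (default 5 reads), then averaged per fixed-width
bin; bins whose total methylation falls below ``min_total`` (default 2.5%)
are flagged as filtered rather than deleted.  ``p_total = p_full +
p_hemi/2`` is the per-cytosine methylation frequency within dyads, i.e.
the initial hemi-methylation frequency right after DNA replication.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dyads import COUNT_COLS

logger = logging.getLogger(__name__)

BIN_COLS = [
    "chrom",
    "start",
    "end",
    "context",
    "n_dyads",
    "p_full",
    "p_hemi",
    "p_unme",
    "p_total",
    "filtered",
]


def aggregate_bins(
    counts: pd.DataFrame,
    bin_size: int = 1000,
    *,
    min_cov: int = 5,
    min_total: float = 0.025,
    pooled: bool = False,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Aggregate per-site dyad counts into per-bin methylation frequencies.

    ``pooled=False`` (default) averages per-dyad frequencies unweighted by
    coverage; ``pooled=True`` sums counts within the bin first.  Partial
    terminal bins keep their true width when ``chrom_sizes`` is given.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    df = counts.copy()
    df["coverage"] = df[COUNT_COLS].sum(axis=1)
    df = df[df["coverage"] >= min_cov]
    if df.empty:
        return pd.DataFrame(columns=BIN_COLS)
    cov = df["coverage"].to_numpy(dtype=float)
    df["f_full"] = df["n_full"] / cov
    df["f_hemi"] = (df["n_hemi_watson"] + df["n_hemi_crick"]) / cov
    df["f_unme"] = df["n_unme"] / cov
    df["bin"] = df["pos"] // bin_size

    g = df.groupby(["chrom", "bin", "context"], observed=True)
    if pooled:
        tot = g[["n_full", "n_hemi_watson", "n_hemi_crick", "n_unme", "coverage"]].sum()
        out = pd.DataFrame(
            {
                "n_dyads": g.size(),
                "p_full": tot["n_full"] / tot["coverage"],
                "p_hemi": (tot["n_hemi_watson"] + tot["n_hemi_crick"])
                / tot["coverage"],
                "p_unme": tot["n_unme"] / tot["coverage"],
            }
        )
    else:
        out = g[["f_full", "f_hemi", "f_unme"]].mean()
        out.columns = ["p_full", "p_hemi", "p_unme"]
        out["n_dyads"] = g.size()
    out = out.reset_index()
    out["p_total"] = out["p_full"] + out["p_hemi"] / 2
    out["filtered"] = out["p_total"] < min_total
    out["start"] = out["bin"] * bin_size
    out["end"] = out["start"] + bin_size
    if chrom_sizes:
        limit = out["chrom"].map(chrom_sizes)
        out["end"] = np.minimum(out["end"], limit.fillna(out["end"]))
    return out[BIN_COLS].sort_values(["chrom", "start", "context"]).reset_index(
        drop=True
    )


def bin_track(
    records: pd.DataFrame,
    bin_size: int,
    chrom_sizes: dict[str, int],
    *,
    input_records: pd.DataFrame | None = None,
    blacklist_factor: float = 2.0,
) -> pd.DataFrame:
    """Average a bedGraph-style track into fixed-width bins.

    Per-bin value is the length-weighted mean of record values (absent
    stretches count as 0, so mass is conserved: sum of value*width over
    bins equals sum over records of value*overlap).  When an input/control
    track is supplied, bins whose binned input coverage exceeds
    ``blacklist_factor`` times its genome-wide mean are blacklisted.
    """
    out = _bin_values(records, bin_size, chrom_sizes)
    out["blacklisted"] = False
    if input_records is not None:
        inp = _bin_values(input_records, bin_size, chrom_sizes)
        widths = (inp["end"] - inp["start"]).to_numpy(dtype=float)
        mean_cov = float((inp["value"] * widths).sum() / widths.sum())
        bad = inp.loc[inp["value"] > blacklist_factor * mean_cov, ["chrom", "start"]]
        key = out.merge(bad.assign(_bad=True), on=["chrom", "start"], how="left")
        out["blacklisted"] = key["_bad"].eq(True).to_numpy()
        logger.info("blacklisted %d bins", int(out["blacklisted"].sum()))
    return out


def _bin_values(records, bin_size, chrom_sizes):
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    frames = []
    for chrom, grp in records.groupby("chrom"):
        size = chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"no chromosome size for {chrom}")
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        vals = grp["value"].to_numpy(float)
        if (starts < 0).any() or (ends > size).any():
            raise ValueError(f"record outside chromosome bounds on {chrom}")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping bedGraph records on {chrom}")
        n_bins = -(-size // bin_size)
        mass = np.zeros(n_bins)
        # split each record across the bins it overlaps
        first = starts // bin_size
        last = (ends - 1) // bin_size
        span = last - first + 1
        rec_idx = np.repeat(np.arange(len(grp)), span)
        bin_idx = np.concatenate(
            [np.arange(f, l + 1) for f, l in zip(first, last)]
        ) if len(grp) else np.empty(0, np.int64)
        b_start = bin_idx * bin_size
        b_end = np.minimum(b_start + bin_size, size)
        ov = np.minimum(ends[rec_idx], b_end) - np.maximum(starts[rec_idx], b_start)
        np.add.at(mass, bin_idx, vals[rec_idx] * ov)
        bs = np.arange(n_bins) * bin_size
        be = np.minimum(bs + bin_size, size)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": bs,
                    "end": be,
                    "value": mass / (be - bs),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


#: default enrichment thresholds: H3K9me2 per the low<=0.1 / high>=5 rule,
#: other marks high>=2 with low as the complement
def classify_regions(
    track: pd.DataFrame,
    mark: str,
    low_thr: float | None = None,
    high_thr: float | None = None,
) -> pd.DataFrame:
    """Label bins low/high/neither by enrichment; blacklisted bins are neither."""
    if mark.lower() == "h3k9me2":
        low_thr = 0.1 if low_thr is None else low_thr
        high_thr = 5.0 if high_thr is None else high_thr
        if low_thr >= high_thr:
            raise ValueError("low threshold must be below high threshold")
        label = np.select(
            [track["value"] <= low_thr, track["value"] >= high_thr],
            ["low", "high"],
            default="neither",
        )
    else:
        high_thr = 2.0 if high_thr is None else high_thr
        label = np.where(track["value"] >= high_thr, "high", "low")
    out = track.copy()
    out["label"] = label
    if "blacklisted" in out:
        out.loc[out["blacklisted"].astype(bool), "label"] = "neither"
    return out
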