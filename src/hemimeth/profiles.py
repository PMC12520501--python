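"""Meta-profiles around nucleosome centers.

Signals (per-dyad methylation frequencies, occupancy, sequence-context
density) are averaged per offset relative to well-positioned nucleosome
centers; profiles can be max-normalized to 1.  The full/hemi ratio per
offset and its Pearson correlation with occupancy quantify whether
nucleosomes impede the hemi-to-full maintenance conversion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .dyads import COUNT_COLS

logger = logging.getLogger(__name__)


def center_profile(
    values: dict[str, tuple[np.ndarray, np.ndarray]],
    centers: dict[str, np.ndarray],
    window: int = 1000,
    step: int = 10,
    *,
    normalize: bool = False,
) -> pd.DataFrame:
    """Average a sparse per-position signal by offset from centers.

    ``values`` maps chromosome to ``(positions, signal)`` arrays (sorted
    positions).  Every data point within ``window`` bp of a center is
    assigned to the offset bucket of width ``step`` nearest its relative
    position; per bucket the mean over all (center, point) pairs is
    reported with the contributing count.  ``normalize=True`` rescales the
    profile maximum to 1.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if step > 2 * window:
        raise ValueError("step larger than the window leaves no offsets")
    offsets = np.arange(-window, window + 1, step)
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=np.int64)
    for chrom, cents in centers.items():
        if chrom not in values:
            continue
        pos, sig = values[chrom]
        pos = np.asarray(pos)
        sig = np.asarray(sig, dtype=float)
        cents = np.asarray(cents)
        lo = np.searchsorted(pos, cents - window, side="left")
        hi = np.searchsorted(pos, cents + window, side="right")
        n_per = hi - lo
        c_rep = np.repeat(cents, n_per)
        idx = _concat_ranges(lo, hi)
        rel = pos[idx] - c_rep
        bucket = np.clip(
            np.rint((rel + window) / step).astype(np.int64), 0, offsets.size - 1
        )
        np.add.at(sums, bucket, sig[idx])
        np.add.at(counts, bucket, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if normalize:
        top = np.nanmax(mean) if np.isfinite(mean).any() else np.nan
        if top and top > 0:
            mean = mean / top
    return pd.DataFrame({"offset": offsets, "value": mean, "n": counts})


def _concat_ranges(lo, hi):
    n = (hi - lo).astype(np.int64)
    g = np.flatnonzero(n > 0)
    if g.size == 0:
        return np.empty(0, dtype=np.int64)
    delta = np.ones(int(n.sum()), dtype=np.int64)
    starts = np.zeros(g.size, dtype=np.int64)
    starts[1:] = np.cumsum(n[g])[:-1]
    delta[starts[0]] = lo[g[0]]
    delta[starts[1:]] = lo[g[1:]] - (hi[g[:-1]] - 1)
    return np.cumsum(delta)


def dyad_frequency_values(
    counts: pd.DataFrame, context: str, *, min_cov: int = 5
) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Sparse per-position full/hemi frequency signals from dyad counts.

    Returns ``{"full": {chrom: (pos, freq)}, "hemi": ...}`` restricted to
    dyads with resolved coverage >= ``min_cov``; a dyad's position is its
    Watson anchor.
    """
    df = counts[counts["context"] == context].copy()
    cov = df[COUNT_COLS].sum(axis=1)
    df = df[cov >= min_cov]
    cov = cov[cov >= min_cov].astype(float)
    df["f_full"] = df["n_full"] / cov
    df["f_hemi"] = (df["n_hemi_watson"] + df["n_hemi_crick"]) / cov
    out = {"full": {}, "hemi": {}}
    for chrom, grp in df.groupby("chrom"):
        grp = grp.sort_values("pos")
        p = grp["pos"].to_numpy(np.int64)
        out["full"][chrom] = (p, grp["f_full"].to_numpy())
        out["hemi"][chrom] = (p, grp["f_hemi"].to_numpy())
    return out


def occupancy_values(
    centers: dict[str, np.ndarray],
    chrom_sizes: dict[str, int],
    *,
    half_width: int = 73,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Dense 0/1 nucleosome-occupancy signal from center positions."""
    out = {}
    for chrom, cents in centers.items():
        size = chrom_sizes[chrom]
        a = np.zeros(size)
        for c in cents:
            a[max(0, c - half_width) : c + half_width + 1] = 1.0
        out[chrom] = (np.arange(size, dtype=np.int64), a)
    return out


def ratio_and_correlation(
    full_profile: pd.DataFrame,
    hemi_profile: pd.DataFrame,
    occupancy_profile: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Per-offset full/hemi ratio and its Pearson r against occupancy.

    The ratio is undefined where the hemi frequency is 0; r is computed
    across offsets where both the ratio and occupancy are defined, and is
    NaN with fewer than 3 such offsets or a constant vector.
    """
    if not (full_profile["offset"].equals(hemi_profile["offset"])):
        raise ValueError("profiles must share offsets")
    ratio = full_profile[["offset"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = full_profile["value"] / hemi_profile["value"]
    ratio["value"] = np.where(hemi_profile["value"] > 0, r, np.nan)
    merged = ratio.merge(
        occupancy_profile[["offset", "value"]], on="offset", suffixes=("", "_occ")
    ).dropna()
    if len(merged) < 3:
        return ratio, np.nan
    x, y = merged["value"].to_numpy(), merged["value_occ"].to_numpy()
    if x.std() == 0 or y.std() == 0:
        return ratio, np.nan
    return ratio, float(stats.pearsonr(x, y).statistic)


def profile_correlation(sig_profile, occupancy_profile) -> float:
    """Pearson r between any signal profile and occupancy, across offsets."""
    merged = sig_profile[["offset", "value"]].merge(
        occupancy_profile[["offset", "value"]], on="offset", suffixes=("_s", "_o")
    ).dropna()
    if len(merged) < 3:
        return np.nan
    x, y = merged["value_s"].to_numpy(), merged["value_o"].to_numpy()
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(stats.pearsonr(x, y).statistic)


def context_density(
    genome,
    centers: dict[str, np.ndarray],
    window: int = 1000,
    step: int = 10,
) -> pd.DataFrame:
    """Dyad-anchor density per offset from centers, normalized to mean 1."""
    from .dyads import find_dyads

    dyads, _ = find_dyads(genome)
    frames = []
    for context, grp in dyads.groupby("context"):
        values = {}
        for chrom, sub in grp.groupby("chrom"):
            p = np.sort(sub["pos"].to_numpy(np.int64))
            values[chrom] = (p, np.ones(p.size))
        prof = center_profile(values, centers, window, step)
        mean = np.nanmean(prof["n"].to_numpy(float))
        prof = prof.assign(
            context=context,
            value=prof["n"] / mean if mean > 0 else np.nan,
        )
        frames.append(prof[["context", "offset", "value", "n"]])
    return pd.concat(frames, ignore_index=True)


def stratified_correlation(
    counts: pd.DataFrame,
    centers: dict[str, np.ndarray],
    labels: pd.DataFrame,
    chrom_sizes: dict[str, int],
    *,
    context: str = "CG",
    window: int = 1000,
    step: int = 10,
    min_centers: int = 10,
    bin_size: int = 1000,
) -> pd.DataFrame:
    """Full/hemi-vs-occupancy correlation computed separately per region stratum.

    Centers are assigned to the ``low``/``high`` stratum of their
    containing bin (from :func:`hemimeth.binning.classify_regions`); for
    each stratum the averaged profiles and the ratio-occupancy Pearson r
    are computed.  Strata with fewer than ``min_centers`` centers are NaN.
    """
    lab_map = {
        (c, s // bin_size): l
        for c, s, l in zip(labels["chrom"], labels["start"], labels["label"])
    }
    signals = dyad_frequency_values(counts, context)
    occ = occupancy_values(centers, chrom_sizes)
    rows = []
    for stratum in ("low", "high"):
        strat_centers = {}
        n_centers = 0
        for chrom, cents in centers.items():
            keep = np.array(
                [lab_map.get((chrom, c // bin_size)) == stratum for c in cents]
            )
            if keep.any():
                strat_centers[chrom] = np.asarray(cents)[keep]
                n_centers += int(keep.sum())
        if n_centers < min_centers:
            logger.warning("stratum %r has %d centers; NA", stratum, n_centers)
            rows.append({"stratum": stratum, "n_centers": n_centers, "r": np.nan})
            continue
        fp = center_profile(signals["full"], strat_centers, window, step)
        hp = center_profile(signals["hemi"], strat_centers, window, step)
        op = center_profile(occ, strat_centers, window, step)
        _, r = ratio_and_correlation(fp, hp, op)
        rows.append({"stratum": stratum, "n_centers": n_centers, "r": r})
    return pd.DataFrame(rows)
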