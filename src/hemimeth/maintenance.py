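"""Maintenance-efficiency models and fits.

Maintenance efficiency is the ratio of full-methylation frequency (P_me)
to total methylation frequency (P_total) of a bin; since replication
distributes methylated cytosines evenly into the daughters, P_total is
the initial hemi-methylation frequency and the ratio measures how much of
it was restored to full methylation by observation time.

Two models are fitted by minimising mean squared error:

* saturation (Michaelis-Menten-like, H3K9me2-depleted regions):
  ``y = E_max * x / (k_m + x)`` where ``E_max`` is the maximum
  maintenance efficiency and ``k_m`` the substrate affinity;
* linear (H3K9me2-enriched regions): ``y = E_base + k_p * x`` with basal
  efficiency ``E_base`` and slope ``k_p``.

The identity ``y = x`` is the fully stochastic limit (two independent de
novo events), against which :func:`stochastic_limit_check` compares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

E_MAX_BOUND = 1.05  # slightly above 1 so boundary estimates stay diagnosable
K_M_BOUNDS = (1e-5, 1.0)


def saturation_model(x, e_max, k_m):
    x = np.asarray(x, dtype=float)
    return e_max * x / (k_m + x)


def linear_model(x, e_base, k_p):
    return e_base + k_p * np.asarray(x, dtype=float)


@dataclass
class MaintenanceFit:
    model: str  # saturation | linear | identity
    params: tuple[float, ...]
    mse: float
    n: int
    converged: bool

    def predict(self, x):
        if self.model == "saturation":
            return saturation_model(x, *self.params)
        if self.model == "linear":
            return linear_model(x, *self.params)
        return np.asarray(x, dtype=float)


def efficiency_points(
    bins: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    stratum: str | None = None,
    *,
    context: str | None = None,
) -> pd.DataFrame:
    """Per-bin (x=P_total, y=P_me/P_total) points for model fitting.

    Bins failing the coverage or 2.5% total-methylation filters are
    excluded; efficiency y is deliberately left uncapped (sampling noise
    can push it above 1 and clipping would bias the fit).  ``labels`` is a
    per-bin region-class table (from
    :func:`hemimeth.binning.classify_regions`) joined on (chrom, start);
    ``stratum`` selects its ``low`` or ``high`` bins.
    """
    df = bins
    if context is not None:
        df = df[df["context"] == context]
    if "filtered" in df:
        df = df[~df["filtered"].astype(bool)]
    if labels is not None:
        lab = labels[["chrom", "start", "label"]]
        df = df.merge(lab, on=["chrom", "start"], how="left")
        if stratum is not None:
            df = df[df["label"] == stratum]
    if df.empty:
        logger.warning("efficiency_points: empty stratum %r", stratum)
        return pd.DataFrame(columns=["chrom", "start", "x", "y", "weight"])
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": df["start"].to_numpy(),
            "x": df["p_total"].to_numpy(float),
            "y": (df["p_full"] / df["p_total"]).to_numpy(float),
            "weight": df["n_dyads"].to_numpy(float),
        }
    )
    return out.reset_index(drop=True)


def _check_points(points):
    x = np.asarray(points["x"], dtype=float)
    y = np.asarray(points["y"], dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 points, got {x.size}")
    if np.unique(x).size < 2:
        raise ValueError("all points share one x value; model not identifiable")
    return x, y


def _weights(points, weighted):
    if not weighted:
        return None
    w = np.asarray(points["weight"], dtype=float)
    return w / w.mean()


def fit_saturation(points: pd.DataFrame, *, weighted: bool = False) -> MaintenanceFit:
    """Fit ``y = E_max x / (k_m + x)`` by multi-start bounded Nelder-Mead.

    The objective is the (optionally dyad-count-weighted) mean squared
    error.  The problem is non-convex in ``k_m``, so starts are spread
    over a log grid; the best local optimum wins.
    """
    x, y = _check_points(points)
    w = _weights(points, weighted)

    def mse(theta):
        r = y - saturation_model(x, *theta)
        return float(np.mean(r * r) if w is None else np.mean(w * r * r))

    best = None
    e0 = float(np.clip(np.max(y), 0.1, E_MAX_BOUND))
    for km0 in np.geomspace(1e-4, 0.5, 5):
        for emax0 in (e0, 0.5):
            res = minimize(
                mse,
                x0=[emax0, km0],
                method="Nelder-Mead",
                bounds=[(0.0, E_MAX_BOUND), K_M_BOUNDS],
                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
    e_max, k_m = (float(v) for v in best.x)
    if e_max > 1:
        logger.warning("fitted E_max %.3f exceeds 1; boundary estimate", e_max)
    return MaintenanceFit(
        model="saturation",
        params=(e_max, k_m),
        mse=float(best.fun),
        n=x.size,
        converged=bool(best.success),
    )


def fit_linear(points: pd.DataFrame, *, weighted: bool = False) -> MaintenanceFit:
    """Closed-form (weighted) least squares for ``y = E_base + k_p x``."""
    x, y = _check_points(points)
    w = _weights(points, weighted)
    ww = np.ones_like(x) if w is None else w
    sw = ww.sum()
    mx = (ww * x).sum() / sw
    my = (ww * y).sum() / sw
    sxx = (ww * (x - mx) ** 2).sum()
    sxy = (ww * (x - mx) * (y - my)).sum()
    k_p = float(sxy / sxx)
    e_base = float(my - k_p * mx)
    r = y - (e_base + k_p * x)
    mse = float(np.mean(ww * r * r) / np.mean(ww))
    return MaintenanceFit(
        model="linear", params=(e_base, k_p), mse=mse, n=x.size, converged=True
    )


def stochastic_limit_check(points: pd.DataFrame) -> dict:
    """How far is the linear fit from the stochastic limit y = x?

    Returns the free-fit parameters, their distance from (0, 1), and the
    MSE of the forced identity model for comparison.
    """
    fit = fit_linear(points)
    x = np.asarray(points["x"], dtype=float)
    y = np.asarray(points["y"], dtype=float)
    identity_mse = float(np.mean((y - x) ** 2))
    e_base, k_p = fit.params
    return {
        "e_base": e_base,
        "k_p": k_p,
        "deviation": (abs(e_base), abs(k_p - 1.0)),
        "free_mse": fit.mse,
        "identity_mse": identity_mse,
        "n": fit.n,
    }


def fit_report(fits: dict[tuple, MaintenanceFit]) -> pd.DataFrame:
    """Tidy table of fits keyed by (context, stratum)."""
    rows = []
    for (context, stratum), f in fits.items():
        rows.append(
            {
                "context": context,
                "stratum": stratum,
                "model": f.model,
                "param1": f.params[0],
                "param2": f.params[1] if len(f.params) > 1 else np.nan,
                "mse": f.mse,
                "n": f.n,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)
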