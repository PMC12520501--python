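"""Exp/Theo ratio curves: how far is each context from stochastic methylation?

Under per-cytosine stochastic deposition the full-methylation frequency of
a bin is (P_total)^2; the log2 Exp/Theo ratio measures the deflection.
CG and CWG dyads sit far above 0 (specific maintenance); CTAG stays near
0 (two independent de novo events); a MET1-loss sample collapses the CG
curve toward the CWG-independent baseline.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

import common
from hemimeth import binning, dyads, exptheo


def curve_for(counts, context, motif=None, label=""):
    sub = counts if motif is None else counts[counts["motif"] == motif]
    bins = binning.aggregate_bins(sub, 1000)
    c = exptheo.exp_theo_curve(bins, context)
    c.insert(0, "sample", label)
    return c


def main():
    genome, chromatin, sites, _ = common.build_scenario()
    frames = []
    for label, params in (
        ("wildtype", common.wildtype_params()),
        ("met1_like", common.met1_params()),
    ):
        _, calls = common.sample_calls(
            genome, chromatin, params, seed_offset=0 if label == "wildtype" else 1
        )
        _, counts, _ = dyads.call_dyads(calls, sites)
        for ctx, motif in (("CG", None), ("CWG", None), ("CWWG", "CTAG")):
            frames.append(curve_for(counts, ctx, motif, label))
    out = pd.concat(frames, ignore_index=True)
    common.write(out, "02_exptheo_curves.tsv")

    summary = (
        out.groupby(["sample", "context"])["log2_ratio"].mean().round(3).unstack()
    )
    print("mean log2 Exp/Theo per context:")
    print(summary.to_string())
    print(
        "CG/CWG sit well above the stochastic line in the wildtype while "
        "MET1 loss pulls the CG curve down; the one-generation snapshot "
        "leaves CTAG at or below the line, since without maintenance its "
        "full methylation needs two independent de novo events"
    )


if __name__ == "__main__":
    main()
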