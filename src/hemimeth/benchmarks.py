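"""Desk-scale benchmark analyses over the synthetic generator.

Each function simulates a dataset under stated study conditions, runs the
corresponding pipeline stage from scratch, and returns the measured
quantities.  These are the package's own calibration studies: caller/truth
equivalence, stochastic-null calibration, model parameter recovery, DMR
error rates and power, strand-concordance and CSG correlation structure,
iSA pairing efficiency, and nucleosome-shielding detection.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import binning, dmr, dyads, exptheo, profiles, strand
from . import simulate as sim
from .maintenance import (
    efficiency_points,
    fit_linear,
    fit_saturation,
    saturation_model,
)

PERFECT_OBS = dict(conversion_rate=1.0, overconversion_rate=0.0, miss_rate=0.0)


def _sub(seed: int, k: int) -> int:
    return int(np.random.default_rng([seed, k]).integers(2**31 - 1))


def dyad_caller_equivalence(seed: int, *, n_molecules: int = 5_000) -> dict:
    """Caller vs generator truth on a 100-kb genome with a perfect observer.

    Every resolved dyad status must match the truth-table recount exactly,
    and per-site status counts must sum to resolved coverage.
    """
    g = sim.make_genome(
        sim.GenomeConfig(chrom_lengths={"chr1": 100_000}), seed=_sub(seed, 1)
    )
    ch = sim.simulate_chromatin(g, sim.ChromatinConfig(), seed=_sub(seed, 2))
    pop = sim.simulate_population(
        g, ch, sim.default_params(), n_molecules, seed=_sub(seed, 3)
    )
    calls = sim.emit_call_table(pop, sim.ObservationParams(**PERFECT_OBS, seed=0))
    d, _ = dyads.find_dyads(g)
    mc, counts, _ = dyads.call_dyads(calls, d)

    truth = pop.truth
    w = truth[truth["strand"] == "W"].rename(columns={"meth": "wm"})
    c = truth[truth["strand"] == "C"].rename(
        columns={"meth": "cm", "pos": "partner_pos"}
    )
    m = d.merge(w[["molecule_id", "chrom", "pos", "wm"]], on=["chrom", "pos"])
    m = m.merge(
        c[["molecule_id", "chrom", "partner_pos", "cm"]],
        on=["molecule_id", "chrom", "partner_pos"],
    )
    m["true_status"] = np.select(
        [m["wm"] & m["cm"], m["wm"] & ~m["cm"], ~m["wm"] & m["cm"]],
        ["full", "hemi_watson", "hemi_crick"],
        default="unme",
    )
    resolved = mc[mc["status"] != "unresolved"]
    joined = resolved.merge(
        m[["molecule_id", "chrom", "pos", "context", "true_status"]],
        on=["molecule_id", "chrom", "pos", "context"],
        how="left",
    )
    n_resolved = len(joined)
    n_mismatch = int((joined["status"] != joined["true_status"]).sum())

    per_site = (
        resolved.groupby(["chrom", "pos", "context"]).size().sort_index()
    )
    cov = counts.set_index(["chrom", "pos", "context"])["coverage"].sort_index()
    conservation_ok = bool(cov.equals(per_site))
    return {
        "n_resolved": n_resolved,
        "n_mismatch": n_mismatch,
        "match_fraction": 1.0 - n_mismatch / n_resolved,
        "counts_conserved": conservation_ok,
    }


def exptheo_null_calibration(
    seed: int, *, n_bins: int = 5_000, dyads_per_bin: int = 45, coverage: int = 15
) -> dict:
    """Independent-mode simulation: every well-filled Exp/Theo group near 0.

    45 dyads per 1-kb bin matches the Arabidopsis CG-dyad density
    (~5.3 M CG dyads over a ~119-Mb genome).
    """
    rng = np.random.default_rng(_sub(seed, 10))
    q = rng.uniform(0.05, 0.6, n_bins)
    cnt = sim.simulate_binned_dyads(n_bins, dyads_per_bin, coverage, q, q, rng)
    bins = binning.aggregate_bins(cnt, 1000)
    curve = exptheo.exp_theo_curve(bins, "CG")
    big = curve[curve["n_bins"] >= 200]
    return {
        "n_groups": len(big),
        "max_abs_log2_ratio": float(big["log2_ratio"].abs().max()),
    }


SATURATION_CONFIGS = [
    (e_max, k_m) for e_max in (0.6, 0.8, 0.93) for k_m in (0.007, 0.05)
]


def saturation_recovery(
    seed: int,
    *,
    n_seeds: int = 20,
    n_bins: int = 5_000,
    dyads_per_bin: int = 20,
    coverage: int = 15,
) -> pd.DataFrame:
    """Fit the saturation model to populations it generated.

    For each (E_max, k_m) configuration, ``n_seeds`` replicate simulations
    are fitted and the mean estimates compared with the generating values.
    P_total is drawn uniformly on [0.03, 0.65], the range over which every
    configuration yields a consistent dyad-status distribution.
    """
    rows = []
    for i, (e_max, k_m) in enumerate(SATURATION_CONFIGS):
        est = []
        for s in range(n_seeds):
            rng = np.random.default_rng(_sub(seed, 100 + 10 * i + s))
            q = rng.uniform(0.03, 0.65, n_bins)
            y = saturation_model(q, e_max, k_m)
            cnt = sim.simulate_binned_dyads(n_bins, dyads_per_bin, coverage, q, y, rng)
            bins = binning.aggregate_bins(cnt, 1000)
            fit = fit_saturation(efficiency_points(bins))
            est.append(fit.params)
        est = np.array(est)
        rows.append(
            {
                "e_max_true": e_max,
                "k_m_true": k_m,
                "e_max_hat": float(est[:, 0].mean()),
                "k_m_hat": float(est[:, 1].mean()),
                "e_max_abs_err": float(abs(est[:, 0].mean() - e_max)),
                "k_m_rel_err": float(abs(est[:, 1].mean() - k_m) / k_m),
                "n_seeds": n_seeds,
            }
        )
    return pd.DataFrame(rows)


def linear_stochastic_limit(
    seed: int, *, n_bins: int = 3_000, dyads_per_bin: int = 20, coverage: int = 15
) -> dict:
    """Independent-mode CTAG simulation: linear fit near the limit (0, 1)."""
    rng = np.random.default_rng(_sub(seed, 20))
    q = rng.uniform(0.05, 0.6, n_bins)
    cnt = sim.simulate_binned_dyads(
        n_bins, dyads_per_bin, coverage, q, q, rng, context="CWWG", motif="CTAG"
    )
    bins = binning.aggregate_bins(cnt, 1000)
    fit = fit_linear(efficiency_points(bins, context="CWWG"))
    return {"e_base": fit.params[0], "k_p": fit.params[1], "n": fit.n}


def dmr_calibration(
    seed: int,
    *,
    n_bins: int = 1_000,
    dyads_per_bin: int = 20,
    coverage: int = 15,
    n_null_seeds: int = 5,
) -> dict:
    """Null call rate, power for a 30-point drop, and the complete-loss rule."""
    null_rates = []
    for s in range(n_null_seeds):
        rng = np.random.default_rng(_sub(seed, 200 + s))
        q = rng.uniform(0.2, 0.8, n_bins)
        y = np.full_like(q, 0.9)
        a = sim.simulate_binned_dyads(n_bins, dyads_per_bin, coverage, q, y, rng)
        b = sim.simulate_binned_dyads(n_bins, dyads_per_bin, coverage, q, y, rng)
        out = dmr.call_dmrs(a, b)
        null_rates.append(out["is_dmr"].mean())

    rng = np.random.default_rng(_sub(seed, 210))
    q = np.full(n_bins, 0.55)
    y = np.full(n_bins, 0.9)
    a = sim.simulate_binned_dyads(n_bins, dyads_per_bin, coverage, q, y, rng)
    pf = y * q - 0.30
    b = sim.simulate_binned_dyads(n_bins, dyads_per_bin, coverage, q, y, rng, p_full=pf)
    power = float(dmr.call_dmrs(a, b)["is_dmr"].mean())

    # complete-loss rule boundaries on deterministic counts
    def loss_flag(n_dyads, wt_freq):
        rows_a, rows_b = [], []
        for i in range(n_dyads):
            base = {
                "chrom": "c",
                "pos": 10 + 20 * i,
                "partner_pos": 11 + 20 * i,
                "context": "CG",
                "motif": "CG",
                "n_hemi_watson": 0,
                "n_hemi_crick": 0,
            }
            nf = int(round(wt_freq * 20))
            rows_a.append({**base, "n_unme": 20 - nf, "n_full": nf})
            rows_b.append({**base, "n_unme": 20, "n_full": 0})
        out = dmr.call_dmrs(pd.DataFrame(rows_a), pd.DataFrame(rows_b))
        return bool(out.iloc[0]["complete_loss"])

    rule_ok = (
        loss_flag(15, 0.5)
        and not loss_flag(10, 0.5)  # needs > 10 dyads
        and not loss_flag(15, 0.25)  # needs > 0.30 change
    )
    return {
        "null_call_rate": float(np.mean(null_rates)),
        "power_30pt_drop": power,
        "complete_loss_rule_exact": rule_ok,
    }


def _population_run(genome, chromatin, params, n_molecules, seed):
    pop = sim.simulate_population(genome, chromatin, params, n_molecules, seed=seed)
    calls = sim.emit_call_table(pop, sim.ObservationParams(**PERFECT_OBS, seed=seed))
    d, csg = dyads.find_dyads(genome)
    mc, counts, _ = dyads.call_dyads(calls, d)
    return pop, calls, mc, counts, csg


def _concordance_genome(seed):
    cfg = sim.GenomeConfig(
        chrom_lengths={"chr1": 100_000},
        base_weights={"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
    )
    g = sim.make_genome(cfg, seed=_sub(seed, 30))
    ch = sim.simulate_chromatin(
        g, sim.ChromatinConfig(het_fraction=0.0), seed=_sub(seed, 31)
    )
    return g, ch


def strand_concordance(seed: int, *, n_molecules: int = 20_000) -> dict:
    """Hemi-same vs hemi-oppo frequency of proximal CG dyads.

    Replication mode (E=0.8, d=0) puts every maintenance-failure 5mC on
    the template strand, forcing same-strand concordance; the independent
    mode has no strand memory and the ratio stays near 1.
    """
    g, ch = _concordance_genome(seed)
    rep = sim.MethylationParams(
        contexts={
            "CG": sim.ContextParams((0.4, 0.4), (0.8, 0.8), 0.0),
            "CWG": sim.ContextParams((0.4, 0.4), (0.8, 0.8), 0.0),
            "CWWG": sim.ContextParams((0.2, 0.2), (0.1, 0.1), 0.0),
            "CCG": sim.ContextParams((0.4, 0.4), (0.2, 0.2), 0.0),
        },
        mode="replication",
    )
    _, _, mc, _, _ = _population_run(g, ch, rep, n_molecules, _sub(seed, 32))
    spec = strand.proximal_status(mc, "CG", "CG").set_index("state")
    same, oppo = (
        float(spec.loc["hemi_same", "frequency"]),
        float(spec.loc["hemi_oppo", "frequency"]),
    )
    rep_ratio = np.inf if oppo == 0 else same / oppo

    _, _, mc2, _, _ = _population_run(
        g, ch, sim.independent_params(0.4), n_molecules, _sub(seed, 33)
    )
    spec2 = strand.proximal_status(mc2, "CG", "CG").set_index("state")
    ind_ratio = float(
        spec2.loc["hemi_same", "frequency"] / spec2.loc["hemi_oppo", "frequency"]
    )
    return {
        "replication_same_oppo_ratio": float(rep_ratio),
        "independent_same_oppo_ratio": ind_ratio,
        "n_pairs_replication": int(spec.loc["hemi_same", "n_pairs"]),
        "n_pairs_independent": int(spec2.loc["hemi_same", "n_pairs"]),
    }


def csg_correlations(seed: int, *, n_molecules: int = 20_000) -> dict:
    """CSG conditional correlations under three generator regimes."""
    g, ch = _concordance_genome(seed)

    def corr_table(params, k, n=n_molecules):
        _, calls, _, _, csg = _population_run(g, ch, params, n, _sub(seed, k))
        trip = strand.csg_triplets(calls, csg)
        return strand.conditional_pearson(trip)

    ind = corr_table(sim.independent_params(0.4), 40)
    defined = ind.dropna(subset=["r"])
    ind_max_scaled = float(
        (defined["r"].abs() * np.sqrt(defined["n"])).max()
    )  # compare against 3

    met1 = sim.MethylationParams(
        contexts={
            "CG": sim.ContextParams((0.4, 0.4), (0.9, 0.9), 0.0),
            "CWG": sim.ContextParams((0.0, 0.0), (0.0, 0.0), 0.0),
            "CWWG": sim.ContextParams((0.0, 0.0), (0.0, 0.0), 0.0),
            "CCG": sim.ContextParams((0.0, 0.0), (0.0, 0.0), 0.0),
        },
        mode="replication",
    )
    m = corr_table(met1, 41, n=n_molecules // 2)
    r_c2c3_c1u = float(
        m.loc[(m["pair"] == "C2-C3") & (m["condition"] == "C1=U"), "r"].iloc[0]
    )

    rep = sim.MethylationParams(
        contexts={
            "CG": sim.ContextParams((0.4, 0.4), (0.85, 0.85), 0.01),
            "CWG": sim.ContextParams((0.3, 0.3), (0.7, 0.7), 0.01),
            "CWWG": sim.ContextParams((0.1, 0.1), (0.1, 0.1), 0.02),
            "CCG": sim.ContextParams((0.35, 0.35), (0.1, 0.1), 0.01),
        },
        mode="replication",
        lineage_spread=0.6,
    )
    r = corr_table(rep, 42)

    def get(pair, cond):
        return float(
            r.loc[(r["pair"] == pair) & (r["condition"] == cond), "r"].iloc[0]
        )

    return {
        "independent_max_abs_r_scaled": ind_max_scaled,
        "met1_r_c2c3_given_c1u": r_c2c3_c1u,
        "replication_r_c1c2_given_c3u": get("C1-C2", "C3=U"),
        "replication_r_c1c3_given_c2u": get("C1-C3", "C2=U"),
        "n_triplets": int(r["n"].sum() // 2),
    }


def isa_benchmark(seed: int, *, n_molecules: int = 5_000) -> dict:
    """Molecule recovery and same-ends enrichment of in silico strand annealing."""
    g = sim.make_genome(
        sim.GenomeConfig(chrom_lengths={"chr1": 200_000}), seed=_sub(seed, 50)
    )
    ch = sim.simulate_chromatin(g, sim.ChromatinConfig(), seed=_sub(seed, 51))
    pop = sim.simulate_population(
        g, ch, sim.default_params(), n_molecules, seed=_sub(seed, 52)
    )
    frags, fcalls = sim.emit_unlinked_fragments(
        pop, sim.ObservationParams(**PERFECT_OBS, seed=_sub(seed, 53))
    )
    # restrict to collision-free coordinates for the recovery figure
    coord_counts = pop.molecules.groupby(["chrom", "start", "end"]).size()
    n_unique = int((coord_counts == 1).sum())
    _, _, report = dyads.isa_pair(frags, fcalls, n_permutations=10, seed=_sub(seed, 54))
    return {
        "recovery_fraction": report["n_pairs"] / len(pop.molecules),
        "recovery_fraction_unique_coords": min(
            1.0, report["n_pairs"] / max(n_unique, 1)
        ),
        "enrichment": float(report["enrichment"]),
        "expected_random_pairs": report["expected_random_pairs"],
    }


def shielding_correlation(
    seed: int, *, n_molecules: int = 30_000, n_replicates: int = 4
) -> dict:
    """Full/hemi-vs-occupancy Pearson r with and without nucleosome shielding.

    The window is half the nucleosome spacing so every position contributes
    to exactly one center (offsets stay independent), and the reported r
    is the mean over replicate populations: across K replicates the
    no-shielding null correlation has standard error ~ 1/sqrt(K * n_offsets).
    """
    g = sim.make_genome(
        sim.GenomeConfig(chrom_lengths={"chr1": 300_000}), seed=_sub(seed, 60)
    )
    ch = sim.simulate_chromatin(
        g,
        sim.ChromatinConfig(het_fraction=0.0, nuc_spacing=180, nuc_jitter=5),
        seed=_sub(seed, 61),
    )
    d, _ = dyads.find_dyads(g)

    def run(shield, k):
        params = sim.MethylationParams(
            contexts={
                "CG": sim.ContextParams((0.4, 0.4), (0.8, 0.8), 0.005),
                "CWG": sim.ContextParams((0.2, 0.2), (0.7, 0.7), 0.005),
                "CWWG": sim.ContextParams((0.05, 0.05), (0.05, 0.05), 0.01),
                "CCG": sim.ContextParams((0.2, 0.2), (0.3, 0.3), 0.005),
            },
            mode="replication",
            nucleosome_shield=shield,
        )
        pop = sim.simulate_population(g, ch, params, n_molecules, seed=_sub(seed, k))
        calls = sim.emit_call_table(
            pop, sim.ObservationParams(**PERFECT_OBS, seed=_sub(seed, k + 1))
        )
        _, counts, _ = dyads.call_dyads(calls, d)
        sig = profiles.dyad_frequency_values(counts, "CG", min_cov=5)
        occ = profiles.occupancy_values(ch.nucleosome_centers, g.chrom_sizes())
        cents = ch.nucleosome_centers
        fp = profiles.center_profile(sig["full"], cents, window=90, step=2)
        hp = profiles.center_profile(sig["hemi"], cents, window=90, step=2)
        op = profiles.center_profile(occ, cents, window=90, step=2)
        _, r = profiles.ratio_and_correlation(fp, hp, op)
        return float(r)

    r_sh = np.mean([run(0.6, 62 + 10 * i) for i in range(n_replicates)])
    r_un = np.mean([run(1.0, 65 + 10 * i) for i in range(n_replicates)])
    return {"r_shielded": float(r_sh), "r_unshielded": float(r_un)}
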