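"""Generator behaviour: genomes, chromatin, populations, observation."""

import numpy as np
import pandas as pd
import pytest

from hemimeth import dyads as dy
from hemimeth import simulate as sim
from conftest import uniform_replication_params


class TestMakeGenome:
    def test_zero_length_rejected(self):
        cfg = sim.GenomeConfig(chrom_lengths={"chr1": 0})
        with pytest.raises(ValueError):
            sim.make_genome(cfg, seed=1)

    def test_negative_weights_rejected(self):
        cfg = sim.GenomeConfig(base_weights={"A": -1, "C": 1, "G": 1, "T": 1})
        with pytest.raises(ValueError):
            sim.make_genome(cfg, seed=1)

    def test_same_seed_same_sequence(self):
        cfg = sim.GenomeConfig(chrom_lengths={"chr1": 5_000})
        a = sim.make_genome(cfg, seed=7)
        b = sim.make_genome(cfg, seed=7)
        assert a.sequences == b.sequences

    def test_spike_in_appended(self, small_genome):
        assert small_genome.spike_in_chrom == "lambda_spike"
        assert len(small_genome.sequences["lambda_spike"]) == 2_000

    def test_cg_density_matches_motif_probability_oracle(self):
        # under i.i.d. base sampling the expected CG-dyad count per position
        # is p_C * p_G; the sampled genome must land within 20% of it
        w = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}
        cfg = sim.GenomeConfig(chrom_lengths={"chr1": 100_000}, base_weights=w)
        g = sim.make_genome(cfg, seed=1)
        dyads, _ = dy.find_dyads(g)
        n_cg = int((dyads["context"] == "CG").sum())
        expected = w["C"] * w["G"] * 100_000
        assert abs(n_cg - expected) / expected < 0.20


class TestChromatin:
    def test_zero_jitter_exactly_periodic(self, small_genome):
        cfg = sim.ChromatinConfig(nuc_spacing=180, nuc_jitter=0)
        ch = sim.simulate_chromatin(small_genome, cfg, seed=3)
        c = ch.nucleosome_centers["chr1"]
        assert np.all(np.diff(c) == 180)

    def test_zero_het_fraction_all_euchromatic(self, small_genome):
        cfg = sim.ChromatinConfig(het_fraction=0.0)
        ch = sim.simulate_chromatin(small_genome, cfg, seed=3)
        for chrom in small_genome.main_chroms:
            assert (ch.region_class[chrom] == sim.EU).all()
            # all values drawn from the low distribution
            assert ch.h3k9me2[chrom].max() < 1.0

    def test_het_enrichment_exceeds_eu(self, small_genome, small_chromatin):
        vals = np.concatenate(list(small_chromatin.h3k9me2.values()))
        cls = np.concatenate(list(small_chromatin.region_class.values()))
        assert (cls == sim.HET).sum() > 0 and (cls == sim.EU).sum() > 0
        assert vals[cls == sim.HET].mean() > vals[cls == sim.EU].mean()

    def test_invalid_spacing_rejected(self, small_genome):
        with pytest.raises(ValueError):
            sim.simulate_chromatin(
                small_genome, sim.ChromatinConfig(nuc_spacing=0), seed=1
            )

    def test_centers_strictly_increasing(self, small_chromatin):
        for c in small_chromatin.nucleosome_centers.values():
            assert np.all(np.diff(c) > 0)


def _dyad_statuses(genome, pop):
    """Ground-truth dyad statuses recomputed by brute-force member pairing."""
    dyads, _ = dy.find_dyads(genome)
    t = pop.truth
    w = t[t["strand"] == "W"][["molecule_id", "chrom", "pos", "meth"]]
    c = t[t["strand"] == "C"][["molecule_id", "chrom", "pos", "meth"]]
    m = dyads.merge(w.rename(columns={"meth": "wm"}), on=["chrom", "pos"])
    m = m.merge(
        c.rename(columns={"meth": "cm", "pos": "partner_pos"}),
        on=["molecule_id", "chrom", "partner_pos"],
    )
    return m


class TestPopulation:
    def test_full_maintenance_no_hemi(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, uniform_replication_params(e=1.0), 500, seed=4
        )
        m = _dyad_statuses(small_genome, pop).merge(
            pop.molecules[["molecule_id", "template_strand"]], on="molecule_id"
        )
        # perfect maintenance: every template-methylated dyad becomes full
        tm = np.where(m["template_strand"] == "W", m["wm"], m["cm"])
        assert (m["wm"] & m["cm"])[tm].all()
        # without cross-dyad CSG coupling no hemi dyad exists at all
        pop2 = sim.simulate_population(
            small_genome,
            flat_chromatin,
            uniform_replication_params(e=1.0, e_ccg=0.0),
            500,
            seed=4,
        )
        m2 = _dyad_statuses(small_genome, pop2)
        m2 = m2[m2["context"].isin(["CG", "CWG", "CWWG"])]
        assert not (m2["wm"] != m2["cm"]).any()

    def test_no_maintenance_all_hemi_on_template(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, uniform_replication_params(e=0.0), 500, seed=5
        )
        m = _dyad_statuses(small_genome, pop)
        assert not (m["wm"] & m["cm"]).any()  # zero full dyads
        hemi = m[m["wm"] != m["cm"]]
        tmpl = hemi.merge(
            pop.molecules[["molecule_id", "template_strand"]], on="molecule_id"
        )
        meth_strand = np.where(tmpl["wm"], "W", "C")
        assert (meth_strand == tmpl["template_strand"]).all()

    def test_hemi_on_template_without_csg_crosstalk(
        self, small_genome, flat_chromatin
    ):
        # with CCG maintenance off, no cytosine can be methylated through a
        # second dyad, so every hemi 5mC sits on the template strand
        p = uniform_replication_params(e=0.8, e_ccg=0.0)
        pop = sim.simulate_population(small_genome, flat_chromatin, p, 800, seed=6)
        m = _dyad_statuses(small_genome, pop)
        m = m[m["context"].isin(["CG", "CWG", "CWWG"])]
        hemi = m[m["wm"] != m["cm"]].merge(
            pop.molecules[["molecule_id", "template_strand"]], on="molecule_id"
        )
        assert len(hemi) > 100
        meth_strand = np.where(hemi["wm"], "W", "C")
        assert (meth_strand == hemi["template_strand"]).all()

    def test_independent_mode_binomial_fractions(self, small_genome, flat_chromatin):
        # q = 0.2: full q^2 = 0.04, hemi 2q(1-q) = 0.32 within 3 SE
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.independent_params(0.2), 30_000, seed=7
        )
        m = _dyad_statuses(small_genome, pop)
        cg = m[m["context"] == "CG"]
        n = len(cg)
        assert n >= 100_000
        f_full = (cg["wm"] & cg["cm"]).mean()
        f_hemi = (cg["wm"] != cg["cm"]).mean()
        assert abs(f_full - 0.04) < 3 * np.sqrt(0.04 * 0.96 / n)
        assert abs(f_hemi - 0.32) < 3 * np.sqrt(0.32 * 0.68 / n)

    def test_full_fraction_monotone_in_efficiency(self, small_genome, flat_chromatin):
        fracs = []
        for e in (0.2, 0.5, 0.8, 1.0):
            pop = sim.simulate_population(
                small_genome,
                flat_chromatin,
                uniform_replication_params(e=e),
                400,
                seed=8,
            )
            m = _dyad_statuses(small_genome, pop)
            fracs.append((m["wm"] & m["cm"]).mean())
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_rejects_nonpositive_molecules(self, small_genome, flat_chromatin):
        with pytest.raises(ValueError):
            sim.simulate_population(
                small_genome, flat_chromatin, sim.default_params(), 0, seed=1
            )

    def test_fragment_lengths_within_range(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 300, seed=9
        )
        lens = pop.molecules["end"] - pop.molecules["start"]
        assert lens.between(100, 200).all()


class TestObservation:
    def test_perfect_observation_equals_truth(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 300, seed=10
        )
        calls = sim.emit_call_table(pop, sim.ObservationParams(1.0, 0.0, 0.0, 1))
        expect = np.where(pop.truth["meth"], "M", "U")
        assert (calls["state"].to_numpy() == expect).all()

    def test_spike_in_apparent_methylation(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 8_000, seed=11
        )
        calls = sim.emit_call_table(pop, sim.ObservationParams(0.995, 0.0, 0.0, 2))
        spike = calls[calls["chrom"] == "lambda_spike"]
        n = len(spike)
        assert n > 2_000
        apparent = (spike["state"] == "M").mean()
        assert abs(apparent - 0.005) < 3 * np.sqrt(0.005 * 0.995 / n)

    def test_call_table_deterministic(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 200, seed=12
        )
        obs = sim.ObservationParams(0.99, 0.01, 0.05, 3)
        a = sim.emit_call_table(pop, obs)
        b = sim.emit_call_table(pop, obs)
        assert a.equals(b)

    def test_unlinked_fragments_shape(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 250, seed=13
        )
        frags, fcalls = sim.emit_unlinked_fragments(
            pop, sim.ObservationParams(1.0, 0.0, 0.0, 4)
        )
        assert len(frags) == 2 * len(pop.molecules)
        assert "molecule_id" not in frags.columns
        # with unique coordinates every W fragment has exactly one C partner
        coords = pop.molecules[["chrom", "start", "end"]].drop_duplicates()
        if len(coords) == len(pop.molecules):
            g = frags.groupby(["chrom", "start", "end"])["strand"].agg(list)
            assert all(sorted(v) == ["C", "W"] for v in g)


class TestBinnedSampler:
    def test_counts_sum_to_coverage(self, rng):
        q = rng.uniform(0.05, 0.6, 100)
        cnt = sim.simulate_binned_dyads(100, 10, 15, q, q, rng)
        total = cnt[["n_unme", "n_hemi_watson", "n_hemi_crick", "n_full"]].sum(axis=1)
        assert (total == 15).all()

    def test_independent_null_matches_binomial(self, rng):
        q = np.full(2_000, 0.3)
        cnt = sim.simulate_binned_dyads(2_000, 20, 15, q, q, rng)
        n_obs = 15 * len(cnt)
        f_full = cnt["n_full"].sum() / n_obs
        f_hemi = (cnt["n_hemi_watson"] + cnt["n_hemi_crick"]).sum() / n_obs
        assert abs(f_full - 0.09) < 3 * np.sqrt(0.09 * 0.91 / n_obs)
        assert abs(f_hemi - 0.42) < 3 * np.sqrt(0.42 * 0.58 / n_obs)
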