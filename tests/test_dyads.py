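"""Dyad-site discovery, status calling, conversion rate, iSA and titration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemimeth import dyads as dy
from hemimeth import simulate as sim
from conftest import uniform_replication_params


def _genome(seq, **kw):
    return sim.GenomeSequence({"c": seq}, **kw)


class TestFindDyads:
    def test_single_cg(self):
        d, _ = dy.find_dyads(_genome("ACGT"))
        cg = d[d["context"] == "CG"]
        assert len(cg) == 1
        assert (cg.iloc[0]["pos"], cg.iloc[0]["partner_pos"]) == (1, 2)

    def test_cwg_and_cwwg(self):
        d, _ = dy.find_dyads(_genome("CAG"))
        assert list(d["context"]) == ["CWG"]
        assert (d.iloc[0]["pos"], d.iloc[0]["partner_pos"]) == (0, 2)
        d, _ = dy.find_dyads(_genome("CATG"))
        assert list(d["context"]) == ["CWWG"]
        assert (d.iloc[0]["pos"], d.iloc[0]["partner_pos"]) == (0, 3)

    def test_csg_site_and_nested_cg(self):
        d, csg = dy.find_dyads(_genome("ACCGT"))
        assert len(csg) == 1
        row = csg.iloc[0]
        assert (row["c1_pos"], row["c1_strand"]) == (1, "W")
        assert (row["c2_pos"], row["c2_strand"]) == (2, "W")
        assert (row["c3_pos"], row["c3_strand"]) == (3, "C")
        cg = d[d["context"] == "CG"]
        assert len(cg) == 1 and cg.iloc[0]["pos"] == 2
        ccg = d[d["context"] == "CCG"]
        assert len(ccg) == 1
        assert (ccg.iloc[0]["pos"], ccg.iloc[0]["partner_pos"]) == (1, 3)

    def test_mirrored_csg_from_watson_cgg(self):
        _, csg = dy.find_dyads(_genome("ACGGT"))
        assert len(csg) == 1
        row = csg.iloc[0]
        assert row["orientation"] == "C"
        assert (row["c1_pos"], row["c1_strand"]) == (3, "C")
        assert (row["c3_pos"], row["c3_strand"]) == (1, "W")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            dy.find_dyads(_genome("ACGN"))

    @settings(max_examples=20, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=400))
    def test_matches_window_scan_oracle(self, seq):
        d, _ = dy.find_dyads(_genome(seq))
        w = set("AT")
        expect = set()
        for i in range(len(seq)):
            s = seq[i : i + 4]
            if s[:2] == "CG":
                expect.add((i, i + 1, "CG"))
            if len(s) >= 3 and s[0] == "C" and s[1] in w and s[2] == "G":
                expect.add((i, i + 2, "CWG"))
            if len(s) == 4 and s[0] == "C" and s[1] in w and s[2] in w and s[3] == "G":
                expect.add((i, i + 3, "CWWG"))
            if len(s) >= 3 and s[:3] in ("CCG", "CGG"):
                expect.add((i, i + 2, "CCG"))
        got = set(zip(d["pos"], d["partner_pos"], d["context"]))
        assert got == expect


def _calls(rows):
    return pd.DataFrame(rows, columns=["molecule_id", "chrom", "pos", "strand", "state"])


class TestCallDyads:
    @pytest.fixture()
    def cg_sites(self):
        d, _ = dy.find_dyads(_genome("ACGT"))
        return d

    @pytest.mark.parametrize(
        "w_state,c_state,status",
        [
            ("M", "M", "full"),
            ("M", "U", "hemi_watson"),
            ("U", "M", "hemi_crick"),
            ("U", "U", "unme"),
            ("M", ".", "unresolved"),
        ],
    )
    def test_status_mapping(self, cg_sites, w_state, c_state, status):
        calls = _calls([(1, "c", 1, "W", w_state), (1, "c", 2, "C", c_state)])
        mc, counts, _ = dy.call_dyads(calls, cg_sites)
        assert mc.iloc[0]["status"] == status
        if status != "unresolved":
            assert counts.iloc[0][f"n_{status}"] == 1

    def test_off_dyad_calls_ignored(self, cg_sites):
        calls = _calls(
            [(1, "c", 1, "W", "M"), (1, "c", 2, "C", "M"), (1, "c", 3, "W", "M")]
        )
        _, counts, tally = dy.call_dyads(calls, cg_sites)
        assert tally["n_ignored_positions"] == 1
        assert counts.iloc[0]["n_full"] == 1

    def test_conflicting_duplicates_become_missing(self, cg_sites):
        calls = _calls(
            [(1, "c", 1, "W", "M"), (1, "c", 1, "W", "U"), (1, "c", 2, "C", "M")]
        )
        mc, counts, _ = dy.call_dyads(calls, cg_sites)
        assert mc.iloc[0]["status"] == "unresolved"
        assert counts.empty

    def test_counts_match_truth_recount(self, small_genome, flat_chromatin):
        """Caller counts equal a brute-force recount from generator truth."""
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 1_000, seed=21
        )
        calls = sim.emit_call_table(pop, sim.ObservationParams(1.0, 0.0, 0.0, 1))
        d, _ = dy.find_dyads(small_genome)
        _, counts, _ = dy.call_dyads(calls, d)

        t = pop.truth
        w = t[t["strand"] == "W"].rename(columns={"meth": "wm"})
        c = t[t["strand"] == "C"].rename(columns={"meth": "cm", "pos": "partner_pos"})
        m = d.merge(w[["molecule_id", "chrom", "pos", "wm"]], on=["chrom", "pos"])
        m = m.merge(
            c[["molecule_id", "chrom", "partner_pos", "cm"]],
            on=["molecule_id", "chrom", "partner_pos"],
        )
        oracle = (
            m.assign(
                n_full=(m["wm"] & m["cm"]).astype(int),
                n_hemi_watson=(m["wm"] & ~m["cm"]).astype(int),
                n_hemi_crick=(~m["wm"] & m["cm"]).astype(int),
                n_unme=(~m["wm"] & ~m["cm"]).astype(int),
            )
            .groupby(["chrom", "pos", "context"])[dy.COUNT_COLS]
            .sum()
        )
        got = counts.set_index(["chrom", "pos", "context"])[dy.COUNT_COLS]
        oracle = oracle.sort_index()
        got = got.sort_index()
        pd.testing.assert_frame_equal(got, oracle, check_dtype=False)

    def test_status_conservation(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 500, seed=22
        )
        calls = sim.emit_call_table(pop, sim.ObservationParams(0.99, 0.01, 0.1, 2))
        d, _ = dy.find_dyads(small_genome)
        mc, counts, _ = dy.call_dyads(calls, d)
        resolved = (
            mc[mc["status"] != "unresolved"]
            .groupby(["chrom", "pos", "context"])
            .size()
        )
        assert (
            counts.set_index(["chrom", "pos", "context"])["coverage"]
            .sort_index()
            .equals(resolved.sort_index())
        )

    def test_strand_swap_symmetry(self):
        # a genome of isolated CG/CWG/CWWG dyads (no shared cytosines)
        unit = "AACGTTTAACAGTTTAACTAGTTT"
        g = _genome(unit * 20)
        d, _ = dy.find_dyads(g)
        assert set(d["context"]) == {"CG", "CWG", "CWWG"}
        rng = np.random.default_rng(5)
        rows = []
        for mol in range(60):
            for _, site in d.sample(8, random_state=int(rng.integers(1e9))).iterrows():
                ws, cs = rng.choice(["M", "U"], 2)
                rows.append((mol, "c", site["pos"], "W", ws))
                rows.append((mol, "c", site["partner_pos"], "C", cs))
        calls = _calls(rows)
        _, counts, _ = dy.call_dyads(calls, d)
        # swap the member states: Watson call takes the Crick state and vice versa
        site_map_w = d.set_index("pos")["partner_pos"]
        site_map_c = d.set_index("partner_pos")["pos"]
        swapped = calls.copy()
        is_w = swapped["strand"] == "W"
        swapped.loc[is_w, "pos"] = swapped.loc[is_w, "pos"].map(site_map_w)
        swapped.loc[~is_w, "pos"] = swapped.loc[~is_w, "pos"].map(site_map_c)
        swapped["strand"] = np.where(is_w, "C", "W")
        _, counts2, _ = dy.call_dyads(swapped, d)
        a = counts.set_index(["chrom", "pos", "context"]).sort_index()
        b = counts2.set_index(["chrom", "pos", "context"]).sort_index()
        assert (a["n_full"] == b["n_full"]).all()
        assert (a["n_unme"] == b["n_unme"]).all()
        assert (a["n_hemi_watson"] == b["n_hemi_crick"]).all()
        assert (a["n_hemi_crick"] == b["n_hemi_watson"]).all()


class TestConversionRate:
    def test_all_converted(self):
        calls = _calls([(1, "spk", i, "W", "U") for i in range(10)])
        assert dy.conversion_rate(calls, "spk") == 1.0

    def test_ratio(self):
        rows = [(1, "spk", i, "W", "U") for i in range(995)]
        rows += [(1, "spk", 1000 + i, "W", "M") for i in range(5)]
        assert dy.conversion_rate(_calls(rows), "spk") == pytest.approx(0.995)

    def test_no_spike_calls_raises(self):
        with pytest.raises(ValueError):
            dy.conversion_rate(_calls([(1, "c", 1, "W", "U")]), "spk")

    def test_estimator_inverts_simulation(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 8_000, seed=23
        )
        calls = sim.emit_call_table(pop, sim.ObservationParams(0.99, 0.0, 0.0, 3))
        est = dy.conversion_rate(calls, "lambda_spike")
        n = (calls["chrom"] == "lambda_spike").sum()
        assert abs(est - 0.99) < 3 * np.sqrt(0.99 * 0.01 / n)


class TestIsa:
    def test_single_pair(self):
        frags = pd.DataFrame(
            {
                "frag_id": [0, 1],
                "chrom": ["c", "c"],
                "start": [10, 10],
                "end": [110, 110],
                "strand": ["W", "C"],
            }
        )
        pairs, _, rep = dy.isa_pair(frags, n_permutations=2, seed=1)
        assert rep["n_pairs"] == 1 and rep["n_dropped"] == 0

    def test_same_strand_never_pairs(self):
        frags = pd.DataFrame(
            {
                "frag_id": [0, 1],
                "chrom": ["c", "c"],
                "start": [10, 10],
                "end": [110, 110],
                "strand": ["W", "W"],
            }
        )
        pairs, _, rep = dy.isa_pair(frags, n_permutations=2, seed=1)
        assert rep["n_pairs"] == 0

    def test_collision_losses_match_matching_oracle(
        self, small_genome, flat_chromatin
    ):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 400, seed=24
        )
        # inject coordinate duplicates: molecules 0-19 clone coords of 20-39
        mols = pop.molecules.copy()
        for col in ("chrom", "start", "end"):
            mols.loc[mols.index[:20], col] = mols.loc[mols.index[20:40], col].to_numpy()
        pop2 = sim.MoleculeSet(molecules=mols, truth=pop.truth)
        frags, _ = sim.emit_unlinked_fragments(
            pop2, sim.ObservationParams(1.0, 0.0, 0.0, 5)
        )
        pairs, _, rep = dy.isa_pair(frags, n_permutations=2, seed=2)
        # oracle: per coordinate group, min(#W, #C) pairs
        oracle = (
            frags.groupby(["chrom", "start", "end"])["strand"]
            .agg(lambda s: min((s == "W").sum(), (s == "C").sum()))
            .sum()
        )
        assert rep["n_pairs"] == oracle

    def test_paired_calls_recover_dyad_statuses(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 600, seed=25
        )
        frags, fcalls = sim.emit_unlinked_fragments(
            pop, sim.ObservationParams(1.0, 0.0, 0.0, 6)
        )
        pairs, pcalls, rep = dy.isa_pair(frags, fcalls, n_permutations=2, seed=3)
        d, _ = dy.find_dyads(small_genome)
        _, counts_isa, _ = dy.call_dyads(pcalls, d)
        calls = sim.emit_call_table(pop, sim.ObservationParams(1.0, 0.0, 0.0, 6))
        _, counts_direct, _ = dy.call_dyads(calls, d)
        # without coordinate collisions iSA recovers nearly every molecule
        frac = rep["n_pairs"] / len(pop.molecules)
        assert frac >= 0.99
        if frac == 1.0:
            a = counts_isa.set_index(["chrom", "pos", "context"])[dy.COUNT_COLS]
            b = counts_direct.set_index(["chrom", "pos", "context"])[dy.COUNT_COLS]
            assert a.sort_index().equals(b.sort_index())


class TestTitration:
    def test_full_target_all_ratios_one(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 2_000, seed=26
        )
        calls = sim.emit_call_table(pop, sim.ObservationParams(1.0, 0.0, 0.0, 7))
        d, _ = dy.find_dyads(small_genome)
        _, counts, _ = dy.call_dyads(calls, d)
        achieved = counts["coverage"].mean()
        out = dy.titrate_coverage(calls, d, [achieved], [1000], seed=1)
        assert out.iloc[0]["median_ratio"] == pytest.approx(1.0)
        assert out.iloc[0]["q25"] == pytest.approx(1.0)

    def test_empty_resolutions_empty_report(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 200, seed=27
        )
        calls = sim.emit_call_table(pop, sim.ObservationParams(1.0, 0.0, 0.0, 8))
        d, _ = dy.find_dyads(small_genome)
        assert dy.titrate_coverage(calls, d, [0.1], [], seed=1).empty

    def test_target_above_achieved_rejected(self, small_genome, flat_chromatin):
        pop = sim.simulate_population(
            small_genome, flat_chromatin, sim.default_params(), 200, seed=28
        )
        calls = sim.emit_call_table(pop, sim.ObservationParams(1.0, 0.0, 0.0, 9))
        d, _ = dy.find_dyads(small_genome)
        with pytest.raises(ValueError):
            dy.titrate_coverage(calls, d, [1e6], [1000], seed=1)
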