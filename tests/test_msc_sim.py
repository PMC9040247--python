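import math
from collections import Counter

import numpy as np
import pytest

from phylodiscord import msc_sim, treekit
from phylodiscord.msc_sim import (Alignment, NoClosedFormError, Pulse, RateSpec,
                                  Scenario, ScenarioError, expected_topology_freq,
                                  extract_site_patterns, scale_branch_lengths,
                                  simulate_alignment, simulate_gene_trees)
from phylodiscord.treekit import parse_newick


def three_taxon_scenario(T, loci, seed, **kw):
    """Triplet + outgroup with internal branch of T coalescent units."""
    newick = f"(((A:1,B:1):{T},C:{1 + T}):8,O:{9 + T});"
    return Scenario(species_tree=parse_newick(newick), outgroup="O",
                    loci=loci, seed=seed, coal_scale=1.0, **kw)


def sister_counts(trees, outgroup):
    out = Counter()
    for t in trees:
        rooted = treekit.reroot_on_outgroup(t, outgroup)
        for n in rooted.root.postorder():
            if not n.is_leaf() and len(n.leaf_labels()) == 2:
                out[frozenset(n.leaf_labels())] += 1
                break
    return out


class TestScenarioValidation:
    def test_gamma_out_of_range(self):
        with pytest.raises(ScenarioError):
            Scenario(species_tree=parse_newick("((A:1,B:1):1,C:2);"),
                     pulses=[Pulse("A", "B", 0.5, 1.5)])

    def test_pulse_time_outside_branch(self):
        with pytest.raises(ScenarioError):
            Scenario(species_tree=parse_newick("((A:1,B:1):1,C:2);"),
                     pulses=[Pulse("A", "B", 1.5, 0.5)])  # A,B branches end at 1

    def test_unknown_pulse_branch(self):
        with pytest.raises(ScenarioError):
            Scenario(species_tree=parse_newick("((A:1,B:1):1,C:2);"),
                     pulses=[Pulse("Z", "B", 0.5, 0.5)])

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ScenarioError):
            Scenario(species_tree=parse_newick("((A:1,B:3):1,C:2);"))

    def test_bad_rate(self):
        with pytest.raises(ScenarioError):
            Scenario(species_tree=parse_newick("((A:1,B:1):1,C:2);"),
                     rates=[RateSpec(frozenset({"A"}), -2.0)])

    def test_validation_before_sampling(self):
        sc = Scenario(species_tree=parse_newick("((A:1,B:1):1,C:2);"))
        sc.loci = -5
        with pytest.raises(ScenarioError):
            simulate_gene_trees(sc)


class TestGeneTreeSimulation:
    def test_star_tree_uniform_topologies(self):
        eps = 1e-9
        sc = Scenario(species_tree=parse_newick(
            f"(((A:1,B:1):{eps},C:{1 + eps}):8,O:{9 + eps});"),
            loci=10_000, seed=11, coal_scale=1.0)
        counts = sister_counts(simulate_gene_trees(sc).trees, "O")
        n = sum(counts.values())
        sd = math.sqrt(n * (1 / 3) * (2 / 3))
        for pair in (("A", "B"), ("A", "C"), ("B", "C")):
            assert abs(counts[frozenset(pair)] - n / 3) < 3 * sd

    def test_discordance_closed_form_T1(self):
        sc = three_taxon_scenario(1.0, 10_000, seed=7)
        counts = sister_counts(simulate_gene_trees(sc).trees, "O")
        n = sum(counts.values())
        p = math.exp(-1.0) / 3
        sd = math.sqrt(n * p * (1 - p))
        for pair in (("A", "C"), ("B", "C")):
            assert abs(counts[frozenset(pair)] - n * p) < 3 * sd

    @pytest.mark.parametrize("T", [0.1, 0.5, 2.0])
    def test_discordance_closed_form_grid(self, T):
        sc = three_taxon_scenario(T, 10_000, seed=int(T * 100))
        counts = sister_counts(simulate_gene_trees(sc).trees, "O")
        n = sum(counts.values())
        p = math.exp(-T) / 3
        sd = math.sqrt(n * p * (1 - p))
        for pair in (("A", "C"), ("B", "C")):
            assert abs(counts[frozenset(pair)] - n * p) < 3 * sd

    def test_gamma_one_pulse_reroutes_everything(self):
        sc = Scenario(species_tree=parse_newick("(((A:1,B:1):1,C:2):8,O:10);"),
                      pulses=[Pulse(donor="C", recipient="B", time=0.5, gamma=1.0)],
                      loci=3000, seed=3, coal_scale=1.0)
        counts = sister_counts(simulate_gene_trees(sc).trees, "O")
        # B always moves into C's branch at t=0.5: expected BC sister frequency
        # is the closed form with T = 2 - 0.5
        n = sum(counts.values())
        p = 1 - (2 / 3) * math.exp(-1.5)
        sd = math.sqrt(n * p * (1 - p))
        assert abs(counts[frozenset(("B", "C"))] - n * p) < 3.5 * sd

    def test_reproducibility_and_per_locus_streams(self):
        sc1 = three_taxon_scenario(1.0, 50, seed=99)
        sc2 = three_taxon_scenario(1.0, 50, seed=99)
        g1 = simulate_gene_trees(sc1)
        g2 = simulate_gene_trees(sc2)
        assert g1.content_hash() == g2.content_hash()
        # locus i is invariant to total locus count
        sc3 = three_taxon_scenario(1.0, 10, seed=99)
        g3 = simulate_gene_trees(sc3)
        for a, b in zip(g3.trees, g1.trees[:10]):
            assert treekit.write_newick(a, canonical=True) == \
                treekit.write_newick(b, canonical=True)

    def test_default_scenarios_match_study_shape(self):
        tribe = msc_sim.tribe_level_scenario(seed=1)
        assert tribe.loci == 2608
        assert len(tribe.species_tree.leaf_labels()) == 6
        sub = msc_sim.subtribe_level_scenario(seed=1)
        assert sub.loci == 1865
        assert len(sub.species_tree.leaf_labels()) == 5
        gts = simulate_gene_trees(msc_sim.tribe_level_scenario(seed=1, loci=30))
        assert len(gts) == 30
        assert all(t.leaf_labels() == tribe.species_tree.leaf_labels() for t in gts)


class TestScaleBranchLengths:
    def test_identity_multiplier_scales_by_mu(self):
        sc = three_taxon_scenario(1.0, 20, seed=5, mu=0.01)
        gts = simulate_gene_trees(sc)
        scaled = scale_branch_lengths(gts, sc)
        for coal, subs in zip(gts.trees, scaled.trees):
            for nc, ns in zip(coal.root.postorder(), subs.root.postorder()):
                if nc is coal.root:
                    continue
                assert math.isclose(ns.length, nc.length * sc.coal_scale * sc.mu,
                                    rel_tol=1e-9)
        assert scaled.unit == "subs/site"

    def test_mu_zero_all_zero(self):
        sc = three_taxon_scenario(1.0, 5, seed=5, mu=0.0)
        scaled = scale_branch_lengths(simulate_gene_trees(sc), sc)
        for t in scaled.trees:
            assert all((n.length or 0.0) == 0.0 for n in t.root.postorder())

    def test_clade_multiplier_root_to_tip_ratio(self):
        # long pendant branches dominate the root-to-tip path, so the fast
        # clade's mean root-to-tip should approach r x background
        r = 5.58123
        sc = Scenario(species_tree=parse_newick("(((A:50,B:50):1,C:51):1,O:52);"),
                      rates=[RateSpec(frozenset({"A"}), r)],
                      loci=300, seed=8, coal_scale=1.0, mu=1e-3)
        scaled = scale_branch_lengths(simulate_gene_trees(sc), sc)
        ratios = []
        for t in scaled.trees:
            r2t = treekit.root_to_tip_lengths(t)
            ratios.append(r2t["A"] / r2t["B"])
        assert abs(np.mean(ratios) - r) / r < 0.10


class TestSimulateAlignment:
    def test_zero_length_star_identical(self):
        t = parse_newick("(A:0,B:0,C:0);")
        aln = simulate_alignment(t, 100, seed=0)
        assert (aln.matrix == aln.matrix[0]).all()

    def test_jc69_p_distance_closed_form(self):
        d = 0.3
        t = parse_newick(f"(A:{d / 2},B:{d / 2});")
        aln = simulate_alignment(t, 100_000, seed=2)
        p_obs = float((aln.row("A") != aln.row("B")).mean())
        p_exp = 0.75 * (1 - math.exp(-4 * d / 3))
        sd = math.sqrt(p_exp * (1 - p_exp) / 100_000)
        assert abs(p_obs - p_exp) < 3 * sd

    def test_hky_p_distance_sane(self):
        d = 0.2
        t = parse_newick(f"(A:{d / 2},B:{d / 2});")
        aln = simulate_alignment(t, 50_000, model="HKY", seed=2, kappa=4.0)
        p_obs = float((aln.row("A") != aln.row("B")).mean())
        assert 0.5 * d < p_obs < d  # multiple hits push p below d

    def test_deterministic_given_seed(self):
        t = parse_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        a1 = simulate_alignment(t, 500, seed=7)
        a2 = simulate_alignment(t, 500, seed=7)
        assert (a1.matrix == a2.matrix).all()

    def test_bad_length(self):
        with pytest.raises(ValueError):
            simulate_alignment(parse_newick("(A:1,B:1);"), 0)

    def test_fasta_round_trip(self, tmp_path):
        t = parse_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        aln = simulate_alignment(t, 200, seed=7)
        path = tmp_path / "aln.fasta"
        aln.to_fasta(path)
        back = Alignment.from_fasta(path)
        assert back.taxa == aln.taxa
        assert (back.matrix == aln.matrix).all()


class TestSitePatterns:
    def _aln(self, rows):
        code = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
        taxa = list(rows)
        mat = np.array([[code[ch] for ch in seq] for seq in rows.values()],
                       dtype=np.uint8)
        return Alignment(taxa=taxa, matrix=mat)

    def test_invariant_alignment_empty(self):
        aln = self._aln({"A": "AAAA", "B": "AAAA", "O": "AAAA"})
        with pytest.warns(UserWarning):
            pats = extract_site_patterns(aln, "O")
        assert pats.n_sites == 0

    def test_polarization_rule(self):
        aln = self._aln({"P1": "G", "P2": "G", "P3": "A", "O": "A"})
        pats = extract_site_patterns(aln, "O")
        assert pats.n_sites == 1
        assert [int(pats.row(t)[0]) for t in ("P1", "P2", "P3", "O")] == [1, 1, 0, 0]

    def test_triallelic_and_gapped_dropped(self):
        aln = self._aln({"A": "GCA", "B": "CC-", "O": "ACA"})
        with pytest.warns(UserWarning):
            pats = extract_site_patterns(aln, "O")
        assert pats.n_sites == 0  # site1 triallelic, site2 invariant, site3 gapped

    def test_missing_outgroup(self):
        with pytest.raises(ValueError):
            extract_site_patterns(self._aln({"A": "A"}), "O")

    def test_tsv_round_trip(self, tmp_path):
        aln = self._aln({"P1": "GA", "P2": "GG", "O": "AG"})
        pats = extract_site_patterns(aln, "O")
        path = tmp_path / "p.tsv"
        pats.to_tsv(path)
        back = msc_sim.SitePatterns.from_tsv(path)
        assert back.taxa == pats.taxa
        assert (back.matrix == pats.matrix).all()


class TestExpectedTopologyFreq:
    def test_T_large_concordant(self):
        sc = three_taxon_scenario(40.0, 1, seed=0)
        freqs = expected_topology_freq(sc, ("A", "B", "C"))
        assert math.isclose(freqs[frozenset(("A", "B"))], 1.0, abs_tol=1e-12)

    def test_T_zero_uniform(self):
        sc = three_taxon_scenario(1e-12, 1, seed=0)
        freqs = expected_topology_freq(sc, ("A", "B", "C"))
        for v in freqs.values():
            assert math.isclose(v, 1 / 3, abs_tol=1e-9)

    def test_T_half_value(self):
        sc = three_taxon_scenario(0.5, 1, seed=0)
        freqs = expected_topology_freq(sc, ("A", "B", "C"))
        assert math.isclose(freqs[frozenset(("A", "C"))],
                            math.exp(-0.5) / 3, rel_tol=1e-12)
        assert math.isclose(freqs[frozenset(("A", "C"))], 0.2022, abs_tol=5e-4)

    def test_single_pulse_mixture_matches_simulation(self):
        sc = Scenario(species_tree=parse_newick("(((A:1,B:1):1,C:2):8,O:10);"),
                      pulses=[Pulse(donor="C", recipient="B", time=0.5, gamma=0.4)],
                      loci=8000, seed=21, coal_scale=1.0)
        freqs = expected_topology_freq(sc, ("A", "B", "C"))
        counts = sister_counts(simulate_gene_trees(sc).trees, "O")
        n = sum(counts.values())
        for pair, f in freqs.items():
            sd = math.sqrt(n * f * (1 - f))
            assert abs(counts[pair] - n * f) < 3.5 * sd

    def test_multi_pulse_no_closed_form(self):
        sc = Scenario(species_tree=parse_newick("(((A:1,B:1):1,C:2):8,O:10);"),
                      pulses=[Pulse("C", "B", 0.5, 0.2), Pulse("A", "B", 0.7, 0.2)],
                      loci=1, seed=0, coal_scale=1.0)
        with pytest.raises(NoClosedFormError):
            expected_topology_freq(sc, ("A", "B", "C"))

    def test_scenario_yaml_round_trip(self, tmp_path):
        sc = msc_sim.tribe_level_scenario(seed=4)
        path = tmp_path / "scenario.yaml"
        msc_sim.save_scenario(sc, path)
        back = msc_sim.load_scenario(path)
        assert back.content_hash() == sc.content_hash()
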