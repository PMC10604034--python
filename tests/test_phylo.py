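import math

import dendropy
import numpy as np
import pytest

from mitocomp.phylo import (Calibration, CalibrationConflictError,
                            SubstitutionModel, bic_rank, concatenate_pcgs,
                            gtr_model, jc_model, k2p_distance, k2p_matrix,
                            k2p_model, loglikelihood, neighbor_joining,
                            optimize_branch_lengths, reltime_date)
from mitocomp.simulate import (EvolSpec, apply_rate_noise, evolve_alignment,
                               evolve_pair, simulate_clock_tree)


class TestK2P:
    def test_identical_sequences(self):
        r = k2p_distance("ACGTACGT", "ACGTACGT")
        assert (r.P, r.Q, r.d) == (0.0, 0.0, 0.0)

    def test_transition_only_closed_form(self):
        a = "A" * 90 + "G" * 10
        b = "A" * 100
        r = k2p_distance(a, b)
        assert r.d == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)

    def test_pairwise_deletion(self):
        r = k2p_distance("ACGTN-", "ACGAAC")
        assert r.n_sites == 4  # N and gap columns dropped

    def test_saturation_flagged_not_raised(self):
        a = "AG" * 50
        b = "GA" * 50
        r = k2p_distance(a, b)
        assert not r.valid
        assert r.d is None
        assert r.P == 1.0

    def test_simulated_distance_within_3se(self):
        aln = evolve_pair(0.15, k2p_model(kappa=4.0), 10000, seed=3)
        r = k2p_distance(aln["A"], aln["B"])
        assert abs(r.d - 0.15) < 3 * r.se

    def test_zero_comparable_sites(self):
        with pytest.raises(ValueError):
            k2p_distance("NNN", "ACG")


class TestConcatenation:
    def test_two_genes_spans(self):
        genes = {"g1": {"A": "ACACAC", "B": "ACACAA"},
                 "g2": {"A": "GGGTTTGGG", "B": "GGGTTTGGA"}}
        aln, spans = concatenate_pcgs(genes, ["g1", "g2"])
        assert len(aln["A"]) == 15
        assert spans == {"g1": (1, 6), "g2": (7, 15)}

    def test_missing_gene_errors_with_names(self):
        genes = {"g1": {"A": "ACA", "B": "ACC"}, "g2": {"A": "GGG"}}
        with pytest.raises(ValueError, match="B.*g2"):
            concatenate_pcgs(genes, ["g1", "g2"])

    def test_taxa_order_invariance(self):
        g = {"g1": {"A": "AC", "B": "AA", "C": "CC"}}
        aln1, _ = concatenate_pcgs(g, ["g1"])
        g2 = {"g1": {"C": "CC", "A": "AC", "B": "AA"}}
        aln2, _ = concatenate_pcgs(g2, ["g1"])
        assert aln1 == dict(aln2)

    def test_thirteen_partition_study_shape(self):
        rng = np.random.default_rng(0)
        taxa = [f"sp{i}" for i in range(15)]
        genes = {f"pcg{k}": {t: "".join(rng.choice(list("ACGT"), size=30))
                             for t in taxa} for k in range(13)}
        aln, spans = concatenate_pcgs(genes, sorted(genes))
        assert len(spans) == 13
        assert all(len(s) == 13 * 30 for s in aln.values())


def _splits(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial bipartitions, each represented by the side not containing
    the lexicographically smallest taxon (rooting-insensitive)."""
    taxa = {l.taxon.label for l in tree.leaf_node_iter()}
    anchor = min(taxa)
    out = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        side = frozenset(taxa - clade) if anchor in clade else clade
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(side)
    return out


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # tree: ((A:1,B:2):1,(C:3,D:4)) with internal edge 1
        D = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], float)
        tree = neighbor_joining(D, ["A", "B", "C", "D"])
        assert _splits(tree) == {frozenset({"C", "D"})}
        lengths = {l.taxon.label: l.edge.length
                   for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxon_resolution(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = neighbor_joining(D, ["A", "B", "C"])
        lengths = {l.taxon.label: l.edge.length
                   for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["A", "B"])

    def test_negative_lengths_clamped_with_warning(self):
        # d(A,B) > d(A,C) + d(B,C) forces a negative central branch
        D = np.array([[0.0, 5.0, 2.0],
                      [5.0, 0.0, 2.0],
                      [2.0, 2.0, 0.0]])
        with pytest.warns(UserWarning, match="clamped"):
            tree = neighbor_joining(D, list("ABC"))
        for e in tree.preorder_edge_iter():
            assert e.length is None or e.length >= 0

    def test_matches_dendropy_on_random_matrix(self):
        """Dual route: package NJ vs dendropy's NJ on a noisy matrix."""
        rng = np.random.default_rng(8)
        n = 6
        base = rng.uniform(0.1, 0.5, size=(n, n))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"t{i}" for i in range(n)]
        mine = neighbor_joining(D, labels)
        import io as _io
        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(f"{D[i, j]:.8f}" for j in range(n))
            for i in range(n))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            _io.StringIO(csv), delimiter=",")
        theirs = pdm.nj_tree()
        assert _splits(mine) == _splits(theirs)

    def test_topology_recovery_from_simulation(self):
        tree, _ = simulate_clock_tree(8, seed=11, depth=0.3)
        aln, _ = evolve_alignment(EvolSpec(tree=tree, model=jc_model(),
                                           sites=5000, seed=12))
        D, labels = k2p_matrix(aln)
        nj = neighbor_joining(D, labels)
        ref = dendropy.Tree.get(data=tree.as_string(schema="newick"),
                                schema="newick")
        assert _splits(nj) == _splits(ref)


def _brute_force_lnl(tree, alignment, model):
    """Independent likelihood oracle: explicit sum over all internal-state
    assignments, using transition matrices only."""
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    rates, weights = model.rate_categories()
    pi = model.freqs
    L = len(next(iter(alignment.values())))
    lnl = 0.0
    for site in range(L):
        site_like = 0.0
        for rate, w in zip(rates, weights):
            P = {id(n): model.transition_matrix(n.edge.length or 0.0, rate)
                 for n in nodes if n.parent_node is not None}
            total = 0.0
            import itertools
            for assign in itertools.product(range(4), repeat=len(internals)):
                state = {id(n): s for n, s in zip(internals, assign)}
                for leaf in leaves:
                    state[id(leaf)] = "ACGT".index(
                        alignment[leaf.taxon.label][site])
                prob = pi[state[id(tree.seed_node)]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    prob *= P[id(n)][state[id(n.parent_node)], state[id(n)]]
                total += prob
            site_like += w * total
        lnl += math.log(site_like)
    return lnl


class TestLikelihood:
    def test_jc_single_site_closed_form(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick")
        lnl = loglikelihood(tree, {"A": "A", "B": "A"}, jc_model())
        p_same = 0.25 * (0.25 + 0.75 * math.exp(-4 * 0.2 / 3))
        assert lnl == pytest.approx(math.log(p_same), abs=1e-12)

    @pytest.mark.parametrize("model", [
        jc_model(),
        k2p_model(kappa=3.0),
        gtr_model([1.3, 3.1, 0.6, 1.4, 4.2, 1.0],
                  [0.35, 0.28, 0.12, 0.25]),
        gtr_model([1.3, 3.1, 0.6, 1.4, 4.2, 1.0],
                  [0.35, 0.28, 0.12, 0.25], gamma_alpha=0.4),
    ], ids=["JC", "K2P", "GTR", "GTR+G"])
    def test_pruning_equals_brute_force(self, model):
        tree = dendropy.Tree.get(
            data="((A:0.12,B:0.31):0.08,(C:0.2,D:0.05):0.11);",
            schema="newick")
        rng = np.random.default_rng(4)
        aln = {t: "".join(rng.choice(list("ACGT"), size=6))
               for t in "ABCD"}
        assert loglikelihood(tree, aln, model) == pytest.approx(
            _brute_force_lnl(tree, aln, model), abs=1e-9)

    def test_gamma_limit_recovers_no_gamma(self):
        tree = dendropy.Tree.get(data="((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.07);",
                                 schema="newick")
        rng = np.random.default_rng(9)
        aln = {t: "".join(rng.choice(list("ACGT"), size=200))
               for t in "ABCD"}
        flat = loglikelihood(tree, aln, jc_model())
        near_flat = loglikelihood(
            tree, aln, SubstitutionModel("JC+G", gamma_alpha=1e6,
                                         gamma_categories=8))
        assert abs(flat - near_flat) < 1e-3

    def test_zero_length_alignment_rejected(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick")
        with pytest.raises(ValueError):
            loglikelihood(tree, {"A": "", "B": ""}, jc_model())

    def test_mismatched_taxa_rejected(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick")
        with pytest.raises(ValueError):
            loglikelihood(tree, {"A": "AC", "X": "AC"}, jc_model())


class TestBicRank:
    def test_identical_sequences_prefer_fewest_parameters(self):
        tree = dendropy.Tree.get(data="(A:0.01,B:0.01,C:0.01);",
                                 schema="newick")
        aln = {t: "ACGT" * 50 for t in "ABC"}
        fits = bic_rank(aln, tree, ["JC", "K2P", "GTR"])
        assert fits[0].model.name == "JC"
        assert abs(fits[0].lnL - fits[-1].lnL) < 0.1
        # branch lengths collapse to ~0 under identical data
        assert fits[0].lnL == pytest.approx(200 * math.log(0.25), abs=0.05)

    def test_jc_data_ranks_jc_over_gtr(self):
        wins = 0
        for seed in range(3):
            tree, _ = simulate_clock_tree(4, seed=300 + seed, depth=0.2)
            aln, _ = evolve_alignment(EvolSpec(tree=tree, model=jc_model(),
                                               sites=10000, seed=400 + seed))
            fits = bic_rank(aln, tree, ["JC", "GTR"])
            wins += fits[0].model.name == "JC"
        assert wins >= 2

    def test_gtr_gamma_data_ranks_gtr_gamma_over_jc(self):
        truth = gtr_model([1.2, 4.0, 0.8, 1.1, 5.0, 1.0],
                          [0.35, 0.30, 0.10, 0.25], gamma_alpha=0.3)
        tree, _ = simulate_clock_tree(5, seed=501, depth=0.25)
        aln, _ = evolve_alignment(EvolSpec(tree=tree, model=truth,
                                           sites=10000, seed=601))
        fits = bic_rank(aln, tree, ["JC", "GTR+G"])
        assert fits[0].model.name == "GTR+G"


def _with_outgroup(tree: dendropy.Tree, og_len: float = 2.0) -> dendropy.Tree:
    nwk = tree.as_string(schema="newick").strip().rstrip(";")
    return dendropy.Tree.get(data=f"(OG:{og_len},{nwk}:1.0);",
                             schema="newick")


class TestReltime:
    def test_clock_tree_relative_heights_exact(self):
        tree, heights = simulate_clock_tree(6, seed=5)
        tt = reltime_date(_with_outgroup(tree), "OG",
                          [Calibration(taxa=("T1", "T6"), age=55.54)])
        for clade, rel, _ in tt.node_ages:
            assert rel == pytest.approx(heights[frozenset(clade)], abs=1e-9)

    def test_two_taxon_point_calibration(self):
        tree = dendropy.Tree.get(data="(OG:3.0,(A:1.0,B:1.0):1.0);",
                                 schema="newick")
        tt = reltime_date(tree, "OG", [Calibration(taxa=("A", "B"),
                                                   age=55.54)])
        assert tt.age_of("A", "B") == pytest.approx(55.54)

    def test_scaling_invariance_of_relative_heights(self):
        tree, _ = simulate_clock_tree(8, seed=17)
        noisy = apply_rate_noise(tree, 0.3, seed=18)
        scaled = noisy.clone(depth=1)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length *= 3.7
        cal = [Calibration(taxa=("T1", "T8"), age=40.0)]
        a = reltime_date(_with_outgroup(noisy), "OG", cal)
        b = reltime_date(_with_outgroup(scaled, og_len=7.4), "OG", cal)
        for (ca, _, age_a), (cb, _, age_b) in zip(a.node_ages, b.node_ages):
            assert ca == cb
            assert age_a == pytest.approx(age_b, rel=1e-9)

    def test_ages_monotone_root_to_tip(self):
        tree, _ = simulate_clock_tree(10, seed=23)
        noisy = apply_rate_noise(tree, 0.5, seed=24)
        tt = reltime_date(_with_outgroup(noisy), "OG",
                          [Calibration(taxa=("T1", "T10"), age=60.0)])
        for node in tt.tree.preorder_node_iter():
            for child in node.child_nodes():
                if not child.is_leaf():
                    assert child.age_mya <= node.age_mya + 1e-9

    def test_lognormal_noise_height_recovery(self):
        import scipy.stats as st
        pears = []
        for seed in range(5):
            tree, heights = simulate_clock_tree(12, seed=100 + seed)
            noisy = apply_rate_noise(tree, 0.2, seed=200 + seed)
            tt = reltime_date(_with_outgroup(noisy), "OG",
                              [Calibration(taxa=("T1", "T12"), age=50.0)])
            est = [rel for _, rel, _ in tt.node_ages]
            true = [heights[frozenset(c)] for c, _, _ in tt.node_ages]
            pears.append(st.pearsonr(est, true)[0])
        assert min(pears) >= 0.95

    def test_calibration_on_tip_rejected(self):
        tree = dendropy.Tree.get(data="(OG:3.0,(A:1.0,B:1.0):1.0);",
                                 schema="newick")
        with pytest.raises(ValueError, match="tip"):
            reltime_date(tree, "OG", [Calibration(taxa=("A",), age=10.0)])

    def test_conflicting_point_calibrations_rejected(self):
        tree = dendropy.Tree.get(
            data="(OG:3.0,((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0):1.0);",
            schema="newick")
        with pytest.raises(CalibrationConflictError):
            reltime_date(tree, "OG", [
                Calibration(taxa=("A", "B"), age=10.0),
                Calibration(taxa=("A", "C"), age=100.0),
            ])

    def test_interval_calibration_respected(self):
        tree = dendropy.Tree.get(data="(OG:3.0,(A:1.0,B:1.0):1.0);",
                                 schema="newick")
        tt = reltime_date(tree, "OG", [Calibration(taxa=("A", "B"),
                                                   min_age=40.0,
                                                   max_age=60.0)])
        assert 40.0 <= tt.age_of("A", "B") <= 60.0


class TestBranchOptimization:
    def test_recovers_generating_branch_length(self):
        truth = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick")
        aln, _ = evolve_alignment(EvolSpec(tree=truth, model=jc_model(),
                                           sites=20000, seed=77))
        work = dendropy.Tree.get(data="(A:0.5,B:0.5);", schema="newick")
        optimize_branch_lengths(work, aln, jc_model())
        total = sum(l.edge.length for l in work.leaf_node_iter())
        assert total == pytest.approx(0.2, abs=0.02)
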