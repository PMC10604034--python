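import numpy as np
import pytest

from mitocomp.trna import (ACCEPTOR_LENGTHS, AC_LOOPS, AC_STEMS, D_LOOPS,
                           D_STEMS, LINK_ACC_D, LINK_AC_T, LINK_D_AC,
                           LINK_T_ACC, T_LOOPS, T_STEMS, CloverleafStructure,
                           FoldFailure, fold_cloverleaf, fold_genome_trnas,
                           pairing_profile, wobble_summary)
from mitocomp.io import extract_feature_sequence


def _brute_force_best_score(seq: str) -> int:
    """Independent exhaustive enumeration of the full template grid,
    written as one flat nested loop (no pruning, no tie-breaks)."""
    def pair_score(i, j):
        x, y = seq[i], seq[j]
        if (x, y) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
            return 2
        if (x, y) in {("G", "T"), ("T", "G")}:
            return 1
        return 0

    def hairpin_score(s, stem, loop):
        return sum(pair_score(s + k, s + 2 * stem + loop - 1 - k)
                   for k in range(stem))

    L = len(seq)
    best = -1
    for a in ACCEPTOR_LENGTHS:
        acc = sum(pair_score(i, L - 1 - i) for i in range(a))
        for l0 in LINK_ACC_D:
            for d in D_STEMS:
                for ld in D_LOOPS:
                    d0 = a + l0
                    d1 = d0 + 2 * d + ld
                    if d1 >= L - a:
                        continue
                    ds = hairpin_score(d0, d, ld)
                    for l1 in LINK_D_AC:
                        for c in AC_STEMS:
                            for lc in AC_LOOPS:
                                c0 = d1 + l1
                                c1 = c0 + 2 * c + lc
                                if c1 >= L - a:
                                    continue
                                cs = hairpin_score(c0, c, lc)
                                for l2 in LINK_AC_T:
                                    for t in T_STEMS:
                                        for lt in T_LOOPS:
                                            t0 = c1 + l2
                                            t1 = t0 + 2 * t + lt
                                            slack = (L - a) - t1
                                            if slack < 0 or slack > max(LINK_T_ACC):
                                                continue
                                            ts = hairpin_score(t0, t, lt)
                                            score = acc + ds + cs + ts
                                            if score > best:
                                                best = score
    return best


class TestFolding:
    def test_planted_arms_recovered_exactly(self, compact_sim):
        genome, truth = compact_sim
        structs = fold_genome_trnas(genome)
        assert len(structs) == 22
        for name, s in structs.items():
            t = truth["trna"][name]
            assert s.acceptor_stem == [tuple(p) for p in t["acceptor_pairs"]]
            assert s.anticodon_arm.stem_pairs == [tuple(p)
                                                  for p in t["ac_pairs"]]
            assert s.t_arm.stem_pairs == [tuple(p) for p in t["t_pairs"]]
            if not t["missing_arms"]:
                assert s.d_arm.stem_pairs == [tuple(p) for p in t["d_pairs"]]
            assert s.anticodon == (t["anticodon"], t["anticodon_pos"])

    def test_dhu_less_serine_flagged(self, compact_sim):
        genome, _ = compact_sim
        structs = fold_genome_trnas(genome)
        assert set(structs["trnS1"].missing_arms) == {"D"}
        for name, s in structs.items():
            if name != "trnS1":
                assert not s.missing_arms

    def test_wobble_pairs_labeled(self, compact_sim):
        genome, truth = compact_sim
        structs = fold_genome_trnas(genome)
        for name, s in structs.items():
            n_wob = sum(1 for v in s.pair_labels.values() if v == "wobble")
            assert n_wob == truth["trna"][name]["n_wobble"]

    def test_pairing_alphabet_only(self, compact_sim):
        genome, _ = compact_sim
        for name, s in fold_genome_trnas(genome).items():
            seq = None
            for f in genome.features:
                if f.name == name:
                    seq = extract_feature_sequence(genome, f)
            for (i, j), label in s.pair_labels.items():
                pair = (seq[i], seq[j])
                assert pair in {("A", "T"), ("T", "A"), ("G", "C"),
                                ("C", "G"), ("G", "T"), ("T", "G")}

    def test_nested_non_crossing(self, compact_sim):
        genome, _ = compact_sim
        for s in fold_genome_trnas(genome).values():
            pairs = sorted(s.all_pairs)
            for (i1, j1) in pairs:
                for (i2, j2) in pairs:
                    if i1 < i2:
                        assert i2 > j1 or j2 < j1  # nested or disjoint

    def test_score_is_template_grid_maximum(self, compact_sim):
        genome, _ = compact_sim
        structs = fold_genome_trnas(genome)
        for name in ("trnF", "trnS1", "trnK"):
            f = genome.get(name)
            seq = extract_feature_sequence(genome, f)
            assert structs[name].score == _brute_force_best_score(seq)

    def test_refold_after_double_revcomp_identical(self, compact_sim):
        from mitocomp.vocab import revcomp
        genome, _ = compact_sim
        seq = extract_feature_sequence(genome, genome.get("trnF"))
        a = fold_cloverleaf(seq, anticodon_hint=genome.get("trnF").anticodon)
        b = fold_cloverleaf(revcomp(revcomp(seq)),
                            anticodon_hint=genome.get("trnF").anticodon)
        assert a.dot_bracket() == b.dot_bracket()
        assert a.score == b.score

    def test_unfoldable_sequence_raises(self):
        with pytest.raises(FoldFailure):
            fold_cloverleaf("A" * 70)

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            fold_cloverleaf("ACGT" * 10)  # 40 nt


class TestPairingProfile:
    def test_counts_mixed(self):
        s = CloverleafStructure(
            length=10, acceptor_stem=[(0, 9)], d_arm=None,
            anticodon_arm=None, t_arm=None, anticodon=("AAA", 4),
            pair_labels={(0, 9): "WC", (1, 8): "WC", (2, 7): "wobble"},
            missing_arms=frozenset(), score=5)
        prof = pairing_profile(s)
        assert prof.counts == {"WC": 2, "wobble": 1}
        assert not prof.all_wc

    def test_all_wc_flag(self):
        s = CloverleafStructure(
            length=6, acceptor_stem=[(0, 5)], d_arm=None, anticodon_arm=None,
            t_arm=None, anticodon=("AAA", 2),
            pair_labels={(0, 5): "WC"}, missing_arms=frozenset(), score=2)
        assert pairing_profile(s).all_wc

    def test_planted_wobble_split_15_7(self, compact_sim):
        genome, _ = compact_sim
        summary = wobble_summary(fold_genome_trnas(genome))
        assert summary["n_with_wobble"] == 15
        assert summary["n_pure_wc"] == 7
        assert "trnS1" in summary["pure_wc"]
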