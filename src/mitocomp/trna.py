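"""Template-constrained cloverleaf folding of mitochondrial tRNA genes.

The folder performs a deterministic search over a constrained cloverleaf
template rather than free-energy minimization: the structural claims made of
mitogenome tRNAs are arm-level (canonical cloverleaf vs. a missing DHU arm,
Watson-Crick vs. wobble pairing), and a template search is exactly
oracle-checkable by exhaustive enumeration.

Template (0-based positions on the gene's sense strand, length L):

* acceptor stem ``a`` in {6,7} pairs ``(i, L-1-i)`` from the termini inward;
* inside it, three hairpins in 5'->3' order — DHU arm (stem 3-4), anticodon
  arm (stem 4-5, loop 5/7/9 with the anticodon centered) and T arm (stem
  4-5) — separated by short linkers (variable region up to 7 nt between the
  anticodon and T arms).

Pairing alphabet: A:T and G:C (Watson-Crick, scored 2) and the G:T wobble
(scored 1).  The returned structure maximizes total score; ties prefer a
longer acceptor stem, then more WC pairs, then the 5'-most DHU arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}

# Template grid bounds.
ACCEPTOR_LENGTHS = (7, 6)
D_STEMS = (3, 4)
AC_STEMS = (4, 5)
T_STEMS = (4, 5)
D_LOOPS = range(3, 10)
AC_LOOPS = (5, 7, 9)
T_LOOPS = range(3, 10)
LINK_ACC_D = range(0, 4)      # acceptor 5' side -> DHU arm
LINK_D_AC = range(0, 4)       # DHU arm -> anticodon arm
LINK_AC_T = range(0, 8)       # variable region
LINK_T_ACC = range(0, 4)      # T arm -> acceptor 3' side


class FoldFailure(ValueError):
    """No acceptor stem with at least 4 legal pairs exists."""


@dataclass
class Arm:
    stem_pairs: list[tuple[int, int]]
    loop: tuple[int, int]  # inclusive span of loop positions
    n_pairs: int
    score: int
    n_wc: int


@dataclass
class CloverleafStructure:
    length: int
    acceptor_stem: list[tuple[int, int]]
    d_arm: Arm
    anticodon_arm: Arm
    t_arm: Arm
    anticodon: tuple[str, int]  # triplet, 0-based start position
    pair_labels: dict[tuple[int, int], str]
    missing_arms: frozenset[str]
    score: int

    @property
    def all_pairs(self) -> list[tuple[int, int]]:
        return (self.acceptor_stem + self.d_arm.stem_pairs +
                self.anticodon_arm.stem_pairs + self.t_arm.stem_pairs)

    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.all_pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)


def _pair_label(x: str, y: str) -> str | None:
    if (x, y) in WC_PAIRS:
        return "WC"
    if (x, y) in WOBBLE_PAIRS:
        return "wobble"
    return None


def _score_pairs(seq: str, candidates: list[tuple[int, int]]):
    """Keep legal pairs only; returns (pairs, score, n_wc)."""
    pairs, score, n_wc = [], 0, 0
    for i, j in candidates:
        lab = _pair_label(seq[i], seq[j])
        if lab == "WC":
            pairs.append((i, j))
            score += 2
            n_wc += 1
        elif lab == "wobble":
            pairs.append((i, j))
            score += 1
    return pairs, score, n_wc


def _hairpin(seq: str, start: int, stem: int, loop: int) -> Arm:
    cands = [(start + k, start + 2 * stem + loop - 1 - k) for k in range(stem)]
    pairs, score, n_wc = _score_pairs(seq, cands)
    return Arm(stem_pairs=pairs, loop=(start + stem, start + stem + loop - 1),
               n_pairs=len(pairs), score=score, n_wc=n_wc)


def _anticodon_window(arm_start: int, stem: int, loop: int) -> int:
    """0-based start of the central triplet of the anticodon loop."""
    return arm_start + stem + (loop - 3) // 2


def fold_cloverleaf(seq: str, anticodon_hint: str | None = None,
                    expected_anticodons: list[str] | None = None,
                    ) -> CloverleafStructure:
    """Fold a tRNA gene sequence (sense strand, 55-95 nt) into a cloverleaf.

    ``anticodon_hint`` constrains the anticodon-loop placement so its central
    triplet equals the hint (the hint always wins over scanning); with no
    hint, ``expected_anticodons`` are tried as soft constraints and the best
    overall structure is kept.  An arm whose best stem retains fewer than two
    legal pairs is reported in ``missing_arms`` (D and/or T).  Raises
    :class:`FoldFailure` when no acceptor stem achieves four legal pairs.
    """
    seq = seq.upper()
    L = len(seq)
    if not 55 <= L <= 95:
        raise ValueError(f"tRNA length {L} outside 55..95")

    acceptor_by_a: dict[int, tuple[list, int, int]] = {}
    for a in ACCEPTOR_LENGTHS:
        acceptor_by_a[a] = _score_pairs(seq, [(i, L - 1 - i) for i in range(a)])
    if max(len(p[0]) for p in acceptor_by_a.values()) < 4:
        raise FoldFailure("no acceptor stem with >= 4 legal pairs")

    hints: list[str | None]
    if anticodon_hint:
        hints = [anticodon_hint.upper()]
    elif expected_anticodons:
        hints = [h.upper() for h in expected_anticodons] + [None]
    else:
        hints = [None]

    best = None
    best_key = None
    for hint in hints:
        cand = _search_templates(seq, L, acceptor_by_a, hint)
        if cand is None:
            continue
        structure, key = cand
        if best_key is None or key > best_key:
            best, best_key = structure, key
    if best is None:
        # hint never matched any loop window: fall back to unconstrained scan
        cand = _search_templates(seq, L, acceptor_by_a, None)
        if cand is None:
            raise FoldFailure("no template placement fits this sequence")
        best = cand[0]
    return best


def _search_templates(seq, L, acceptor_by_a, hint):
    best = None
    best_key = None
    for a in ACCEPTOR_LENGTHS:
        acc_pairs, acc_score, acc_wc = acceptor_by_a[a]
        lo, hi = a, L - a  # interior half-open span
        for l0, d, ld in product(LINK_ACC_D, D_STEMS, D_LOOPS):
            d_start = lo + l0
            d_end = d_start + 2 * d + ld
            if d_end >= hi:
                continue
            d_arm = _hairpin(seq, d_start, d, ld)
            for l1, c, lc in product(LINK_D_AC, AC_STEMS, AC_LOOPS):
                ac_start = d_end + l1
                ac_end = ac_start + 2 * c + lc
                if ac_end >= hi:
                    continue
                ac_pos = _anticodon_window(ac_start, c, lc)
                if hint is not None and seq[ac_pos:ac_pos + 3] != hint:
                    continue
                ac_arm = _hairpin(seq, ac_start, c, lc)
                for l2, t, lt in product(LINK_AC_T, T_STEMS, T_LOOPS):
                    t_start = ac_end + l2
                    t_end = t_start + 2 * t + lt
                    slack = hi - t_end
                    if slack < 0 or slack > max(LINK_T_ACC):
                        continue
                    t_arm = _hairpin(seq, t_start, t, lt)
                    score = acc_score + d_arm.score + ac_arm.score + t_arm.score
                    n_wc = acc_wc + d_arm.n_wc + ac_arm.n_wc + t_arm.n_wc
                    key = (score, a, n_wc, -d_start)
                    if best_key is None or key > best_key:
                        missing = frozenset(
                            name for name, arm in (("D", d_arm), ("T", t_arm))
                            if arm.n_pairs < 2
                        )
                        labels = {
                            (i, j): _pair_label(seq[i], seq[j])
                            for i, j in (acc_pairs + d_arm.stem_pairs +
                                         ac_arm.stem_pairs + t_arm.stem_pairs)
                        }
                        best = CloverleafStructure(
                            length=L,
                            acceptor_stem=list(acc_pairs),
                            d_arm=d_arm, anticodon_arm=ac_arm, t_arm=t_arm,
                            anticodon=(seq[ac_pos:ac_pos + 3], ac_pos),
                            pair_labels=labels,
                            missing_arms=missing,
                            score=score,
                        )
                        best_key = key
    if best is None:
        return None
    return best, best_key


@dataclass
class PairingProfile:
    counts: dict[str, int] = field(default_factory=dict)
    all_wc: bool = True


def pairing_profile(structure: CloverleafStructure) -> PairingProfile:
    """Watson-Crick vs wobble pair counts for one folded tRNA."""
    wc = sum(1 for v in structure.pair_labels.values() if v == "WC")
    wob = sum(1 for v in structure.pair_labels.values() if v == "wobble")
    return PairingProfile(counts={"WC": wc, "wobble": wob}, all_wc=(wob == 0))


def fold_genome_trnas(genome, extractor=None) -> dict[str, CloverleafStructure]:
    """Fold every annotated tRNA of a genome; returns {gene name: structure}."""
    from .io import extract_feature_sequence

    extractor = extractor or extract_feature_sequence
    out = {}
    for f in genome.features:
        if f.ftype != "tRNA":
            continue
        hint = f.anticodon if f.anticodon and f.anticodon != "NNN" else None
        out[f.name] = fold_cloverleaf(extract_feature_sequence(genome, f),
                                      anticodon_hint=hint)
    return out


def wobble_summary(structures: dict[str, CloverleafStructure]) -> dict:
    """Genome-level split: tRNAs with >=1 wobble pair vs pure Watson-Crick."""
    with_wobble = sorted(n for n, s in structures.items()
                         if not pairing_profile(s).all_wc)
    pure_wc = sorted(n for n, s in structures.items()
                     if pairing_profile(s).all_wc)
    return {"with_wobble": with_wobble, "pure_wc": pure_wc,
            "n_with_wobble": len(with_wobble), "n_pure_wc": len(pure_wc)}
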