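"""Synthetic mitogenomes and sequence evolution with known ground truth.

``simulate_mitogenome`` builds a circular vertebrate-like mitogenome from a
:class:`GenomeSpec` — 37 genes in a configurable order on two strands,
codon-structured protein-coding genes with configurable (possibly incomplete)
start/stop codons, tRNA genes engineered to fold into cloverleafs (with
planted wobble pairs and an optional DHU-armless serine), and a control
region carrying a planted tandem repeat and CSB-like motifs — and returns the
genome together with a JSON-serializable ground-truth record of everything it
planted.  ``evolve_alignment`` simulates sequences along a tree under the
package's substitution models.

Determinism: one seed per spec; every feature draws from a sub-generator
derived from (seed, feature name), so adding or reordering stages never
perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .datasets import default_csb_motifs, load_belcheri_codons, load_belcheri_table
from .io import Feature, MitoGenome
from .vocab import (CANONICAL_TELEOST_ORDER, VERTEBRATE_MITO_STOPS,
                    classify_ftype, revcomp)

BASES = "ACGT"

#: Published partition composition of the P. belcheri record, used as the
#: default base-frequency targets (A, C, G, T).
DEFAULT_PARTITION_FREQS = {
    "whole": (0.2809, 0.2956, 0.1624, 0.2606),
    "PCGs": (0.2500, 0.3127, 0.1600, 0.2773),
    "rRNAs": (0.3142, 0.2533, 0.2187, 0.2138),
    "tRNAs": (0.2783, 0.2172, 0.2314, 0.2731),
    "CR": (0.3025, 0.2384, 0.1251, 0.3340),
}

#: The 15 tRNAs reported to carry at least one wobble pair in the P. belcheri
#: structures, and by complement the 7 pure Watson-Crick ones.
DEFAULT_WOBBLE_TRNAS = frozenset({
    "trnA", "trnF", "trnQ", "trnM", "trnW", "trnN", "trnC", "trnY",
    "trnS2", "trnD", "trnG", "trnR", "trnH", "trnE", "trnP",
})

NON_STOP_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in VERTEBRATE_MITO_STOPS
)


class SpecError(ValueError):
    """The genome spec is internally inconsistent."""


def freqs_from_skews(pct_at: float, at_skew: float, gc_skew: float
                     ) -> tuple[float, float, float, float]:
    """(A, C, G, T) frequencies realizing given AT% and AT/GC skews."""
    w = pct_at / 100.0 if pct_at > 1 else pct_at
    a = w * (1 + at_skew) / 2
    t = w * (1 - at_skew) / 2
    g = (1 - w) * (1 + gc_skew) / 2
    c = (1 - w) * (1 - gc_skew) / 2
    return (a, c, g, t)


@dataclass(frozen=True)
class PCGPlan:
    start_codon: str = "ATG"
    stop_codon: str = "TAA"  # printed form: TAA/TAG/AGA/AGG or TA-/T--


@dataclass(frozen=True)
class TRNAPlan:
    anticodon: str
    n_wobble: int = 0
    dhu_less: bool = False


@dataclass(frozen=True)
class RepeatPlan:
    period: int = 72
    copies: float = 2.5


@dataclass
class GenomeSpec:
    """Everything the generator needs, with the planted truth made explicit."""

    accession: str
    genome_length: int
    features: list[Feature]
    pcg_plans: dict[str, PCGPlan]
    trna_plans: dict[str, TRNAPlan]
    partition_freqs: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARTITION_FREQS))
    cr_repeat: RepeatPlan | None = field(default_factory=RepeatPlan)
    csb_motifs: dict[str, str] | None = None
    csb_mismatches: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for f in self.features:
            if f.end > self.genome_length:
                raise SpecError(f"{f.name} exceeds genome length")
        for name, plan in self.pcg_plans.items():
            f = next(x for x in self.features if x.name == name)
            rem = f.length % 3
            incomplete = "-" in plan.stop_codon
            if incomplete != (rem in (1, 2)):
                raise SpecError(
                    f"{name}: stop plan {plan.stop_codon!r} inconsistent with "
                    f"length {f.length} (mod 3 = {rem})")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_table(cls, genome: MitoGenome | None = None,
                   seed: int = 0) -> "GenomeSpec":
        """Spec cloned from an annotation table (default: the packaged
        P. belcheri table).

        Printed stop codons that contradict the gene length mod 3 (a known
        quirk of deposited tables) are reconciled in favor of the length:
        remainder 1 plants ``T--``, remainder 2 ``TA-``, remainder 0 keeps a
        printed complete stop or falls back to TAA.
        """
        if genome is None:
            genome = load_belcheri_table()
            printed = {r.gene: (r.start_codon, r.stop_codon)
                       for r in load_belcheri_codons().itertuples()}
            # normalize printed PCG labels to vocabulary names
            from .vocab import normalize_gene_name
            printed = {normalize_gene_name(k): v for k, v in printed.items()}
        else:
            printed = {}
        pcg_plans: dict[str, PCGPlan] = {}
        for f in genome.features:
            if f.ftype != "PCG":
                continue
            start, stop = printed.get(f.name, ("ATG", "TAA"))
            rem = f.length % 3
            if rem == 1:
                stop = "T--"
            elif rem == 2:
                stop = "TA-"
            elif "-" in stop:
                stop = "TAA"
            pcg_plans[f.name] = PCGPlan(start_codon=start, stop_codon=stop)
        trna_plans = {
            f.name: TRNAPlan(
                anticodon=f.anticodon if f.anticodon not in (None, "NNN")
                else "AAA",
                n_wobble=1 if f.name in DEFAULT_WOBBLE_TRNAS else 0,
                dhu_less=(f.name == "trnS1"),
            )
            for f in genome.features if f.ftype == "tRNA"
        }
        return cls(accession=f"sim-{genome.accession}",
                   genome_length=genome.genome_length,
                   features=list(genome.features),
                   pcg_plans=pcg_plans, trna_plans=trna_plans, seed=seed)

    @classmethod
    def compact(cls, seed: int = 0, intergenic: int = 5,
                pcg_codons: int = 100, trna_length: int = 70,
                rrna_length: int = 400, cr_length: int = 700,
                incomplete_pcgs: tuple[str, ...] = ("nad2", "cox2"),
                ) -> "GenomeSpec":
        """An overlap-free genome in canonical teleost order.

        Every junction is a spacer of ``intergenic`` bp, so no feature's
        planted content is ever overwritten by a neighbor — the spec of
        choice for structure-recovery tests.  ``incomplete_pcgs`` get T--
        stops (length adjusted to remainder 1).
        """
        anticodons = {f.name: f.anticodon for f in load_belcheri_table().features
                      if f.ftype == "tRNA"}
        feats: list[Feature] = []
        pcg_plans: dict[str, PCGPlan] = {}
        trna_plans: dict[str, TRNAPlan] = {}
        at = 1
        for name, sign in CANONICAL_TELEOST_ORDER:
            ftype = classify_ftype(name)
            if ftype == "PCG":
                length = pcg_codons * 3
                if name in incomplete_pcgs:
                    length += 1
                    pcg_plans[name] = PCGPlan(stop_codon="T--")
                else:
                    pcg_plans[name] = PCGPlan(stop_codon="TAA")
            elif ftype == "tRNA":
                length = trna_length
                trna_plans[name] = TRNAPlan(
                    anticodon=anticodons.get(name) or "AAA",
                    n_wobble=1 if name in DEFAULT_WOBBLE_TRNAS else 0,
                    dhu_less=(name == "trnS1"),
                )
            elif ftype == "rRNA":
                length = rrna_length
            else:
                length = cr_length
            feats.append(Feature(
                name=name, ftype=ftype, start=at, end=at + length - 1,
                strand="H" if sign > 0 else "L",
                anticodon=trna_plans[name].anticodon if ftype == "tRNA" else None,
            ))
            at += length + intergenic
        return cls(accession="sim-compact", genome_length=at - 1,
                   features=feats, pcg_plans=pcg_plans,
                   trna_plans=trna_plans, seed=seed)


def _feature_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _draw(rng: np.random.Generator, freqs, n: int) -> str:
    p = np.asarray(freqs, dtype=float)
    p = p / p.sum()  # published percentages carry rounding error
    return "".join(rng.choice(list(BASES), size=n, p=p))


_WC_CHOICES = (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"))


def _design_trna(length: int, anticodon: str, n_wobble: int, dhu_less: bool,
                 rng: np.random.Generator) -> tuple[str, dict]:
    """Design-and-verify loop: draw a candidate cloverleaf, fold it back with
    the template folder, and redraw if the fold is not exactly the designed
    structure (a chance shift-invariant stem can otherwise create an
    equal-score alternative placement)."""
    from .trna import fold_cloverleaf

    last_exc: Exception | None = None
    for _ in range(25):
        seq, truth = _draw_trna(length, anticodon, n_wobble, dhu_less, rng)
        try:
            s = fold_cloverleaf(seq, anticodon_hint=anticodon)
        except ValueError as exc:
            last_exc = exc
            continue
        ok = (s.acceptor_stem == truth["acceptor_pairs"]
              and s.anticodon_arm.stem_pairs == truth["ac_pairs"]
              and s.t_arm.stem_pairs == truth["t_pairs"]
              and s.anticodon == (truth["anticodon"],
                                  truth["anticodon_pos"]))
        if dhu_less:
            ok = ok and set(s.missing_arms) == {"D"}
        else:
            ok = (ok and s.d_arm.stem_pairs == truth["d_pairs"]
                  and not s.missing_arms)
        if ok:
            return seq, truth
    raise SpecError(
        f"could not design a uniquely foldable tRNA of length {length}"
        + (f" ({last_exc})" if last_exc else ""))


def _draw_trna(length: int, anticodon: str, n_wobble: int, dhu_less: bool,
               rng: np.random.Generator) -> tuple[str, dict]:
    """Engineer a cloverleaf-foldable sequence with fully-paired stems.

    Template: acceptor 7 bp, D stem 4, anticodon stem 5 / loop 7 (anticodon
    centered), T stem 5, linkers to fit the length.  Loop and linker bases
    are drawn from {A, C} only, so they cannot pair — the designed template
    is the unique score-maximal fold up to chance.  ``n_wobble`` G:T pairs
    replace Watson-Crick pairs in the T stem; ``dhu_less`` replaces the D
    hairpin with an unpairable {A,C} stretch.
    """
    a, d, c, lc, t = 7, 4, 5, 7, 5
    layout = None
    for ld in (7, 8, 9, 6, 5, 4, 3):
        for lt in (7, 8, 9, 6, 5, 4, 3):
            for l2 in (4, 5, 6, 7, 3, 2, 1, 0):
                for l0 in (1, 0, 2, 3):
                    for l1 in (1, 0, 2, 3):
                        for l3 in (0, 1, 2, 3):
                            total = (2 * a + l0 + 2 * d + ld + l1 +
                                     2 * c + lc + l2 + 2 * t + lt + l3)
                            if total == length:
                                layout = (ld, lt, l2, l0, l1, l3)
                                break
                        if layout:
                            break
                    if layout:
                        break
                if layout:
                    break
            if layout:
                break
        if layout:
            break
    if layout is None:
        raise SpecError(f"no cloverleaf layout for tRNA length {length}")
    ld, lt, l2, l0, l1, l3 = layout

    seq = [""] * length
    unpairable = lambda n: "".join(rng.choice(["A", "C"], size=n))

    def plant_hairpin(start: int, stem: int, loop: int, wobble: int = 0,
                      loop_seq: str | None = None):
        pairs = []
        for k in range(stem):
            i, j = start + k, start + 2 * stem + loop - 1 - k
            if wobble > 0:
                x, y = "G", "T"
                wobble -= 1
            else:
                x, y = _WC_CHOICES[rng.integers(0, 4)]
            seq[i], seq[j] = x, y
            pairs.append((i, j))
        ls = loop_seq if loop_seq is not None else unpairable(loop)
        for k, ch in enumerate(ls):
            seq[start + stem + k] = ch
        return pairs

    # acceptor
    acc_pairs = []
    for k in range(a):
        x, y = _WC_CHOICES[rng.integers(0, 4)]
        seq[k], seq[length - 1 - k] = x, y
        acc_pairs.append((k, length - 1 - k))
    pos = a
    for k in range(l0):
        seq[pos + k] = unpairable(1)
    pos += l0
    d_start = pos
    if dhu_less:
        for k in range(2 * d + ld):
            seq[pos + k] = unpairable(1)
        d_pairs = []
    else:
        d_pairs = plant_hairpin(pos, d, ld)
    pos += 2 * d + ld
    for k in range(l1):
        seq[pos + k] = unpairable(1)
    pos += l1
    ac_start = pos
    loop_seq = unpairable(2) + anticodon.upper() + unpairable(2)
    ac_pairs = plant_hairpin(pos, c, lc, loop_seq=loop_seq)
    ac_pos = pos + c + 2
    pos += 2 * c + lc
    for k in range(l2):
        seq[pos + k] = unpairable(1)
    pos += l2
    t_start = pos
    t_pairs = plant_hairpin(pos, t, lt, wobble=n_wobble)
    pos += 2 * t + lt
    for k in range(l3):
        seq[pos + k] = unpairable(1)

    truth = dict(
        acceptor_pairs=acc_pairs, d_pairs=d_pairs, ac_pairs=ac_pairs,
        t_pairs=t_pairs, anticodon=anticodon.upper(), anticodon_pos=ac_pos,
        d_start=d_start, ac_start=ac_start, t_start=t_start,
        n_wobble=0 if dhu_less else n_wobble,
        missing_arms=["D"] if dhu_less else [],
        layout=dict(a=a, d=d, ld=ld, c=c, lc=lc, t=t, lt=lt,
                    l0=l0, l1=l1, l2=l2, l3=l3),
    )
    return "".join(seq), truth


def _design_pcg(length: int, plan: PCGPlan, freqs,
                rng: np.random.Generator) -> str:
    rem = length % 3
    start = plan.start_codon.upper()
    if "-" in plan.stop_codon:
        stop = plan.stop_codon.replace("-", "")
        if len(stop) != rem:
            raise SpecError(
                f"incomplete stop {plan.stop_codon!r} needs length mod 3 == "
                f"{len(stop)}, got {rem}")
    else:
        if rem != 0:
            raise SpecError("complete stop needs length divisible by 3")
        stop = plan.stop_codon.upper()
    n_codons = (length - 3 - len(stop)) // 3
    interior = "".join(
        NON_STOP_CODONS[i]
        for i in rng.integers(0, len(NON_STOP_CODONS), size=n_codons)
    )
    return start + interior + stop


def _design_cr(length: int, spec: GenomeSpec,
               rng: np.random.Generator) -> tuple[str, dict]:
    freqs = spec.partition_freqs["CR"]
    motifs = spec.csb_motifs or default_csb_motifs()
    truth: dict = {"csb": {}, "repeat": None}
    pieces: list[str] = []
    at = 0

    def emit(s: str):
        nonlocal at
        pieces.append(s)
        at += len(s)

    emit(_draw(rng, freqs, 30))
    for block, motif in motifs.items():
        planted = list(motif)
        m = spec.csb_mismatches.get(block, 0)
        if m:
            idx = rng.choice(len(planted), size=m, replace=False)
            for i in idx:
                planted[i] = {"A": "G", "C": "T", "G": "A", "T": "C"}[planted[i]]
        start = at
        emit("".join(planted))
        truth["csb"][block] = {"span_cr": (start + 1, at),
                               "mismatches": int(m)}
        emit(_draw(rng, freqs, 20))
    if spec.cr_repeat is not None:
        p, copies = spec.cr_repeat.period, spec.cr_repeat.copies
        unit = _draw(rng, freqs, p)
        n_full = int(copies)
        frac = int(round((copies - n_full) * p))
        rep = unit * n_full + unit[:frac]
        start = at
        emit(rep)
        truth["repeat"] = {"period": p, "copies": copies, "unit": unit,
                           "span_cr": (start + 1, at)}
    if at > length:
        raise SpecError(f"CR plan needs {at} bp but CR is only {length} bp")
    emit(_draw(rng, freqs, length - at))
    return "".join(pieces), truth


def simulate_mitogenome(spec: GenomeSpec) -> tuple[MitoGenome, dict]:
    """Build the genome and the ground-truth record.

    Features are written in annotation order onto a circular buffer; at
    overlaps the earlier feature's bases are fixed and the later feature's
    achieved codons (recorded in the ground truth, along with the conflict
    positions) may differ from its plan.  Intergenic spacers are filled from
    the whole-genome base frequencies.
    """
    spec.validate()
    L = spec.genome_length
    buf: list[str | None] = [None] * L
    conflicts: list[dict] = []
    truth: dict = {
        "seed": spec.seed, "accession": spec.accession,
        "codons": {}, "trna": {}, "cr": None,
        "partition_freqs": {k: list(v) for k, v in spec.partition_freqs.items()},
        "conflicts": conflicts,
    }

    def write(feature: Feature, sense: str):
        plus = revcomp(sense) if feature.strand == "L" else sense
        for k, ch in enumerate(plus):
            pos = feature.start - 1 + k
            if buf[pos] is None:
                buf[pos] = ch
            elif buf[pos] != ch:
                conflicts.append({"feature": feature.name, "position": pos + 1,
                                  "kept": buf[pos], "wanted": ch})

    for f in spec.features:
        rng = _feature_rng(spec.seed, f.name)
        if f.ftype == "PCG":
            sense = _design_pcg(f.length, spec.pcg_plans[f.name],
                                spec.partition_freqs["PCGs"], rng)
            write(f, sense)
        elif f.ftype == "tRNA":
            plan = spec.trna_plans[f.name]
            sense, t = _design_trna(f.length, plan.anticodon, plan.n_wobble,
                                    plan.dhu_less, rng)
            write(f, sense)
            truth["trna"][f.name] = t
        elif f.ftype == "rRNA":
            write(f, _draw(rng, spec.partition_freqs["rRNAs"], f.length))
        else:  # CR
            sense, t = _design_cr(f.length, spec, rng)
            write(f, sense)
            truth["cr"] = t

    bg = _feature_rng(spec.seed, "__background__")
    whole = spec.partition_freqs["whole"]
    fill = _draw(bg, whole, sum(1 for b in buf if b is None))
    it = iter(fill)
    sequence = "".join(b if b is not None else next(it) for b in buf)

    genome = MitoGenome(accession=spec.accession, genome_length=L,
                        features=list(spec.features), sequence=sequence)

    # achieved codons, post hoc from the final sequence
    from .composition import classify_codons
    for rep in classify_codons(genome):
        truth["codons"][rep.gene] = {
            "start": rep.start_codon, "stop": rep.stop_codon,
            "stop_class": rep.stop_class,
        }
    truth["incomplete_pcgs"] = sorted(
        g for g, v in truth["codons"].items() if v["stop_class"] == "incomplete")
    return genome, truth


# ---------------------------------------------------------------------------
# Sequence evolution on trees


@dataclass
class EvolSpec:
    """Tree + substitution model + site count for sequence simulation."""

    tree: dendropy.Tree | str
    model: "object"  # SubstitutionModel
    sites: int
    seed: int = 0

    def resolved_tree(self) -> dendropy.Tree:
        if isinstance(self.tree, str):
            return dendropy.Tree.get(data=self.tree, schema="newick")
        return self.tree


def evolve_alignment(spec: EvolSpec) -> tuple[dict[str, str], dendropy.Tree]:
    """Simulate an alignment along a tree.

    The root sequence is drawn from the model's stationary frequencies; each
    branch evolves its parent's states through the model's transition
    probabilities at the branch length; with gamma rate variation each site
    keeps one rate category across the whole tree.  Deterministic under the
    spec seed.
    """
    if spec.sites < 1:
        raise SpecError("sites must be >= 1")
    model = spec.model
    tree = spec.resolved_tree()
    rng = np.random.default_rng(spec.seed)
    pi = model.freqs
    rates, weights = model.rate_categories()
    cats = rng.choice(len(rates), size=spec.sites, p=weights)
    site_rates = rates[cats]
    Q = model.rate_matrix()

    from scipy.linalg import expm

    root_states = rng.choice(4, size=spec.sites, p=pi)
    tree.seed_node._states = root_states
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        parent_states = node.parent_node._states
        if bl <= 0:
            node._states = parent_states.copy()
            continue
        states = np.empty(spec.sites, dtype=np.int64)
        for r in np.unique(site_rates):
            P = expm(Q * bl * r)
            P = np.clip(P, 0, None)
            P /= P.sum(axis=1, keepdims=True)
            mask = site_rates == r
            ps = parent_states[mask]
            draw = np.empty(ps.shape[0], dtype=np.int64)
            u = rng.random(ps.shape[0])
            for s in range(4):
                sel = ps == s
                if sel.any():
                    cdf = np.cumsum(P[s])
                    draw[sel] = np.searchsorted(cdf, u[sel])
            states[mask] = np.clip(draw, 0, 3)
        node._states = states
    out = {}
    for leaf in tree.leaf_node_iter():
        out[leaf.taxon.label] = "".join(BASES[s] for s in leaf._states)
    return out, tree


def evolve_pair(distance: float, model, sites: int, seed: int = 0
                ) -> dict[str, str]:
    """Two sequences separated by a total path length ``distance``."""
    half = distance / 2
    newick = f"(A:{half:.10g},B:{half:.10g});"
    aln, _ = evolve_alignment(EvolSpec(tree=newick, model=model, sites=sites,
                                       seed=seed))
    return aln


def simulate_clock_tree(n_taxa: int, seed: int = 0, depth: float = 1.0,
                        ) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """Random ultrametric (strictly clock-like) tree via recursive splitting.

    Returns the tree and the true node depths keyed by the frozenset of
    descendant tip labels (tips at depth 0, root at ``depth``).
    """
    rng = np.random.default_rng(seed)
    labels = [f"T{i+1}" for i in range(n_taxa)]
    heights: dict[frozenset, float] = {}

    def build(tips: list[str], parent_h: float) -> str:
        if len(tips) == 1:
            return f"{tips[0]}:{parent_h:.10g}"
        node_h = parent_h * float(rng.uniform(0.3, 0.8))
        heights[frozenset(tips)] = node_h
        k = int(rng.integers(1, len(tips)))
        return (f"({build(tips[:k], node_h)},{build(tips[k:], node_h)})"
                f":{parent_h - node_h:.10g}")

    heights[frozenset(labels)] = depth
    k = int(rng.integers(1, n_taxa))
    newick = (f"({build(labels[:k], depth)},"
              f"{build(labels[k:], depth)});")
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tree, heights


def apply_rate_noise(tree: dendropy.Tree, sigma: float, seed: int = 0
                     ) -> dendropy.Tree:
    """Multiply every branch length by an i.i.d. lognormal(0, sigma) rate."""
    rng = np.random.default_rng(seed)
    noisy = tree.clone(depth=1)
    for edge in noisy.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * float(rng.lognormal(0.0, sigma))
    return noisy
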