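"""Gene-architecture accounting for annotated mitogenomes.

Junction gaps/overlaps, strand distribution, extreme-length protein-coding
genes, signed gene-order strings, and comparison against the canonical
teleost arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import MitoGenome
from .vocab import CANONICAL_TELEOST_ORDER


@dataclass(frozen=True)
class Junction:
    """Signed gap between two adjacent annotations.

    ``gap = start(downstream) - end(upstream) - 1``: positive values are
    intergenic spacers, negative values overlaps, zero contiguity.  The
    circular closing junction (last feature back to the first) uses the same
    formula modulo genome length.
    """

    upstream: str
    downstream: str
    gap: int


@dataclass
class ArchitectureReport:
    junctions: list[Junction]
    n_overlaps: int
    total_overlap_bp: int
    longest_overlap: tuple[int, str] | None
    n_spacers: int
    total_spacer_bp: int
    longest_spacer: tuple[int, str] | None
    strand_counts: dict[str, int]
    shortest_pcg: tuple[str, int] | None
    longest_pcg: tuple[str, int] | None
    gene_order: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_contiguous(self) -> int:
        return len(self.junctions) - self.n_overlaps - self.n_spacers


def junction_gaps(genome: MitoGenome,
                  include_circular_closure: bool = False) -> list[Junction]:
    """One :class:`Junction` per adjacent feature pair in annotation order.

    With ``include_circular_closure`` the wrap-around junction from the last
    feature back to the first is appended, computed modulo genome length.
    """
    feats = genome.features
    if len(feats) < 2:
        raise ValueError("need at least two features")
    if any(feats[i].start > feats[i + 1].start for i in range(len(feats) - 1)):
        raise RuntimeError("features are not sorted by start")
    out = [
        Junction(a.name, b.name, b.start - a.end - 1)
        for a, b in zip(feats, feats[1:])
    ]
    if include_circular_closure:
        last, first = feats[-1], feats[0]
        gap = (first.start - last.end - 1) % genome.genome_length
        out.append(Junction(last.name, first.name, gap))
    return out


def gene_order(genome: MitoGenome) -> list[tuple[str, int]]:
    """Signed gene-name sequence in annotation order, rotated to start at trnF
    when present (+1 = heavy strand, -1 = light strand)."""
    order = [(f.name, 1 if f.strand == "H" else -1) for f in genome.features]
    names = [n for n, _ in order]
    if "trnF" in names:
        i = names.index("trnF")
        order = order[i:] + order[:i]
    return order


def architecture_summary(genome: MitoGenome,
                         include_circular_closure: bool = False) -> ArchitectureReport:
    """Full architecture accounting.

    The junction chain is linear in annotation order by default (circular
    closure opt-in), matching how annotation tables attach intergenic counts
    to the upstream gene row.  The control region is part of the junction
    chain but excluded from strand counts (it is not a gene).  Ties for
    longest spacer/overlap break to the first occurrence.
    """
    juncs = junction_gaps(genome, include_circular_closure)
    overlaps = [j for j in juncs if j.gap < 0]
    spacers = [j for j in juncs if j.gap > 0]

    def _extreme(js: list[Junction]) -> tuple[int, str] | None:
        if not js:
            return None
        best = max(js, key=lambda j: abs(j.gap))
        return abs(best.gap), f"{best.upstream}-{best.downstream}"

    strand_counts = {"H": 0, "L": 0}
    for f in genome.genes:
        strand_counts[f.strand] += 1

    pcgs = [f for f in genome.features if f.ftype == "PCG"]
    shortest = min(pcgs, key=lambda f: f.length) if pcgs else None
    longest = max(pcgs, key=lambda f: f.length) if pcgs else None

    return ArchitectureReport(
        junctions=juncs,
        n_overlaps=len(overlaps),
        total_overlap_bp=sum(-j.gap for j in overlaps),
        longest_overlap=_extreme(overlaps),
        n_spacers=len(spacers),
        total_spacer_bp=sum(j.gap for j in spacers),
        longest_spacer=_extreme(spacers),
        strand_counts=strand_counts,
        shortest_pcg=(shortest.name, shortest.length) if shortest else None,
        longest_pcg=(longest.name, longest.length) if longest else None,
        gene_order=gene_order(genome),
    )


def _adjacency_set(order: list[tuple[str, int]]) -> set[tuple[str, int, str, int]]:
    """Strand-aware circular adjacency set; orientation-normalized so that a
    jointly inverted adjacency matches its mirror."""
    adj = set()
    n = len(order)
    for i in range(n):
        (a, sa), (b, sb) = order[i], order[(i + 1) % n]
        fwd = (a, sa, b, sb)
        rev = (b, -sb, a, -sa)
        adj.add(min(fwd, rev))
    return adj


def compare_gene_order(a: MitoGenome | list[tuple[str, int]],
                       b: MitoGenome | list[tuple[str, int]] | str = "teleost",
                       ) -> dict:
    """Compare two signed circular gene orders.

    ``b`` may be a genome, an explicit signed order, or the named reference
    ``"teleost"`` (the canonical vertebrate/teleost arrangement).  Returns a
    record with an identity flag, the adjacencies of one order absent from
    the other, the breakpoint distance, and any genes missing from one side
    (reported, never raised).
    """
    order_a = gene_order(a) if isinstance(a, MitoGenome) else list(a)
    if isinstance(b, str):
        if b != "teleost":
            raise ValueError(f"unknown reference order {b!r}")
        order_b = list(CANONICAL_TELEOST_ORDER)
    else:
        order_b = gene_order(b) if isinstance(b, MitoGenome) else list(b)

    names_a = {n for n, _ in order_a}
    names_b = {n for n, _ in order_b}
    missing = sorted((names_a ^ names_b))
    common = names_a & names_b
    ra = [(n, s) for n, s in order_a if n in common]
    rb = [(n, s) for n, s in order_b if n in common]
    adj_a, adj_b = _adjacency_set(ra), _adjacency_set(rb)
    differing = sorted(adj_a - adj_b)
    distance = len(differing)
    return dict(
        identical=(distance == 0 and not missing and ra == _rotate_like(rb, ra)),
        breakpoint_distance=distance,
        differing_adjacencies=differing,
        missing_genes=missing,
    )


def _rotate_like(order: list[tuple[str, int]],
                 template: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Rotate a circular order to start at the template's first gene."""
    if not order or not template:
        return order
    names = [n for n, _ in order]
    first = template[0][0]
    if first in names:
        i = names.index(first)
        return order[i:] + order[:i]
    return order
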