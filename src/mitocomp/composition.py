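"""Nucleotide composition, AT/GC skews, and start/stop codon classification.

Skew conventions: AT-skew = (A - T)/(A + T), GC-skew = (G - C)/(G + C),
computed interchangeably from counts or percentages (scale-invariant).
Partition composition is measured on the deposited heavy (plus) strand for
every partition — light-strand genes contribute their plus-strand substring —
while codon classification alone works on sense strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .io import GenomeStateError, MitoGenome, extract_feature_sequence
from .vocab import revcomp

PARTITIONS = ("whole", "PCGs", "rRNAs", "tRNAs", "CR")
_PARTITION_OF_FTYPE = {"PCG": "PCGs", "rRNA": "rRNAs", "tRNA": "tRNAs", "CR": "CR"}


class UndefinedSkewError(ValueError):
    """A+T (or G+C) is zero: the corresponding skew is undefined, not 0."""


def _round(x: float, places: int) -> float:
    """Half-up rounding at the reporting boundary."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PartitionStats:
    partition: str
    length: int
    pct_A: float
    pct_T: float
    pct_G: float
    pct_C: float
    pct_AT: float
    at_skew: float | None
    gc_skew: float | None


@dataclass(frozen=True)
class CodonReport:
    gene: str
    start_codon: str
    stop_codon: str
    stop_class: str  # "complete" | "incomplete"


def base_composition(seq: str, partition: str = "whole") -> PartitionStats:
    """Percent composition (2 decimals) and skews (3 decimals) of a sequence.

    N's are excluded from the percentage denominator; ``length`` reports the
    full sequence length.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    pct = {b: 100.0 * counts[b] / denom for b in "ACGT"}
    try:
        at, gc = skews(counts["A"], counts["T"], counts["G"], counts["C"])
    except UndefinedSkewError:
        at = gc = None
        if counts["A"] + counts["T"] > 0:
            at, _ = skews(counts["A"], counts["T"], 1, 1)
        if counts["G"] + counts["C"] > 0:
            _, gc = skews(1, 1, counts["G"], counts["C"])
    return PartitionStats(
        partition=partition,
        length=len(seq),
        pct_A=_round(pct["A"], 2), pct_T=_round(pct["T"], 2),
        pct_G=_round(pct["G"], 2), pct_C=_round(pct["C"], 2),
        pct_AT=_round(pct["A"] + pct["T"], 2),
        at_skew=at, gc_skew=gc,
    )


def skews(A: float, T: float, G: float, C: float) -> tuple[float, float]:
    """(AT-skew, GC-skew) from counts or percentages, 3-decimal reporting."""
    if A + T <= 0 or G + C <= 0:
        raise UndefinedSkewError("skew undefined when A+T or G+C is zero")
    return _round((A - T) / (A + T), 3), _round((G - C) / (G + C), 3)


def partition_sequences(genome: MitoGenome) -> dict[str, str]:
    """Plus-strand concatenated sequence per partition, in annotation order."""
    if genome.sequence is None:
        raise GenomeStateError("genome carries no sequence")
    parts: dict[str, list[str]] = {p: [] for p in PARTITIONS}
    parts["whole"].append(genome.sequence)
    for f in genome.features:
        sub = genome.sequence[f.start - 1:f.end]
        parts[_PARTITION_OF_FTYPE[f.ftype]].append(sub)
    return {p: "".join(chunks) for p, chunks in parts.items() if chunks}


def partition_stats(genome: MitoGenome) -> list[PartitionStats]:
    """Composition rows for whole genome, PCGs, rRNAs, tRNAs and CR.

    Partitions with no member features are omitted (with a warning via the
    returned row set simply lacking them).
    """
    return [
        base_composition(seq, partition=p)
        for p, seq in partition_sequences(genome).items()
    ]


def classify_codons(genome: MitoGenome) -> list[CodonReport]:
    """Start/stop codon report per protein-coding gene.

    The start codon is the first sense-strand triplet.  The stop codon is
    classified from sense length mod 3: remainder 0 reports the final
    triplet as a complete stop; remainder 1 the final base as ``X--``;
    remainder 2 the final two bases as ``XY-`` — the incomplete forms
    completed to TAA by post-transcriptional polyadenylation in vivo.
    """
    reports = []
    for f in genome.features:
        if f.ftype != "PCG":
            continue
        seq = extract_feature_sequence(genome, f)
        if len(seq) < 6:
            raise ValueError(f"{f.name}: PCG shorter than 6 nt")
        rem = len(seq) % 3
        if rem == 0:
            stop, cls = seq[-3:], "complete"
        elif rem == 1:
            stop, cls = seq[-1] + "--", "incomplete"
        else:
            stop, cls = seq[-2:] + "-", "incomplete"
        reports.append(CodonReport(f.name, seq[:3], stop, cls))
    return reports


def sense_partition_sequences(genome: MitoGenome) -> dict[str, str]:
    """Sense-strand variant of :func:`partition_sequences` (codon analyses)."""
    if genome.sequence is None:
        raise GenomeStateError("genome carries no sequence")
    parts: dict[str, list[str]] = {}
    for f in genome.features:
        sub = genome.sequence[f.start - 1:f.end]
        if f.strand == "L":
            sub = revcomp(sub)
        parts.setdefault(_PARTITION_OF_FTYPE[f.ftype], []).append(sub)
    return {p: "".join(v) for p, v in parts.items()}
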