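"""Control-region analytics: tandem repeats, CSB motif scanning, variable sites.

The repeat scanner is a deterministic period scan (compare ``seq[i]`` with
``seq[i+p]``), not a probabilistic alignment: at control-region scale (~1 kb)
this is exact, reproducible and oracle-checkable.  CSB detection is a best
ungapped local alignment of each library motif (match +1 / mismatch -1); the
shipped default motif library is an editable FASTA and results on real data
are explicitly library-dependent.  Spans are 1-based inclusive within the
scanned sequence; alignment column indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter


@dataclass
class RepeatRecord:
    period: int
    copies: float
    span: tuple[int, int]  # 1-based inclusive within the scanned sequence
    consensus: str
    identity: float


@dataclass
class CSBHit:
    block: str
    span: tuple[int, int] | None  # None when the block is absent
    score: int | None
    identity: float | None
    present: bool
    variable_sites: list[int] | None = None


def _exact_runs(match: list[bool]) -> list[tuple[int, int]]:
    runs, s = [], None
    for i, x in enumerate(match):
        if x and s is None:
            s = i
        elif not x and s is not None:
            runs.append((s, i - 1))
            s = None
    if s is not None:
        runs.append((s, len(match) - 1))
    return runs


def _merge_runs(runs: list[tuple[int, int]], min_identity: float):
    """Greedy left-to-right merge of exact-match runs while the merged
    stretch keeps identity >= threshold."""
    merged = []
    for s, e in runs:
        if merged:
            ps, pe, pm = merged[-1]
            span = e - ps + 1
            matches = pm + (e - s + 1)
            if matches / span >= min_identity:
                merged[-1] = (ps, e, matches)
                continue
        merged.append((s, e, e - s + 1))
    return [(s, e) for s, e, _ in merged]


def find_tandem_repeats(seq: str, min_period: int = 2, max_period: int = 100,
                        min_copies: float = 2.0, min_identity: float = 0.9,
                        ) -> list[RepeatRecord]:
    """Detect tandem repeats by deterministic period scanning.

    For each period ``p`` the scan marks positions where ``seq[i] ==
    seq[i+p]``, merges match runs while identity stays above threshold, and
    emits maximal regions with at least ``min_copies`` (fractional copies
    allowed).  The consensus is the column-majority string over the aligned
    copies; overlapping reports of the same locus across periods collapse to
    the highest-identity, then smallest-period record.
    """
    seq = seq.upper()
    L = len(seq)
    if not (1 <= min_period <= max_period <= L // 2):
        raise ValueError("invalid period thresholds")
    if min_copies < 1 or not (0 < min_identity <= 1):
        raise ValueError("invalid copy/identity thresholds")

    records: list[RepeatRecord] = []
    for p in range(min_period, max_period + 1):
        match = [seq[i] == seq[i + p] for i in range(L - p)]
        for s, e in _merge_runs(_exact_runs(match), min_identity):
            span_len = e - s + 1 + p
            copies = span_len / p
            if copies < min_copies:
                continue
            region = seq[s:s + span_len]
            consensus = "".join(
                Counter(region[j::p]).most_common(1)[0][0] for j in range(p)
            )
            ident = sum(
                region[i] == consensus[i % p] for i in range(span_len)
            ) / span_len
            if ident < min_identity:
                continue
            records.append(RepeatRecord(
                period=p, copies=round(copies, 2), span=(s + 1, s + span_len),
                consensus=consensus, identity=round(ident, 4),
            ))
    return _collapse(records)


def _collapse(records: list[RepeatRecord]) -> list[RepeatRecord]:
    """Collapse overlapping records of the same locus: keep the
    highest-identity, then smallest-period representative."""
    records = sorted(records, key=lambda r: (-r.identity, r.period,
                                             r.span[0]))
    kept: list[RepeatRecord] = []
    for rec in records:
        s, e = rec.span
        if any(not (e < k.span[0] or s > k.span[1]) for k in kept):
            continue
        kept.append(rec)
    return sorted(kept, key=lambda r: r.span)


CSB_ORDER = ("CSB-D", "CSB-I", "CSB-II", "CSB-III")


def scan_csb(cr_seq: str, motif_library: dict[str, str] | None = None,
             min_score_fraction: float = 0.5) -> list[CSBHit]:
    """Locate conserved sequence blocks in a control-region sequence.

    Each motif is slid ungapped along the sequence; the best window scores
    ``matches - mismatches`` and the block is called present when the score
    reaches ``min_score_fraction * len(motif)`` (0.5 corresponds to 75%
    identity).  Hits come back in genome order of their spans.
    """
    if motif_library is None:
        from .datasets import default_csb_motifs
        motif_library = default_csb_motifs()
    if not motif_library:
        raise ValueError("empty motif library")
    cr_seq = cr_seq.upper()
    hits: list[CSBHit] = []
    for block, motif in motif_library.items():
        motif = motif.upper()
        m = len(motif)
        best_score, best_at = None, None
        for off in range(len(cr_seq) - m + 1):
            window = cr_seq[off:off + m]
            matches = sum(a == b for a, b in zip(window, motif))
            score = 2 * matches - m
            if best_score is None or score > best_score:
                best_score, best_at = score, off
        if best_score is not None and best_score >= min_score_fraction * m:
            identity = (best_score + m) / (2 * m)
            hits.append(CSBHit(block=block, span=(best_at + 1, best_at + m),
                               score=best_score, identity=round(identity, 4),
                               present=True))
        else:
            hits.append(CSBHit(block=block, span=None, score=best_score,
                               identity=None, present=False))
    present = sorted((h for h in hits if h.present), key=lambda h: h.span)
    absent = [h for h in hits if not h.present]
    return present + absent


def variable_sites(aligned_blocks: dict[str, list[str]] | list[str]) -> dict:
    """Variable and parsimony-informative alignment columns per block.

    A variable column carries >= 2 distinct bases; a parsimony-informative
    column carries >= 2 bases each present in >= 2 sequences.  Column indices
    are 0-based.  Raises ``ValueError`` on ragged alignments.
    """
    if isinstance(aligned_blocks, list):
        aligned_blocks = {"block": aligned_blocks}
    out = {}
    for block, seqs in aligned_blocks.items():
        if len(seqs) < 2:
            raise ValueError(f"{block}: need >= 2 sequences")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"{block}: ragged sequence lengths {lengths}")
        variable, informative = [], []
        for j in range(lengths.pop()):
            col = Counter(s[j].upper() for s in seqs)
            if len(col) >= 2:
                variable.append(j)
                if sum(1 for c in col.values() if c >= 2) >= 2:
                    informative.append(j)
        out[block] = {"variable": variable,
                      "parsimony_informative": informative}
    return out
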