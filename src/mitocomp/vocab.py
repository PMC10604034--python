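"""Controlled gene vocabulary and naming conventions for vertebrate mitogenomes.

The 37-gene vertebrate mitochondrial complement is referred to throughout the
package by MITOS-style lowercase labels: ``nad1``..``nad6`` + ``nad4l`` and
``cox1``..``cox3``, ``atp6``/``atp8``, ``cob`` for the protein-coding genes,
``rrnS``/``rrnL`` for the ribosomal RNAs, ``trnX`` (one-letter amino-acid code)
for the tRNAs, and ``CR`` for the control region.  The two leucine and two
serine tRNAs carry isoacceptor tags: ``trnL1`` (CUN codons), ``trnL2`` (UUR),
``trnS1`` (AGY), ``trnS2`` (UCN).
"""

from __future__ import annotations

PCG_NAMES = (
    "nad1", "nad2", "cox1", "cox2", "atp8", "atp6", "cox3",
    "nad3", "nad4l", "nad4", "nad5", "nad6", "cob",
)

TRNA_NAMES = (
    "trnF", "trnV", "trnL2", "trnI", "trnQ", "trnM", "trnW", "trnA", "trnN",
    "trnC", "trnY", "trnS2", "trnD", "trnK", "trnG", "trnR", "trnH", "trnS1",
    "trnL1", "trnE", "trnT", "trnP",
)

RRNA_NAMES = ("rrnS", "rrnL")

GENE_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES

#: Canonical vertebrate/teleost gene order starting at trnF, with strand signs
#: (+1 heavy, -1 light).  This is the arrangement shared by most teleosts and
#: used as the reference for gene-order comparison.
CANONICAL_TELEOST_ORDER: tuple[tuple[str, int], ...] = (
    ("trnF", 1), ("rrnS", 1), ("trnV", 1), ("rrnL", 1), ("trnL2", 1),
    ("nad1", 1), ("trnI", 1), ("trnQ", -1), ("trnM", 1), ("nad2", 1),
    ("trnW", 1), ("trnA", -1), ("trnN", -1), ("trnC", -1), ("trnY", -1),
    ("cox1", 1), ("trnS2", -1), ("trnD", 1), ("cox2", 1), ("trnK", 1),
    ("atp8", 1), ("atp6", 1), ("cox3", 1), ("trnG", 1), ("nad3", 1),
    ("trnR", 1), ("nad4l", 1), ("nad4", 1), ("trnH", 1), ("trnS1", 1),
    ("trnL1", 1), ("nad5", 1), ("nad6", -1), ("trnE", -1), ("cob", 1),
    ("trnT", 1), ("trnP", -1), ("CR", 1),
)

# Synonym table for labels seen in GenBank records and published tables.
_SYNONYMS = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6",
    "nad1": "nad1", "nad2": "nad2", "nad3": "nad3", "nad4": "nad4",
    "nad4l": "nad4l", "nad5": "nad5", "nad6": "nad6",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "cox1": "cox1", "cox2": "cox2", "cox3": "cox3",
    "atp6": "atp6", "atp8": "atp8", "atpase6": "atp6", "atpase8": "atp8",
    "cytb": "cob", "cob": "cob", "cyt b": "cob",
    "12s rrna": "rrnS", "16s rrna": "rrnL", "12s": "rrnS", "16s": "rrnL",
    "rrns": "rrnS", "rrnl": "rrnL",
    "s-rrna": "rrnS", "l-rrna": "rrnL",
    "control region": "CR", "d-loop": "CR", "cr": "CR",
}

_AA3_TO_1 = {
    "phe": "F", "val": "V", "leu": "L", "ile": "I", "gln": "Q", "met": "M",
    "trp": "W", "ala": "A", "asn": "N", "cys": "C", "tyr": "Y", "ser": "S",
    "asp": "D", "lys": "K", "gly": "G", "arg": "R", "his": "H", "glu": "E",
    "thr": "T", "pro": "P",
}

# Codon-family triplets (as printed in annotation tables) -> isoacceptor tag.
_ISOACCEPTOR_BY_TRIPLET = {
    ("L", "TTA"): "trnL2", ("L", "TAA"): "trnL2",
    ("L", "CTA"): "trnL1", ("L", "TAG"): "trnL1",
    ("S", "TCA"): "trnS2", ("S", "TGA"): "trnS2",
    ("S", "AGC"): "trnS1", ("S", "GCT"): "trnS1",
}

VERTEBRATE_MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_gene_name(raw: str, anticodon: str | None = None) -> str:
    """Map a free-form gene label to the controlled vocabulary.

    Handles NAD/ND spellings, COI/COX numbering, Cytb/cob, rRNA labels, the
    control region, and tRNAs given either as ``tRNA-Leu`` (isoacceptor
    resolved from the supplied triplet) or already-tagged ``trnL1`` forms.
    Unrecognized labels are returned stripped but otherwise unchanged.
    """
    label = raw.strip()
    key = label.lower()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    if key.startswith("trna-") or key.startswith("trn"):
        rest = key[5:] if key.startswith("trna-") else key[3:]
        rest = rest.strip()
        if rest in _AA3_TO_1:
            aa = _AA3_TO_1[rest]
        elif len(rest) in (1, 2) and rest[0].upper() in "FVLIQMWANCYSDKGRHETP":
            tagged = "trn" + rest[0].upper() + rest[1:]
            if tagged in TRNA_NAMES:
                return tagged
            aa = rest[0].upper()
        else:
            return label
        if aa in ("L", "S"):
            if anticodon:
                tag = _ISOACCEPTOR_BY_TRIPLET.get((aa, anticodon.upper()))
                if tag:
                    return tag
            return "trn" + aa  # ambiguous isoacceptor, caller may disambiguate
        return "trn" + aa
    return label


def classify_ftype(name: str) -> str:
    """Feature class for a controlled-vocabulary name: PCG, tRNA, rRNA or CR."""
    if name in PCG_NAMES:
        return "PCG"
    if name in RRNA_NAMES:
        return "rRNA"
    if name == "CR":
        return "CR"
    if name.startswith("trn"):
        return "tRNA"
    raise ValueError(f"gene name not in controlled vocabulary: {name!r}")
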