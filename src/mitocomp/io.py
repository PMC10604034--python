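"""Readers/writers for mitogenome representations.

Coordinates are 1-based inclusive throughout the public surface, matching the
convention of published mitogenome annotation tables.  Conversion to 0-based
slices happens only inside this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .vocab import classify_ftype, normalize_gene_name, revcomp

VALID_STRANDS = ("H", "L")
FTYPES = ("PCG", "tRNA", "rRNA", "CR")


class CoordinateError(ValueError):
    """A feature's coordinates are inconsistent or exceed the genome."""


class GenomeStateError(RuntimeError):
    """An operation needs data (e.g. sequence) the genome does not carry."""


@dataclass(frozen=True)
class Feature:
    """A single annotated feature on the circular mitogenome.

    ``start``/``end`` are 1-based inclusive with ``end >= start`` (features in
    input tables never wrap the origin).  ``anticodon`` holds the triplet
    printed by the annotation (codon-family style) and is present iff the
    feature is a tRNA.
    """

    name: str
    ftype: str
    start: int
    end: int
    strand: str
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.ftype not in FTYPES:
            raise ValueError(f"unknown ftype {self.ftype!r}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be H or L, got {self.strand!r}")
        if self.end < self.start:
            raise CoordinateError(
                f"{self.name}: end {self.end} < start {self.start}"
            )
        if (self.ftype == "tRNA") != (self.anticodon is not None):
            raise ValueError(
                f"{self.name}: anticodon must be present iff ftype is tRNA"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MitoGenome:
    """A circular mitogenome: sequence (optional) plus ordered annotations."""

    accession: str
    genome_length: int
    features: list[Feature] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise ValueError(f"disallowed sequence characters: {sorted(bad)}")
            if len(self.sequence) != self.genome_length:
                raise ValueError(
                    f"genome_length {self.genome_length} != sequence length "
                    f"{len(self.sequence)}"
                )
        for f in self.features:
            if f.end > self.genome_length:
                raise CoordinateError(
                    f"{f.name} ends at {f.end} beyond genome length "
                    f"{self.genome_length}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        self._check_duplicates()

    def _check_duplicates(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise ValueError(f"duplicate gene name {f.name!r}")
            seen.add(f.name)

    @property
    def genes(self) -> list[Feature]:
        """All features except the control region."""
        return [f for f in self.features if f.ftype != "CR"]

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def _resolve_isoacceptors(rows: list[dict]) -> None:
    """Disambiguate trnL/trnS rows lacking a usable triplet by genome order.

    In the canonical arrangement trnL2 (UUR) precedes trnL1 (CUN) and trnS2
    (UCN) precedes trnS1 (AGY); annotation order is used as the fallback when
    the printed triplet does not resolve the isoacceptor.
    """
    for base, order in (("trnL", ("trnL2", "trnL1")), ("trnS", ("trnS2", "trnS1"))):
        pending = [r for r in rows if r["name"] == base]
        if not pending:
            continue
        taken = {r["name"] for r in rows if r["name"] in order}
        free = [t for t in order if t not in taken]
        for r, tag in zip(sorted(pending, key=lambda r: r["start"]), free):
            r["name"] = tag


def read_feature_table(path: str | Path, genome_length: int) -> MitoGenome:
    """Load a TSV annotation table (columns: gene, start, end, strand, and
    optionally anticodon, ftype, size) into a :class:`MitoGenome` without
    sequence.

    Sizes are recomputed as ``end - start + 1``; a provided size column that
    disagrees triggers a warning, never an error.  ``start > end`` raises
    :class:`CoordinateError`; a duplicate non-isoacceptor gene name raises
    ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"gene", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")

    rows: list[dict] = []
    for _, r in df.iterrows():
        start = int(str(r["start"]).replace(",", ""))
        end = int(str(r["end"]).replace(",", ""))
        if start > end:
            raise CoordinateError(f"{r['gene']}: start {start} > end {end}")
        anticodon = None
        if "anticodon" in df.columns and isinstance(r.get("anticodon"), str):
            val = r["anticodon"].strip()
            if val and val != ".":
                anticodon = val.upper()
        name = normalize_gene_name(str(r["gene"]), anticodon)
        try:
            ftype = classify_ftype(name) if name not in ("trnL", "trnS") else "tRNA"
        except ValueError:
            ftype = str(r.get("ftype", "")).strip() or "PCG"
        if ftype == "tRNA" and anticodon is None:
            anticodon = "NNN"
        if "size" in df.columns and isinstance(r.get("size"), str):
            printed = r["size"].replace(",", "").strip()
            if printed and printed != "." and int(printed) != end - start + 1:
                warnings.warn(
                    f"{name}: printed size {printed} != recomputed "
                    f"{end - start + 1}", stacklevel=2,
                )
        rows.append(dict(name=name, ftype=ftype, start=start, end=end,
                         strand=str(r["strand"]).strip(), anticodon=anticodon))
    _resolve_isoacceptors(rows)
    feats = [Feature(**r) for r in rows]
    return MitoGenome(accession=Path(path).stem, genome_length=genome_length,
                      features=feats)


def write_feature_table(genome: MitoGenome, path: str | Path) -> None:
    """Write the annotation to TSV (columns gene,ftype,start,end,strand,anticodon)."""
    df = pd.DataFrame(
        [
            dict(gene=f.name, ftype=f.ftype, start=f.start, end=f.end,
                 strand=f.strand, anticodon=f.anticodon or ".")
            for f in genome.features
        ]
    )
    df.to_csv(path, sep="\t", index=False)


_GENBANK_KEYS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}


def read_genbank(path: str | Path) -> MitoGenome:
    """Parse a GenBank flat file with CDS/tRNA/rRNA/D-loop features.

    Feature labels are taken from ``gene``/``product``/``note`` qualifiers and
    mapped to the controlled vocabulary; unknown feature keys are skipped.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    seq = str(record.seq).upper()
    rows: list[dict] = []
    for feat in record.features:
        ftype = _GENBANK_KEYS.get(feat.type)
        if ftype is None:
            continue
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        if end > len(seq):
            raise CoordinateError(
                f"feature {feat.type} at {start}..{end} exceeds sequence "
                f"length {len(seq)}"
            )
        strand = "L" if feat.location.strand == -1 else "H"
        quals = feat.qualifiers
        label = (quals.get("gene") or quals.get("product") or
                 quals.get("note") or [feat.type])[0]
        anticodon = None
        if ftype == "tRNA":
            ac = quals.get("anticodon") or quals.get("codon_recognized")
            anticodon = ac[0].upper() if ac else "NNN"
        name = normalize_gene_name(label, anticodon)
        if ftype == "CR":
            name = "CR"
        rows.append(dict(name=name, ftype=ftype, start=start, end=end,
                         strand=strand, anticodon=anticodon))
    _resolve_isoacceptors(rows)
    feats = [Feature(**r) for r in rows]
    return MitoGenome(accession=record.id or Path(path).stem,
                      genome_length=len(seq), features=feats, sequence=seq)


def write_genbank(genome: MitoGenome, path: str | Path) -> None:
    """Write a minimal GenBank flat file (sequence + gene features)."""
    if genome.sequence is None:
        raise GenomeStateError("cannot write GenBank without a sequence")
    from Bio.SeqFeature import SeqFeature, SimpleLocation

    rec = SeqRecord(Seq(genome.sequence), id=genome.accession,
                    name=genome.accession[:16], description="mitogenome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    key_of = {v: k for k, v in _GENBANK_KEYS.items()}
    for f in genome.features:
        loc = SimpleLocation(f.start - 1, f.end,
                             strand=-1 if f.strand == "L" else 1)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        rec.features.append(SeqFeature(loc, type=key_of[f.ftype],
                                       qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def extract_feature_sequence(genome: MitoGenome, feature: Feature) -> str:
    """Sense-strand sequence of a feature.

    H-strand features return the plus-strand substring; L-strand features its
    reverse complement.  ``end < start`` signals an origin-spanning feature
    (internal calls on circular synthetic genomes only).
    """
    if genome.sequence is None:
        raise GenomeStateError("genome carries no sequence")
    if feature.end >= feature.start:
        plus = genome.sequence[feature.start - 1:feature.end]
    else:  # wraps the origin
        plus = (genome.sequence[feature.start - 1:] +
                genome.sequence[:feature.end])
    return revcomp(plus) if feature.strand == "L" else plus


def flip_strand(feature: Feature) -> Feature:
    return replace(feature, strand="L" if feature.strand == "H" else "H")
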