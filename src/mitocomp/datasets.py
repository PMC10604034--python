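"""Packaged reference datasets.

Ships the published annotation table of the *Psettodes belcheri* mitogenome
(GenBank OR231239) and the published partition-composition table for the three
*Psettodes* records, so the characterization stages can be exercised and
checked without network access.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import MitoGenome, read_feature_table

BELCHERI_GENOME_LENGTH = 16747


def _data_path(name: str):
    return resources.files("mitocomp").joinpath("data", name)


def load_belcheri_table() -> MitoGenome:
    """The P. belcheri (OR231239) annotation as a sequence-less genome.

    38 features: 13 PCGs, 22 tRNAs, 2 rRNAs and the control region on a
    16,747 bp circle.
    """
    with resources.as_file(_data_path("psettodes_belcheri_or231239.tsv")) as p:
        return read_feature_table(p, genome_length=BELCHERI_GENOME_LENGTH)


def load_belcheri_codons() -> pd.DataFrame:
    """Printed start/stop codons per PCG from the deposited annotation."""
    with resources.as_file(_data_path("psettodes_belcheri_or231239.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    df = df[df["start_codon"] != "."][["gene", "start_codon", "stop_codon"]]
    return df.reset_index(drop=True)


def load_psettodes_composition() -> pd.DataFrame:
    """Published partition-wise composition of the three Psettodes records."""
    with resources.as_file(_data_path("psettodes_composition.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def default_csb_motifs() -> dict[str, str]:
    """The shipped (synthetic, editable) CSB consensus motif library."""
    text = _data_path("csb_motifs.fasta").read_text()
    motifs: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            motifs[name] = ""
        elif name:
            motifs[name] += line.upper()
    return motifs
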