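"""Small alphabet helpers shared across modules.

Genomic sequences and FASTQ reads live in the DNA alphabet; mature miRNAs and
everything duplex-related live in RNA. All cross-alphabet comparisons go
through :func:`to_rna` / :func:`to_dna`.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")

#: canonical base pairs used for folding and duplex scoring (RNA alphabet)
WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}
CAN_PAIR = WATSON_CRICK | WOBBLE


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return to_rna(seq).translate(_RNA_COMP)[::-1]


def check_alphabet(seq: str, alphabet: str = "ACGU") -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"sequence contains non-{alphabet} characters: {sorted(bad)}")
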