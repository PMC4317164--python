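"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CODON_STOPS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case; N maps to N."""
    return seq.translate(_RC)[::-1]


def u_to_t(seq: str) -> str:
    """Normalize an RNA-alphabet sequence to DNA (U/u -> T/t)."""
    return seq.replace("U", "T").replace("u", "t")


def translate(seq: str) -> str:
    """Translate complete codons; trailing partial codon ignored. Unknown codons -> 'X'."""
    return "".join(
        _CODON_TABLE.get(seq[i : i + 3].upper(), "X")
        for i in range(0, len(seq) - 2, 3)
    )


def is_stop(codon: str) -> bool:
    return codon.upper() in _CODON_STOPS


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform-composition random DNA sequence of length n."""
    return "".join(rng.choice(list(BASES), size=n))
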