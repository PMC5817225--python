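"""Small sequence helpers used across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

BASES = np.array(list("ACGT"))


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet out)."""
    return seq.translate(_COMP)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def random_seq(rng: np.random.Generator, n: int, p=(0.29, 0.21, 0.21, 0.29)) -> str:
    """Random DNA with a mild AT bias (noncoding-like composition)."""
    return "".join(rng.choice(BASES, size=n, p=list(p)))


_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
# fixed codon preference: GC-rich codons favoured, giving coding sequence a
# hexamer/composition signature distinct from the noncoding background
_CODON_W = np.array([1.0 + 2.0 * sum(ch in "GC" for ch in c) for c in _CODONS])
_CODON_P = _CODON_W / _CODON_W.sum()


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + codon-biased body + stop: a synthetic open reading frame."""
    body = "".join(rng.choice(np.array(_CODONS), size=n_codons - 2, p=_CODON_P))
    stop = rng.choice(np.array(sorted(_STOPS)))
    return "ATG" + body + stop
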