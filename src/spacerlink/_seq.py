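"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement (non-ACGT characters map to themselves or N)."""
    return seq.translate(_COMPLEMENT)[::-1]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int) -> str:
    """I.i.d. uniform nucleotide string of the given length."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate_substitutions(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Apply exactly ``n_mut`` substitutions at distinct positions."""
    if n_mut == 0:
        return seq
    if n_mut > len(seq):
        raise ValueError("more substitutions requested than positions")
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [b for b in ALPHABET if b != out[p]]
        out[p] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def encode(seq: str) -> np.ndarray:
    """Byte-encode a sequence for vectorized/compiled comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(encode(a) != encode(b)))


def count_motif(seq: str, motif: str) -> int:
    """Non-overlapping motif occurrences on the forward strand."""
    return seq.count(motif)
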