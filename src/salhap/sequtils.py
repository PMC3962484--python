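"""Fixed-length nucleotide sequence utilities.

All loci in this package are fixed-length (default 74 nt) strings over
{A, C, G, T}; comparing them is whole-locus Hamming comparison, so a handful
of small vectorised helpers cover every alignment-like step in the pipeline.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
LOCUS_LENGTH = 74


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array."""
    try:
        return np.fromiter((_BASE_TO_CODE[b] for b in seq), dtype=np.uint8,
                           count=len(seq))
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"non-ACGT base in sequence: {exc}") from None


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def encode_many(seqs) -> np.ndarray:
    """Encode a list of equal-length sequences as an (n, L) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences of unequal length: {sorted(lengths)}")
    return np.vstack([encode(s) for s in seqs])


def _one_hot(mat: np.ndarray) -> np.ndarray:
    n, length = mat.shape
    oh = np.zeros((n, length * 4), dtype=np.float32)
    cols = np.arange(length) * 4
    for i in range(n):
        oh[i, cols + mat[i]] = 1.0
    return oh


def hamming_matrix(seqs_a, seqs_b=None) -> np.ndarray:
    """Pairwise Hamming distances between two sets of equal-length sequences.

    Accepts lists of strings or pre-encoded uint8 matrices.  Uses a one-hot
    matmul (matches = X_a @ X_b.T), which is fast for the few thousand
    distinct sequences the pipeline sees.
    """
    a = seqs_a if isinstance(seqs_a, np.ndarray) else encode_many(seqs_a)
    if seqs_b is None:
        b = a
    else:
        b = seqs_b if isinstance(seqs_b, np.ndarray) else encode_many(seqs_b)
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[0]), dtype=np.int32)
    if a.shape[1] != b.shape[1]:
        raise ValueError("sequence length mismatch between the two sets")
    length = a.shape[1]
    matches = _one_hot(a) @ _one_hot(b).T
    return np.rint(length - matches).astype(np.int32)


def hamming(seq_a: str, seq_b: str) -> int:
    if len(seq_a) != len(seq_b):
        raise ValueError("sequence length mismatch")
    return sum(x != y for x, y in zip(seq_a, seq_b))


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length))


def mutate(seq: str, positions, bases) -> str:
    """Return ``seq`` with substitutions ``bases[i]`` at ``positions[i]``."""
    out = list(seq)
    for pos, base in zip(positions, bases):
        if out[pos] == base:
            raise ValueError(f"substitution at {pos} equals reference base")
        out[pos] = base
    return "".join(out)


def alternate_base(base: str, k: int = 0) -> str:
    """The k-th (0..2) base distinct from ``base``, in ACGT order."""
    others = [b for b in BASES if b != base]
    return others[k % 3]
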