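"""Low-level DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

from .errors import InvalidSequenceError

ALPHABET = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGT (case-insensitive) to uint8 codes 0..3."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise InvalidSequenceError(f"non-ACGT character {bad!r} in sequence")
    return arr


_DEC = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


def kmer_to_index(kmer: str) -> int:
    idx = 0
    for c in encode(kmer):
        idx = (idx << 2) | int(c)
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(ALPHABET[idx & 3])
        idx >>= 2
    return "".join(reversed(out))


def rolling_kmer_indices(codes: np.ndarray, k: int) -> np.ndarray:
    """Index of the k-mer *ending* at each position.

    Positions before the first full window use a left-truncated context,
    equivalent to left-padding with 'A' (code 0).
    """
    pad = np.concatenate([np.zeros(k - 1, dtype=codes.dtype), codes])
    windows = np.lib.stride_tricks.sliding_window_view(pad, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows.astype(np.int64) @ powers


def gc_count(kmer: str) -> int:
    return sum(1 for c in kmer if c in "GC")


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0
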