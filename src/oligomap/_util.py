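"""Small shared helpers: sequence arithmetic, vectorised Hamming scans, seeded RNG streams."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """ASCII bytes of a sequence as a uint8 vector (zero-copy view)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming_scan(subject: str, probe: str, max_mismatch: int = 1) -> list[tuple[int, int]]:
    """All placements of `probe` on `subject` within `max_mismatch` substitutions.

    Returns (start, mismatches) pairs with 1-based inclusive starts, in
    ascending order. Vectorised over the subject: one shifted comparison per
    probe base, so O(len(probe)) numpy passes.
    """
    s = encode(subject)
    p = encode(probe)
    n = len(s) - len(p) + 1
    if n <= 0:
        return []
    mism = np.zeros(n, dtype=np.int32)
    for i, base in enumerate(p):
        mism += s[i : i + n] != base
    hits = np.nonzero(mism <= max_mismatch)[0]
    return [(int(i) + 1, int(mism[i])) for i in hits]


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Named random stream derived from a master seed.

    Streams are keyed by a CRC of the label so that adding a new stream never
    perturbs existing ones, and identical (seed, label) always reproduces the
    same sequence.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals; adjacent (gap 0) intervals coalesce."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))
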