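"""Independent brute-force reference implementations used only by tests.

Deliberately written without reusing the package's search machinery: plain
window-by-window comparison over both strands.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_hits(
    sequences: dict[str, str], probe: str, max_mismatch: int = 1
) -> set[tuple[str, int, str, int]]:
    """Every (chrom, 1-based start, strand, mismatches) placement of the probe."""
    hits = set()
    L = len(probe)
    for strand in ("+", "-"):
        query = probe if strand == "+" else reverse_complement(probe)
        for chrom, seq in sequences.items():
            for i in range(len(seq) - L + 1):
                mm = 0
                for a, b in zip(seq[i : i + L], query):
                    if a != b:
                        mm += 1
                        if mm > max_mismatch:
                            break
                else:
                    hits.add((chrom, i + 1, strand, mm))
    return hits


def spliced_sequence(genome_seq: dict[str, str], chrom: str, blocks, strand: str) -> str:
    """Re-extract and splice genomic blocks; '-' returns the reverse complement."""
    joined = "".join(genome_seq[chrom][s - 1 : e] for s, e in blocks)
    return joined if strand == "+" else reverse_complement(joined)


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))
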