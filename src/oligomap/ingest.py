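"""Collapse per-array probe lists into a species-level non-redundant probe set.

A single probe sequence can appear on several array designs (and several
times on one array under different probeset/grid coordinates). Alignment is
computed once per unique sequence and fanned back out to every member probe,
so collapsing preserves the many-to-many probe<->array relationship exactly.
"""

from __future__ import annotations

from pathlib import Path

from .models import NonRedundantProbe, ProbeRecord


def collapse_probes(probes: list[ProbeRecord]) -> list[NonRedundantProbe]:
    """Group probes by exact sequence (case-insensitive, strand-sensitive).

    A probe and its reverse complement are distinct probes. Duplicate
    (array, probe_name) pairs are rejected. Output is ordered by the first
    appearance of each sequence, members in (array, probe_name) order.
    """
    seen: set[tuple[str, str]] = set()
    by_seq: dict[str, list[ProbeRecord]] = {}
    for p in probes:
        key = (p.array_name, p.probe_name)
        if key in seen:
            raise ValueError(f"duplicate probe {p.probe_name!r} on array {p.array_name!r}")
        seen.add(key)
        by_seq.setdefault(p.sequence.upper(), []).append(p)
    collapsed = []
    for seq, members in by_seq.items():
        members.sort(key=lambda p: (p.array_name, p.probe_name))
        collapsed.append(NonRedundantProbe(sequence=seq, members=members))
    return collapsed


def write_nonredundant_fasta(collapsed: list[NonRedundantProbe], path: str | Path) -> None:
    """FASTA of unique probe sequences, one entry per NonRedundantProbe."""
    with open(path, "w") as fh:
        for nr in collapsed:
            fh.write(f">{nr.name}\n{nr.sequence}\n")
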