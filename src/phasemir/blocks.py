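"""Clustering of mapped reads into blocks on a precursor.

A block is a stack of overlapping reads summarized by its most abundant
member, the representative. Blocks are built greedily, most abundant seed
first; a member may extend at most ``overhang_tol`` (default 3) nt beyond
the representative on either end, tolerating the imprecise ends RNase III
enzymes leave. Two post-filters follow: junction-straddling ("spanning")
blocks are discarded, and blocks with fewer than ``min_reads`` total reads
(default 5) are dropped as likely sequencing noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .reads import Hit, ReadRecord

__all__ = ["Block", "build_blocks", "drop_spanning", "filter_min_reads", "write_blocks_tsv"]


@dataclass
class Block:
    precursor_id: str
    start: int  # representative span, 1-based inclusive
    end: int
    representative: ReadRecord
    total_count: int
    members: list[Hit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Block") -> bool:
        return self.start <= other.end and other.start <= self.end


def _seed_key(h: Hit) -> tuple:
    # most abundant first; ties: smaller start, shorter read, lexicographic
    return (-h.count, h.start, h.length, h.read.sequence)


def build_blocks(hits: Sequence[Hit], overhang_tol: int = 3) -> list[Block]:
    """Greedy partition of one precursor's hits into blocks.

    Repeatedly seeds a block with the highest-count unassigned hit (the
    representative) and absorbs every unassigned hit lying within the
    representative's span extended by ``overhang_tol`` nt on each side.
    Each hit joins exactly one block. Blocks are returned 5'->3' by start.
    """
    if not hits:
        return []
    pids = {h.precursor_id for h in hits}
    if len(pids) > 1:
        raise ValueError(f"hits span multiple precursors: {sorted(pids)}")

    remaining = sorted(hits, key=_seed_key)
    blocks: list[Block] = []
    while remaining:
        rep = remaining[0]
        members = [
            h
            for h in remaining
            if h.start >= rep.start - overhang_tol and h.end <= rep.end + overhang_tol
        ]
        assigned = set(id(h) for h in members)
        remaining = [h for h in remaining if id(h) not in assigned]
        blocks.append(
            Block(
                precursor_id=rep.precursor_id,
                start=rep.start,
                end=rep.end,
                representative=rep.read,
                total_count=sum(h.count for h in members),
                members=members,
            )
        )
    blocks.sort(key=lambda b: (b.start, b.end))
    return blocks


def drop_spanning(blocks: Sequence[Block]) -> list[Block]:
    """Remove blocks straddling the junction between two neighboring blocks.

    A block is spanning when it overlaps (by >= 1 nt) two distinct other
    blocks that do not overlap each other and that are each at least as
    abundant as it. The abundance condition confines removal to minor
    junction artifacts: without it, any well-expressed block flanked by
    single-read degradation clusters would be discarded. All spanning
    calls are evaluated against the input set, then removed together.
    """
    keep: list[Block] = []
    for b in blocks:
        overl = [
            o
            for o in blocks
            if o is not b and b.overlaps(o) and o.total_count >= b.total_count
        ]
        spanning = any(
            not x.overlaps(y) for i, x in enumerate(overl) for y in overl[i + 1 :]
        )
        if not spanning:
            keep.append(b)
    return keep


def filter_min_reads(blocks: Iterable[Block], min_reads: int = 5) -> list[Block]:
    """Keep blocks with at least ``min_reads`` total reads."""
    return [b for b in blocks if b.total_count >= min_reads]


def write_blocks_tsv(blocks: Iterable[Block], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "precursor_id\tblock_index\tstart\tend\trepresentative_seq\t"
            "total_count\tn_members\n"
        )
        for i, b in enumerate(blocks, start=1):
            fh.write(
                f"{b.precursor_id}\t{i}\t{b.start}\t{b.end}\t"
                f"{b.representative.sequence}\t{b.total_count}\t{len(b.members)}\n"
            )
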