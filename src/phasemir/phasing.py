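"""Phasing, duplex pairing, and hairpin-position classification of blocks.

Successive dicing from a fixed entry point leaves small-RNA 5' ends spaced
at the dicing interval (~21 nt), possibly with one empty slot where a
product was degraded or not sequenced. Duplex partners sit on opposite
arms of the hairpin and, being RNase III products, carry ~2-nt 3'-end
overhangs on both strands. Position classes record whether additional
products lie between the annotated miRNA/miRNA* duplex and the loop (+),
toward the hairpin base (-), or on both sides (+/-).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .blocks import Block
from .precursor import MatureAnnotation, PairTable

__all__ = [
    "Duplex",
    "PhasedGroup",
    "PositionClass",
    "classify_positions",
    "detect_phased_groups",
    "find_duplexes",
    "partner_region",
]


@dataclass
class PhasedGroup:
    precursor_id: str
    phase_len: int
    members: list[Block]  # ordered 5'->3'
    registers: list[int] = field(default_factory=list)  # deviation per member, nt

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Duplex:
    block_5p: Block
    block_3p: Block
    overhang_3p_on_5parm: int  # 3' overhang of the 5'-arm strand
    overhang_3p_on_3parm: int  # 3' overhang of the 3'-arm strand

    @property
    def start(self) -> int:
        """5'-most coordinate of the duplex (used for k-ordering in names)."""
        return min(self.block_5p.start, self.block_3p.start)

    @property
    def total_count(self) -> int:
        return self.block_5p.total_count + self.block_3p.total_count


@dataclass
class PositionClass:
    precursor_id: str
    label: str  # '+', '-', or '+/-'
    per_block: dict[int, str] = field(default_factory=dict)  # block start -> side


def detect_phased_groups(
    blocks: Sequence[Block],
    phase_len: int = 21,
    tol: int = 1,
    max_skip: int = 1,
) -> list[PhasedGroup]:
    """Chain blocks whose 5' starts follow each other at the phase interval.

    Consecutive members' starts must differ by phase_len +/- tol, or — when
    ``max_skip`` >= 1 — by one skipped slot, 2*phase_len +/- 2*tol. Chains
    are grown greedily 5'->3' and maximal; a block belongs to at most one
    group, and singleton chains are discarded. Registers give each member's
    deviation from the ideal register anchored at the chain's first block.
    """
    ordered = sorted(blocks, key=lambda b: (b.start, b.end))
    used: set[int] = set()
    groups: list[PhasedGroup] = []

    def gap_ok(d: int) -> bool:
        if phase_len - tol <= d <= phase_len + tol:
            return True
        if max_skip >= 1 and 2 * phase_len - 2 * tol <= d <= 2 * phase_len + 2 * tol:
            return True
        return False

    for i, seed in enumerate(ordered):
        if i in used:
            continue
        chain = [i]
        while True:
            tail = ordered[chain[-1]]
            nxt = None
            for j in range(chain[-1] + 1, len(ordered)):
                if j in used:
                    continue
                if gap_ok(ordered[j].start - tail.start):
                    nxt = j
                    break
            if nxt is None:
                break
            chain.append(nxt)
        if len(chain) >= 2:
            used.update(chain)
            members = [ordered[j] for j in chain]
            anchor = members[0].start
            registers = []
            for m in members:
                offset = m.start - anchor
                slots = round(offset / phase_len)
                registers.append(offset - slots * phase_len)
            groups.append(
                PhasedGroup(
                    precursor_id=members[0].precursor_id,
                    phase_len=phase_len,
                    members=members,
                    registers=registers,
                )
            )
    return groups


def partner_region(
    block: Block, pair_table: PairTable, min_paired_frac: float = 0.5
) -> tuple[int, int] | None:
    """Interval on the opposite arm paired with this block, or None.

    Returns [min, max] of the partners of the block's paired bases.
    ``None`` when fewer than ``min_paired_frac`` of the block's bases are
    paired — loop-proximal or loop-spanning blocks have no usable partner.
    """
    partners = [
        pair_table[i]
        for i in range(block.start, min(block.end, len(pair_table)) + 1)
        if 1 <= i <= len(pair_table) and pair_table[i] != 0
    ]
    if len(partners) < min_paired_frac * block.length:
        return None
    return min(partners), max(partners)


def _first_paired(block: Block, pair_table: PairTable) -> tuple[int, int] | None:
    """(offset from 5' end, position) of the block's 5'-most paired base."""
    for i in range(block.start, min(block.end, len(pair_table)) + 1):
        if pair_table[i] != 0:
            return i - block.start, i
    return None


def duplex_overhangs(
    a: Block, b: Block, pair_table: PairTable
) -> tuple[int, int] | None:
    """Measure both 3' overhangs for blocks a (5'-arm) and b (3'-arm).

    Each strand's 3' overhang is the number of its 3'-end nucleotides
    extending past the position paired with the partner strand's 5' end.
    Measured on the pair table so bulged stems are handled; when a 5' end
    itself is unpaired the nearest paired base is used and the offset
    added back.
    """
    fb = _first_paired(b, pair_table)
    fa = _first_paired(a, pair_table)
    if fa is None or fb is None:
        return None
    off_b, pos_b = fb
    off_a, pos_a = fa
    # position on a's arm pairing with b's (effective) 5' end
    anchor_a = pair_table[pos_b] + off_b
    anchor_b = pair_table[pos_a] + off_a
    return a.end - anchor_a, b.end - anchor_b


def find_duplexes(
    blocks: Sequence[Block],
    pair_table: PairTable,
    expected_overhang: int = 2,
    tol: int = 1,
    min_mutual_overlap: float = 0.5,
) -> list[Duplex]:
    """Pair blocks across the stem into duplexes with ~2-nt 3' overhangs.

    Every ordered pair of blocks on opposite arms whose spans mutually
    overlap each other's partner region by >= ``min_mutual_overlap`` is
    scored; a pair is a duplex candidate when both 3' overhangs are within
    ``expected_overhang +/- tol``. Each block joins at most one duplex;
    candidates closest to the expected overhang win, ties going to the
    more abundant pairing.
    """
    cands: list[tuple[int, int, Duplex]] = []  # (deviation, -count, duplex)
    n = len(blocks)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = blocks[i], blocks[j]
            if a.start > b.start:
                continue  # a must be the 5'-side block
            pa = partner_region(a, pair_table)
            pb = partner_region(b, pair_table)
            if pa is None or pb is None:
                continue
            if _overlap_len(b.start, b.end, *pa) < min_mutual_overlap * b.length:
                continue
            if _overlap_len(a.start, a.end, *pb) < min_mutual_overlap * a.length:
                continue
            ov = duplex_overhangs(a, b, pair_table)
            if ov is None:
                continue
            o5, o3 = ov
            if abs(o5 - expected_overhang) > tol or abs(o3 - expected_overhang) > tol:
                continue
            dev = abs(o5 - expected_overhang) + abs(o3 - expected_overhang)
            dup = Duplex(a, b, o5, o3)
            cands.append((dev, -(a.total_count + b.total_count), dup))

    cands.sort(key=lambda t: (t[0], t[1], t[2].block_5p.start, t[2].block_3p.start))
    taken: set[int] = set()
    out: list[Duplex] = []
    for _, _, dup in cands:
        k5, k3 = id(dup.block_5p), id(dup.block_3p)
        if k5 in taken or k3 in taken:
            continue
        taken.update((k5, k3))
        out.append(dup)
    out.sort(key=lambda d: d.start)
    return out


def _overlap_len(a1: int, a2: int, b1: int, b2: int) -> int:
    return max(0, min(a2, b2) - max(a1, b1) + 1)


def classify_positions(
    blocks: Sequence[Block],
    matures: Sequence[MatureAnnotation],
    pair_table: PairTable,
) -> PositionClass | None:
    """Label non-annotated blocks loop-side (+) or base-side (-).

    The annotated miRNA/miRNA* duplex splits each arm in two: positions
    between the duplex and the terminal loop are loop-side, positions
    between the duplex and the hairpin base are base-side. The precursor
    label aggregates over its retained non-annotated blocks: '+', '-', or
    '+/-' when both sides occur. Returns ``None`` (with a warning) when no
    annotation is available.
    """
    if not matures or not blocks:
        if not matures:
            warnings.warn("no mature annotation; position classification skipped")
        return None
    pid = blocks[0].precursor_id
    loop = pair_table.loop_region()
    if loop is None:
        loop_mid = len(pair_table) // 2
    else:
        loop_mid = (loop[0] + loop[1]) // 2

    ann_5p = [m for m in matures if (m.start + m.end) / 2 < loop_mid]
    ann_3p = [m for m in matures if (m.start + m.end) / 2 >= loop_mid]
    # inner duplex boundary on each arm; infer the missing arm's boundary
    # through the pair table when only one arm is annotated
    if ann_5p:
        bound_5p = max(m.end for m in ann_5p)
    else:
        pos = min(m.start for m in ann_3p)
        p = _nearest_partner(pos, pair_table)
        bound_5p = p if p is not None else loop_mid
    if ann_3p:
        bound_3p = min(m.start for m in ann_3p)
    else:
        pos = max(m.end for m in ann_5p)
        p = _nearest_partner(pos, pair_table)
        bound_3p = p if p is not None else loop_mid

    ann_spans = [(m.start, m.end) for m in matures]
    per_block: dict[int, str] = {}
    for b in blocks:
        mid = (b.start + b.end) // 2
        if any(_overlap_len(b.start, b.end, s, e) >= 0.5 * b.length for s, e in ann_spans):
            continue  # the annotated miRNA/miRNA* itself
        if mid < loop_mid:
            side = "loop" if mid > bound_5p else "base"
        else:
            side = "loop" if mid < bound_3p else "base"
        per_block[b.start] = side

    sides = set(per_block.values())
    if sides == {"loop"}:
        label = "+"
    elif sides == {"base"}:
        label = "-"
    elif sides:
        label = "+/-"
    else:
        label = ""
    return PositionClass(precursor_id=pid, label=label, per_block=per_block)


def _nearest_partner(pos: int, pair_table: PairTable) -> int | None:
    """Partner of pos, walking outward to the nearest paired base if needed."""
    n = len(pair_table)
    for d in range(0, n):
        for p in (pos - d, pos + d):
            if 1 <= p <= n and pair_table[p] != 0:
                return pair_table[p] + (pos - p)
    return None
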