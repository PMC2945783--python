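from __future__ import annotations

import random

import pytest

from phasemir.blocks import Block
from phasemir.reads import Hit, ReadRecord


def make_hit(start: int, end: int, count: int, pid: str = "pre1", seq: str | None = None) -> Hit:
    if seq is None:
        rng = random.Random(start * 1000003 + end * 1009 + count)
        seq = "".join(rng.choice("ACGU") for _ in range(end - start + 1))
    return Hit(read=ReadRecord(seq, count), precursor_id=pid, start=start, end=end)


def make_block(start: int, end: int, count: int, pid: str = "pre1", seq: str | None = None) -> Block:
    h = make_hit(start, end, count, pid, seq)
    return Block(
        precursor_id=pid,
        start=start,
        end=end,
        representative=h.read,
        total_count=count,
        members=[h],
    )


@pytest.fixture
def perfect_hairpin():
    """A deterministic perfect-stem hairpin with its structure."""
    from phasemir.simulate import SimConfig, make_hairpin

    cfg = SimConfig(seed=11)
    pre, db = make_hairpin(cfg)
    return pre, db, cfg
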