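"""End-to-end orchestration of the discovery and targeting stages.

``run_discover`` takes collapsed reads plus precursors (and optional
structures/annotations) through mapping, block building, the spanning and
minimum-read filters, phasing, duplex calling, position classification and
naming, returning one report bundle. ``run_target`` scans named records
against transcripts and optionally attaches degradome signatures. Both are
deterministic for identical inputs and parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

from .blocks import Block, build_blocks, drop_spanning, filter_min_reads
from .nomenclature import NamedSmallRNA, assign_names, first_nt_fractions, ago_summary
from .phasing import (
    Duplex,
    PhasedGroup,
    PositionClass,
    classify_positions,
    detect_phased_groups,
    find_duplexes,
)
from .precursor import Precursor
from .reads import Hit, ReadRecord, filter_reads, map_exact
from .targeting import (
    ScoringParams,
    TargetHit,
    degradome_signature,
    scan_transcript,
)

logger = logging.getLogger("phasemir")

__all__ = ["PipelineParams", "PrecursorReport", "DiscoveryReport", "run_discover", "run_target"]


@dataclass(frozen=True)
class PipelineParams:
    """Every numeric constant of the pipeline, with its published default."""

    min_read_len: int = 17
    min_block_reads: int = 5
    overhang_tol: int = 3
    phase_len: int = 21
    phase_tol: int = 1
    max_skip: int = 1
    duplex_overhang: int = 2
    duplex_tol: int = 1
    star_fold: float = 5.0
    min_loop: int = 3
    scoring: ScoringParams = field(default_factory=ScoringParams)
    seed: int = 0

    def __post_init__(self):
        for name in (
            "min_read_len",
            "min_block_reads",
            "overhang_tol",
            "phase_len",
            "phase_tol",
            "duplex_overhang",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PrecursorReport:
    precursor_id: str
    hits: list[Hit]
    blocks_raw: list[Block]
    blocks: list[Block]  # after spanning + min-read filters
    phased_groups: list[PhasedGroup]
    duplexes: list[Duplex]
    position_class: PositionClass | None
    named: list[NamedSmallRNA]


@dataclass
class DiscoveryReport:
    params: PipelineParams
    per_precursor: dict[str, PrecursorReport]
    n_reads_in: int
    filter_tally: dict

    @property
    def named(self) -> list[NamedSmallRNA]:
        out = []
        for rep in self.per_precursor.values():
            out.extend(rep.named)
        return out

    def new_records(self) -> list[NamedSmallRNA]:
        """Named records beyond the annotated miRNA/miRNA* (the discoveries)."""
        return [r for r in self.named if not r.is_annotated]

    def summary_stats(self) -> dict:
        new = self.new_records()
        out: dict = {
            "n_new_records": len(new),
            "n_precursors_with_new": len({r.precursor_id for r in new}),
        }
        if new:
            comp = first_nt_fractions(new)
            out["first_nt_fractions"] = comp.fraction_by_first_nt
            out["ago"] = ago_summary(new)
        return out


def run_discover(
    reads: Sequence[ReadRecord],
    precursors: Mapping[str, Precursor],
    params: PipelineParams = PipelineParams(),
    blacklist: Sequence[str] = (),
) -> DiscoveryReport:
    """Run the full discovery pipeline over collapsed reads.

    Precursor annotations travel on the Precursor objects (``matures``);
    structures likewise (falling back to max-pair folding). Empty inputs
    produce an empty report.
    """
    n_in = len(reads)
    kept, tally = filter_reads(reads, min_len=params.min_read_len, blacklist=blacklist)
    if not kept:
        logger.warning("no reads survive filtering; empty report")
    hits = map_exact(kept, precursors)

    by_pre: dict[str, list[Hit]] = {pid: [] for pid in precursors}
    for h in hits:
        by_pre[h.precursor_id].append(h)

    per: dict[str, PrecursorReport] = {}
    for pid, pre in precursors.items():
        phits = by_pre[pid]
        raw = build_blocks(phits, overhang_tol=params.overhang_tol)
        blocks = filter_min_reads(
            drop_spanning(raw), min_reads=params.min_block_reads
        )
        pair_table = pre.pair_table(min_loop=params.min_loop) if blocks else None
        groups = detect_phased_groups(
            blocks,
            phase_len=params.phase_len,
            tol=params.phase_tol,
            max_skip=params.max_skip,
        )
        duplexes = (
            find_duplexes(
                blocks,
                pair_table,
                expected_overhang=params.duplex_overhang,
                tol=params.duplex_tol,
            )
            if pair_table is not None
            else []
        )
        pos = (
            classify_positions(blocks, pre.matures, pair_table)
            if pair_table is not None and pre.matures
            else None
        )
        in_duplex = {id(b) for d in duplexes for b in (d.block_5p, d.block_3p)}
        orphans = [b for b in blocks if id(b) not in in_duplex]
        named = (
            assign_names(
                pid,
                pre.matures,
                duplexes,
                orphans,
                pair_table=pair_table,
                star_fold=params.star_fold,
                position_class=pos,
            )
            if blocks
            else []
        )
        per[pid] = PrecursorReport(
            precursor_id=pid,
            hits=phits,
            blocks_raw=raw,
            blocks=blocks,
            phased_groups=groups,
            duplexes=duplexes,
            position_class=pos,
            named=named,
        )
    return DiscoveryReport(
        params=params, per_precursor=per, n_reads_in=n_in, filter_tally=dict(tally)
    )


def run_target(
    records: Sequence[NamedSmallRNA],
    transcripts: Mapping[str, str],
    degradome: Mapping[str, Mapping[int, int]] | None = None,
    params: PipelineParams = PipelineParams(),
) -> list[TargetHit]:
    """Scan every named record against every transcript.

    Hits are filtered by the scoring cutoff inside ``scan_transcript``;
    when degradome counts are supplied for a transcript, each hit gets its
    cleavage-site count, p-value and support flag. Output is sorted by
    record name, then score, then transcript/position.
    """
    sp = params.scoring
    out: list[TargetHit] = []
    for rec in records:
        for tid, seq in transcripts.items():
            hits = scan_transcript(
                rec.sequence, seq, sp, srna_name=rec.name, transcript_id=tid
            )
            if degradome is not None and tid in degradome:
                hits = [degradome_signature(h, degradome[tid], sp) for h in hits]
            out.extend(hits)
    out.sort(key=lambda h: (h.srna_name, h.score, h.transcript_id, h.site_start))
    return out
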