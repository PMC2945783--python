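"""Naming of small RNAs on a precursor and summary statistics.

Naming follows the miRn.k scheme: the annotated miRNA keeps index 1
(miRn.1, star miRn.1*), and each additional duplex or orphan block gets
the next index in 5'->3' order along the precursor. Within a duplex the
minor strand is the star when the abundance ratio reaches ``star_fold``;
comparable abundances get -5p/-3p suffixes by arm instead.

The module also computes the catalog-level statistics used to
characterize these RNAs — first-nucleotide composition, Argonaute (AGO)
association, abundance ratios — and ships a packaged catalog of the 19
Arabidopsis precursors with 35 miRNA-like RNAs on which those statistics
were first reported.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .blocks import Block
from .phasing import Duplex, PositionClass
from .precursor import MatureAnnotation, PairTable, normalize_rna

__all__ = [
    "CompositionSummary",
    "NamedSmallRNA",
    "ago_summary",
    "assign_names",
    "catalog_stats",
    "first_nt_fractions",
    "fold_change",
    "load_catalog",
]


@dataclass
class NamedSmallRNA:
    name: str
    precursor_id: str
    sequence: str
    start: int
    end: int
    total_count: int
    is_annotated: bool = False
    arm: str | None = None  # "5p" | "3p"
    side: str | None = None  # "loop" | "base"
    ago_set: frozenset[int] = field(default_factory=frozenset)
    pare_targets: tuple[str, ...] = ()


@dataclass
class CompositionSummary:
    fraction_by_first_nt: dict[str, float]
    n_records: int


def _arm_of(block: Block, pair_table: PairTable | None) -> str:
    if pair_table is None:
        return "5p"
    loop = pair_table.loop_region()
    mid = (loop[0] + loop[1]) // 2 if loop else len(pair_table) // 2
    return "5p" if (block.start + block.end) // 2 < mid else "3p"


def assign_names(
    precursor_id: str,
    matures: list[MatureAnnotation],
    duplexes: list[Duplex],
    orphan_blocks: list[Block],
    pair_table: PairTable | None = None,
    star_fold: float = 5.0,
    position_class: PositionClass | None = None,
    block_counts: dict[int, tuple[str, int]] | None = None,
) -> list[NamedSmallRNA]:
    """Assign miRn.k names to the retained duplexes and orphan blocks.

    ``matures`` identify the annotated miRNA/miRNA* whose blocks take the
    reserved .1 index (a duplex overlapping an annotated span is the .1
    duplex even if discovered de novo). New duplexes and orphans share a
    single 5'->3' ordering by their 5'-most coordinate; each entity gets
    the next k. Within a duplex, a ``star_fold``-or-greater count ratio
    makes the minor strand the star (miRn.k*); otherwise both strands are
    named by arm (miRn.k-5p / miRn.k-3p). When no annotation exists, the
    most 5' duplex is taken as .1 with a warning.
    """
    base = _name_stem(precursor_id)

    def annotated_span_for(block: Block) -> MatureAnnotation | None:
        for m in matures:
            ov = min(block.end, m.end) - max(block.start, m.start) + 1
            if ov >= 0.5 * (m.end - m.start + 1):
                return m
        return None

    entities: list[tuple[int, str, object]] = []  # (5'-most start, kind, payload)
    for d in duplexes:
        entities.append((d.start, "duplex", d))
    for b in orphan_blocks:
        entities.append((b.start, "orphan", b))
    entities.sort(key=lambda t: t[0])

    # split annotated from new entities
    annotated_entities = []
    new_entities = []
    for ent in entities:
        _, kind, payload = ent
        blocks = (
            [payload.block_5p, payload.block_3p] if kind == "duplex" else [payload]
        )
        if any(annotated_span_for(b) is not None for b in blocks):
            annotated_entities.append(ent)
        else:
            new_entities.append(ent)

    if not annotated_entities and new_entities:
        if matures:
            warnings.warn(
                f"{precursor_id}: no retained block matches an annotation; "
                "promoting the most 5' duplex to .1"
            )
        else:
            warnings.warn(f"{precursor_id}: no annotation; most 5' entity becomes .1")
        annotated_entities = [new_entities.pop(0)]

    records: list[NamedSmallRNA] = []

    def emit(block: Block, name: str, annotated: bool) -> None:
        side = None
        if position_class is not None:
            side = position_class.per_block.get(block.start)
        records.append(
            NamedSmallRNA(
                name=name,
                precursor_id=precursor_id,
                sequence=block.representative.sequence,
                start=block.start,
                end=block.end,
                total_count=block.total_count,
                is_annotated=annotated,
                arm=_arm_of(block, pair_table),
                side=side,
            )
        )

    def name_entity(ent, k: int, annotated: bool) -> None:
        _, kind, payload = ent
        if kind == "orphan":
            emit(payload, f"{base}.{k}", annotated)
            return
        d: Duplex = payload
        b5, b3 = d.block_5p, d.block_3p
        major, minor = (b5, b3) if b5.total_count >= b3.total_count else (b3, b5)
        if annotated:
            # respect the annotation's own miRNA/miRNA* roles when they map
            roles = {id(b): annotated_span_for(b) for b in (b5, b3)}
            guide = next(
                (b for b in (b5, b3) if roles[id(b)] and roles[id(b)].role == "miRNA"),
                major,
            )
            star = b3 if guide is b5 else b5
            emit(guide, f"{base}.{k}", True)
            emit(star, f"{base}.{k}*", True)
            return
        if minor.total_count == 0 or major.total_count / max(minor.total_count, 1) >= star_fold:
            emit(major, f"{base}.{k}", False)
            emit(minor, f"{base}.{k}*", False)
        else:
            emit(b5, f"{base}.{k}-5p", False)
            emit(b3, f"{base}.{k}-3p", False)

    for ent in annotated_entities:
        name_entity(ent, 1, True)
    for k, ent in enumerate(new_entities, start=2):
        name_entity(ent, k, False)

    records.sort(key=lambda r: (r.start, r.end))
    return records


def _name_stem(precursor_id: str) -> str:
    """miR-style stem from a precursor id (ath-MIR159a -> miR159a)."""
    m = re.search(r"(?:mir|MIR|miR)[-]?([0-9]+[a-z]*)", precursor_id)
    if m:
        return f"miR{m.group(1)}"
    return precursor_id


def first_nt_fractions(sequences_or_records) -> CompositionSummary:
    """Fraction of records starting with each nucleotide (A/C/G/U).

    Computed over all records as given — entries sharing a sequence are
    each counted. Raises on empty input.
    """
    seqs = [
        r.sequence if isinstance(r, NamedSmallRNA) else str(r)
        for r in sequences_or_records
    ]
    if not seqs:
        raise ValueError("no records to summarize")
    n = len(seqs)
    frac = {nt: 0.0 for nt in "ACGU"}
    for s in seqs:
        first = normalize_rna(s)[0]
        if first in frac:
            frac[first] += 1.0
    for nt in frac:
        frac[nt] /= n
    return CompositionSummary(fraction_by_first_nt=frac, n_records=n)


def ago_summary(records: list[NamedSmallRNA]) -> dict:
    """AGO-association summary over named records.

    A record is associated when its ago_set is non-empty. Returns per-AGO
    record counts, the overall associated count and fraction, and the
    number of distinct precursors with at least one associated record.
    """
    per_ago: dict[int, int] = {}
    associated = 0
    precursors_assoc: set[str] = set()
    for r in records:
        if r.ago_set:
            associated += 1
            precursors_assoc.add(r.precursor_id)
        for a in r.ago_set:
            per_ago[a] = per_ago.get(a, 0) + 1
    return {
        "per_ago": dict(sorted(per_ago.items())),
        "associated": associated,
        "associated_fraction": associated / len(records) if records else 0.0,
        "precursors_associated": len(precursors_assoc),
    }


def fold_change(count_a: float, count_b: float) -> float:
    """Abundance ratio count_a / count_b (count_b must be positive)."""
    if count_b <= 0:
        raise ValueError("denominator count must be positive")
    return count_a / count_b


# ---------------------------------------------------------------------------
# Packaged catalog


def load_catalog() -> pd.DataFrame:
    """Load the packaged Arabidopsis miRNA-like RNA catalog.

    Columns: precursor, loci_class, name, is_new, sequence, reads,
    ago_list, pare_targets. ``is_new`` distinguishes the 35 newly
    identified miRNA-like RNAs from the annotated miRNA/miRNA* context
    rows.
    """
    ref = resources.files("phasemir").joinpath("data/mirna_like_catalog.tsv")
    with ref.open() as fh:
        df = pd.read_csv(
            fh,
            sep="\t",
            comment="#",
            dtype={"reads": int, "is_new": int},
            keep_default_na=False,
        )
    # rows omit trailing empty columns; normalize to empty strings
    return df.fillna("")


def _catalog_records(df: pd.DataFrame) -> list[NamedSmallRNA]:
    recs = []
    for _, row in df.iterrows():
        ago = frozenset(
            int(x) for x in str(row.get("ago_list", "")).split(",") if x.strip().isdigit()
        )
        pare = tuple(
            x.strip() for x in str(row.get("pare_targets", "")).split(",") if x.strip()
        )
        recs.append(
            NamedSmallRNA(
                name=row["name"],
                precursor_id=row["precursor"],
                sequence=normalize_rna(row["sequence"]),
                start=0,
                end=0,
                total_count=int(row["reads"]),
                is_annotated=not bool(row["is_new"]),
                ago_set=ago,
                pare_targets=pare,
            )
        )
    return recs


def catalog_stats(df: pd.DataFrame | None = None, total_annotated_precursors: int = 207) -> dict:
    """Summary statistics over the packaged catalog's new records.

    ``total_annotated_precursors`` is the size of the annotated miRNA
    precursor complement against which the discovery fraction is quoted
    (207 Arabidopsis precursors in the miRBase release the catalog was
    built on).
    """
    if df is None:
        df = load_catalog()
    new = df[df["is_new"] == 1]
    records = _catalog_records(new)

    def family(pre: str) -> str:
        m = re.search(r"([0-9]+)", pre)
        return m.group(1) if m else pre

    comp = first_nt_fractions(records)
    ago = ago_summary(records)
    n_precursors = new["precursor"].nunique()
    ratio_319b = fold_change(
        int(df.loc[df["name"] == "miR319b.2", "reads"].iloc[0]),
        int(df.loc[df["name"] == "miR319b.1", "reads"].iloc[0]),
    )
    mir822_gt5 = int(((new["precursor"] == "miR822") & (new["reads"] > 5)).sum())
    loci = df.groupby("precursor")["loci_class"].first()
    return {
        "n_mirna_like": len(records),
        "n_precursors": n_precursors,
        "n_families": new["precursor"].map(family).nunique(),
        "precursor_fraction_pct": 100.0 * n_precursors / total_annotated_precursors,
        "first_nt_pct": {
            nt: 100.0 * f for nt, f in comp.fraction_by_first_nt.items()
        },
        "ago_associated": ago["associated"],
        "ago_associated_pct": 100.0 * ago["associated_fraction"],
        "ago_precursors": ago["precursors_associated"],
        "per_ago": ago["per_ago"],
        "mir822_new_gt5_reads": mir822_gt5,
        "loci_plus": int((loci == "+").sum()),
        "loci_minus": int((loci == "-").sum()),
        "loci_both": int((loci == "+/-").sum()),
        "mir319b2_over_mir319b1": ratio_319b,
    }
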