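"""Small-RNA read processing: adapter trimming, collapsing, filtering, mapping.

Reads are collapsed to unique sequences with multiplicities, filtered by a
minimum length and against a structural-RNA blacklist (tRNA/rRNA/snRNA/
snoRNA), and mapped to precursor hairpins requiring zero mismatches on the
sense strand. Multi-locus reads are retained at every locus with the locus
count recorded so downstream reports can flag them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .precursor import Precursor, normalize_rna, revcomp_rna

__all__ = [
    "Hit",
    "ReadRecord",
    "collapse",
    "filter_reads",
    "map_exact",
    "read_small_rna_file",
    "trim_3p_adapter",
    "write_collapsed_fasta",
    "write_hits_tsv",
]


@dataclass(frozen=True)
class ReadRecord:
    """A unique small-RNA sequence and its read multiplicity."""

    sequence: str
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Hit:
    """A zero-mismatch occurrence of a read on a precursor (1-based span)."""

    read: ReadRecord
    precursor_id: str
    start: int
    end: int
    n_loci: int = 1

    @property
    def count(self) -> int:
        return self.read.count

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def trim_3p_adapter(
    sequence: str, adapter: str, min_overlap: int = 6
) -> tuple[str, bool]:
    """Remove a 3' sequencing adapter from a read.

    Trims from the leftmost position where either the full adapter occurs,
    or a prefix of the adapter (>= ``min_overlap`` nt) runs through the
    read's 3' end. Returns ``(trimmed, True)`` on a match and
    ``(sequence, False)`` when no adapter is found (the read may be an
    adapter-free insert and is kept by callers).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = normalize_rna(sequence)
    ad = normalize_rna(adapter)

    full = seq.find(ad)
    # candidate suffix matches: adapter prefix occupying the read's 3' end
    suffix_cut = None
    max_ov = min(len(ad), len(seq))
    for ov in range(max_ov, min_overlap - 1, -1):
        if seq.endswith(ad[:ov]) is False:
            continue
        cut = len(seq) - ov
        if suffix_cut is None or cut < suffix_cut:
            suffix_cut = cut
    candidates = [c for c in (full if full >= 0 else None, suffix_cut) if c is not None]
    if not candidates:
        return seq, False
    return seq[: min(candidates)], True


def collapse(sequences: Iterable[str]) -> list[ReadRecord]:
    """Collapse raw sequences into unique records with counts.

    The sum of counts equals the number of input sequences; output is
    ordered by descending count then sequence for determinism.
    """
    tally = Counter(normalize_rna(s) for s in sequences)
    return [
        ReadRecord(seq, n)
        for seq, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def filter_reads(
    records: Iterable[ReadRecord],
    min_len: int = 17,
    blacklist: Iterable[str] = (),
) -> tuple[list[ReadRecord], Counter]:
    """Apply the minimum-length and blacklist filters.

    A record is rejected when shorter than ``min_len`` nt or when its
    sequence is an exact substring of any blacklist entry on either strand
    (blacklist entries are structural RNAs; reverse complements are checked
    so antisense fragments are also excluded). Returns the kept records and
    a tally with keys ``kept``, ``too_short``, ``blacklisted``.
    """
    bl_seqs: list[str] = []
    for b in blacklist:
        fwd = normalize_rna(b)
        bl_seqs.append(fwd)
        bl_seqs.append(revcomp_rna(fwd))

    kept: list[ReadRecord] = []
    tally: Counter = Counter()
    for rec in records:
        if len(rec.sequence) < min_len:
            tally["too_short"] += 1
            continue
        if any(rec.sequence in b for b in bl_seqs):
            tally["blacklisted"] += 1
            continue
        tally["kept"] += 1
        kept.append(rec)
    return kept, tally


def map_exact(
    records: Iterable[ReadRecord], precursors: Mapping[str, Precursor]
) -> list[Hit]:
    """Map reads to precursors with zero mismatches, sense strand only.

    Every occurrence of every read on every precursor is reported;
    ``n_loci`` on each hit is the total occurrence count of that read
    across all precursors. Reads without any occurrence are dropped.
    """
    hits: list[Hit] = []
    per_read: Counter = Counter()
    for rec in records:
        seq = rec.sequence
        found: list[tuple[str, int]] = []
        for pid, pre in precursors.items():
            pos = pre.sequence.find(seq)
            while pos >= 0:
                found.append((pid, pos + 1))
                pos = pre.sequence.find(seq, pos + 1)
        per_read[seq] = len(found)
        for pid, start in found:
            hits.append(
                Hit(
                    read=rec,
                    precursor_id=pid,
                    start=start,
                    end=start + len(seq) - 1,
                    n_loci=len(found),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# I/O


def read_small_rna_file(path: str | Path) -> list[ReadRecord]:
    """Read FASTA/FASTQ small-RNA input into collapsed records.

    FASTQ is detected from the .fastq/.fq extension. The collapsed-FASTA
    dialect encodes multiplicity in the header as ``>name_xCOUNT``; plain
    headers count as one read each, and identical sequences are merged.
    """
    p = Path(path)
    fmt = "fastq" if p.suffix.lower() in (".fastq", ".fq") else "fasta"
    tally: Counter = Counter()
    for rec in SeqIO.parse(str(p), fmt):
        count = 1
        if fmt == "fasta" and "_x" in rec.id:
            tail = rec.id.rsplit("_x", 1)[1]
            if tail.isdigit():
                count = int(tail)
        tally[normalize_rna(str(rec.seq))] += count
    return [
        ReadRecord(seq, n)
        for seq, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def write_collapsed_fasta(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(records, start=1):
            fh.write(f">read{i}_x{rec.count}\n{rec.sequence}\n")


def write_hits_tsv(hits: Iterable[Hit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_seq\tcount\tprecursor_id\tstart\tend\tn_loci\n")
        for h in hits:
            fh.write(
                f"{h.read.sequence}\t{h.count}\t{h.precursor_id}\t"
                f"{h.start}\t{h.end}\t{h.n_loci}\n"
            )
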