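"""Target complementarity scoring and degradome cleavage signatures.

Plant small RNAs guide cleavage of near-complementary mRNA sites. A site
is scored with an additive penalty scheme: each mismatch costs 1, each
G:U wobble 0.5, and penalties are doubled in the seed region (positions
2-7 from the small RNA's 5' end). Lower scores mean better
complementarity; sites at or below the score cutoff (default 4.5) are
reported. Degradome (PARE) libraries sequence uncapped mRNA 5' ends;
a read pileup at the position opposite small-RNA positions 10-11 is the
signature of guided cleavage, quantified here by a rank-based empirical
p-value over the transcript's nonzero degradome positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .precursor import normalize_rna

__all__ = [
    "ScoringParams",
    "TargetHit",
    "complementarity_score",
    "degradome_signature",
    "map_degradome_tags",
    "pair_class",
    "read_degradome_tsv",
    "scan_transcript",
    "write_target_hits_tsv",
]

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}  # sRNA letter first


@dataclass(frozen=True)
class ScoringParams:
    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5
    seed_start: int = 2  # 1-based sRNA positions, inclusive
    seed_end: int = 7
    seed_multiplier: float = 2.0
    score_cutoff: float = 4.5
    pvalue_cutoff: float = 0.2
    cleavage_srna_pos: int = 10  # slicing occurs opposite sRNA positions 10-11

    def __post_init__(self):
        if self.mismatch_penalty < 0 or self.wobble_penalty < 0:
            raise ValueError("penalties must be non-negative")
        if self.seed_start > self.seed_end or self.seed_start < 1:
            raise ValueError("bad seed range")


@dataclass
class TargetHit:
    srna_name: str
    transcript_id: str
    site_start: int  # 1-based inclusive on the transcript
    site_end: int
    score: float
    cleavage_pos: int
    degradome_count: int | None = None
    p_value: float | None = None
    supported: bool = False


def pair_class(srna_nt: str, target_nt: str) -> str:
    """Classify an antiparallel base opposition: match, wobble, or mismatch.

    Ambiguity codes and anything outside ACGU count as mismatches.
    """
    pair = (srna_nt.upper().replace("T", "U"), target_nt.upper().replace("T", "U"))
    if pair in _WC:
        return "match"
    if pair in _WOBBLE:
        return "wobble"
    return "mismatch"


def complementarity_score(
    srna: str, target_site: str, params: ScoringParams = ScoringParams()
) -> float:
    """Penalty score of an ungapped sRNA:site alignment (lower is better).

    Both sequences are given 5'->3'; the comparison is antiparallel, so
    sRNA position i faces site position L-i+1. Penalties follow
    ``params``, doubled (seed_multiplier) within the seed region.
    """
    s = normalize_rna(srna)
    t = normalize_rna(target_site)
    if len(s) != len(t):
        raise ValueError(f"length mismatch: sRNA {len(s)} vs site {len(t)}")
    L = len(s)
    score = 0.0
    for i in range(1, L + 1):
        cls = pair_class(s[i - 1], t[L - i])
        if cls == "match":
            continue
        pen = params.mismatch_penalty if cls == "mismatch" else params.wobble_penalty
        if params.seed_start <= i <= params.seed_end:
            pen *= params.seed_multiplier
        score += pen
    return score


def scan_transcript(
    srna: str,
    transcript: str,
    params: ScoringParams = ScoringParams(),
    srna_name: str = "sRNA",
    transcript_id: str = "transcript",
) -> list[TargetHit]:
    """Score every ungapped window of the transcript against the sRNA.

    Windows scoring at or below ``params.score_cutoff`` are returned,
    sorted by ascending score then position. The predicted cleavage
    position is the transcript nucleotide facing sRNA position
    ``params.cleavage_srna_pos`` (canonical slicing between positions
    10 and 11).
    """
    s = normalize_rna(srna)
    t = normalize_rna(transcript)
    L = len(s)
    if len(t) < L:
        return []
    hits: list[TargetHit] = []
    for w in range(1, len(t) - L + 2):  # 1-based window start
        site = t[w - 1 : w - 1 + L]
        score = complementarity_score(s, site, params)
        if score <= params.score_cutoff:
            hits.append(
                TargetHit(
                    srna_name=srna_name,
                    transcript_id=transcript_id,
                    site_start=w,
                    site_end=w + L - 1,
                    score=score,
                    cleavage_pos=w + L - params.cleavage_srna_pos,
                )
            )
    hits.sort(key=lambda h: (h.score, h.site_start))
    return hits


def degradome_signature(
    hit: TargetHit,
    counts: Mapping[int, int] | Sequence[int],
    params: ScoringParams = ScoringParams(),
) -> TargetHit:
    """Attach the degradome 5'-end count and rank p-value to a hit.

    ``counts`` maps transcript position (1-based) to the number of
    degradome 5' ends there (a sequence is taken as counts for positions
    1..n). The p-value is the fraction of nonzero-count positions whose
    count is >= the count at the cleavage site; with no signal at the
    site (or an all-zero vector) it is 1.0. The hit is flagged supported
    when score <= score_cutoff and p <= pvalue_cutoff.
    """
    if isinstance(counts, Mapping):
        cmap = {int(k): int(v) for k, v in counts.items() if int(v) != 0}
    else:
        cmap = {i + 1: int(c) for i, c in enumerate(counts) if int(c) != 0}
    at_site = cmap.get(hit.cleavage_pos, 0)
    if at_site == 0 or not cmap:
        p = 1.0
    else:
        ge = sum(1 for c in cmap.values() if c >= at_site)
        p = ge / len(cmap)
    hit.degradome_count = at_site
    hit.p_value = p
    hit.supported = hit.score <= params.score_cutoff and p <= params.pvalue_cutoff
    return hit


# ---------------------------------------------------------------------------
# Degradome I/O


def read_degradome_tsv(path: str | Path) -> dict[str, dict[int, int]]:
    """Read (transcript_id, position, count) rows into nested mappings."""
    out: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("transcript_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            tid, pos, cnt = parts[0], int(parts[1]), int(parts[2])
            out.setdefault(tid, {})[pos] = out.setdefault(tid, {}).get(pos, 0) + cnt
    return out


def map_degradome_tags(
    tags: Iterable[str], transcripts: Mapping[str, str]
) -> dict[str, dict[int, int]]:
    """Build per-position 5'-end counts by exact-matching degradome tags.

    Each tag's 5' end is counted at every exact occurrence start on every
    transcript (sense strand: degradome tags read into the mRNA).
    """
    norm = {tid: normalize_rna(seq) for tid, seq in transcripts.items()}
    out: dict[str, dict[int, int]] = {}
    for tag in tags:
        t = normalize_rna(tag)
        for tid, seq in norm.items():
            pos = seq.find(t)
            while pos >= 0:
                d = out.setdefault(tid, {})
                d[pos + 1] = d.get(pos + 1, 0) + 1
                pos = seq.find(t, pos + 1)
    return out


def write_target_hits_tsv(hits: Iterable[TargetHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "srna_name\ttranscript_id\tsite_start\tsite_end\tscore\t"
            "cleavage_pos\tdegradome_count\tp_value\tsupported\n"
        )
        for h in hits:
            dc = "" if h.degradome_count is None else h.degradome_count
            pv = "" if h.p_value is None else f"{h.p_value:.4g}"
            fh.write(
                f"{h.srna_name}\t{h.transcript_id}\t{h.site_start}\t{h.site_end}\t"
                f"{h.score:g}\t{h.cleavage_pos}\t{dc}\t{pv}\t{int(h.supported)}\n"
            )
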