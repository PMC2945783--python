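"""Precursor hairpins: sequences, secondary structure, and mature annotations.

A miRNA precursor is a single-stranded transcript that folds back on itself
into a stem-loop. All coordinates on a precursor are 1-based and inclusive,
matching the way hairpin positions are labelled in figures and reports.
Structure may be supplied as a dot-bracket string (e.g. from an RNAfold run
or a database annotation); when none is available, :func:`fold_maxpair`
provides a deterministic maximum-base-pairing fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "MalformedStructureError",
    "MatureAnnotation",
    "PairTable",
    "Precursor",
    "fold_maxpair",
    "load_annotations",
    "normalize_rna",
    "parse_dotbracket",
    "read_precursor_fasta",
    "read_vienna",
    "revcomp_rna",
]

#: canonical pairs used by the max-pair folder: Watson-Crick plus G:U wobble
_PAIRABLE = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class MalformedStructureError(ValueError):
    """Raised for unbalanced or illegal dot-bracket strings."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


_RC = str.maketrans("ACGU", "UGCA")


def revcomp_rna(seq: str) -> str:
    """Reverse complement of a U-normalized RNA string."""
    return normalize_rna(seq).translate(_RC)[::-1]


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and spell thymine as uracil.

    DNA-alphabet input (as in most read files and miRBase-derived tables)
    and RNA-alphabet input compare equal after normalization, so exact
    matching is invariant to T/U spelling on either side.
    """
    return seq.strip().upper().replace("T", "U")


class PairTable:
    """Base-pairing partners of a nested secondary structure, 1-based.

    ``partner[i]`` is the partner of position ``i`` or 0 when unpaired.
    The table is symmetric (``partner[partner[i]] == i``) and nested
    (pseudoknot-free) by construction.
    """

    def __init__(self, partner: Sequence[int]):
        # partner[0] is a placeholder so the table indexes 1..n directly
        self._partner = list(partner)
        n = len(self._partner) - 1
        for i in range(1, n + 1):
            j = self._partner[i]
            if j:
                if j == i:
                    raise MalformedStructureError(f"position {i} pairs with itself", i)
                if not (1 <= j <= n) or self._partner[j] != i:
                    raise MalformedStructureError(f"asymmetric pair at {i}", i)

    def __len__(self) -> int:
        return len(self._partner) - 1

    def __getitem__(self, i: int) -> int:
        if not 1 <= i <= len(self):
            raise IndexError(f"position {i} outside 1..{len(self)}")
        return self._partner[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PairTable) and self._partner == other._partner

    def pairs(self) -> list[tuple[int, int]]:
        """All (i, j) pairs with i < j, ascending in i."""
        return [
            (i, self._partner[i])
            for i in range(1, len(self) + 1)
            if self._partner[i] > i
        ]

    def n_pairs(self) -> int:
        return len(self.pairs())

    def render(self) -> str:
        """Dot-bracket string; inverse of :func:`parse_dotbracket`."""
        out = ["."] * len(self)
        for i, j in self.pairs():
            out[i - 1] = "("
            out[j - 1] = ")"
        return "".join(out)

    def loop_region(self) -> tuple[int, int] | None:
        """The terminal loop of the (innermost) hairpin as a 1-based interval.

        Returns the interval enclosed by the innermost base pair, i.e. the
        pair (i, j) with no other pair nested inside it; when several
        hairpin loops exist the 5'-most is returned. ``None`` for a fully
        unpaired structure.
        """
        best: tuple[int, int] | None = None
        for i, j in self.pairs():
            if all(self._partner[k] == 0 for k in range(i + 1, j)):
                if best is None or i < best[0]:
                    best = (i + 1, j - 1)
        return best


@dataclass(frozen=True)
class MatureAnnotation:
    """An annotated mature small RNA span on a precursor."""

    name: str
    start: int  # 1-based inclusive
    end: int
    role: str  # "miRNA" or "miRNA*"

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad span {self.start}..{self.end} for {self.name}")
        if self.role not in ("miRNA", "miRNA*"):
            raise ValueError(f"role must be miRNA or miRNA*, got {self.role!r}")


@dataclass
class Precursor:
    """A miRNA precursor hairpin with optional structure and annotations."""

    id: str
    sequence: str
    structure: str | None = None
    matures: list[MatureAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = normalize_rna(self.sequence)
        if not self.sequence:
            raise ValueError(f"precursor {self.id} has empty sequence")
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise ValueError(
                f"precursor {self.id}: structure length {len(self.structure)} "
                f"!= sequence length {len(self.sequence)}"
            )
        for m in self.matures:
            if m.end > len(self.sequence):
                raise ValueError(
                    f"annotation {m.name} ({m.start}..{m.end}) exceeds "
                    f"precursor {self.id} length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive [start, end]."""
        return self.sequence[start - 1 : end]

    def pair_table(self, min_loop: int = 3) -> PairTable:
        """Pair table from the supplied structure, folding as a fallback."""
        db = self.structure
        if db is None:
            db = fold_maxpair(self.sequence, min_loop=min_loop)
        return parse_dotbracket(db)


def parse_dotbracket(db: str) -> PairTable:
    """Parse a dot-bracket string into a :class:`PairTable`.

    Raises :class:`MalformedStructureError` (with the offending 1-based
    position) on unbalanced parentheses or illegal characters.
    """
    partner = [0] * (len(db) + 1)
    stack: list[int] = []
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise MalformedStructureError(f"unmatched ')' at position {pos}", pos)
            i = stack.pop()
            partner[i], partner[pos] = pos, i
        elif ch != ".":
            raise MalformedStructureError(
                f"illegal character {ch!r} at position {pos}", pos
            )
    if stack:
        raise MalformedStructureError(
            f"unmatched '(' at position {stack[-1]}", stack[-1]
        )
    return PairTable(partner)


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


def fold_maxpair(sequence: str, min_loop: int = 3) -> str:
    """Fold a sequence by maximizing base pairs (Watson-Crick plus G:U).

    Dynamic program over intervals: an optimal nested structure either
    leaves the 5'-most position of the interval unpaired or pairs it with
    some admissible partner. Hairpin loops keep at least ``min_loop``
    unpaired positions. The traceback is deterministic: the 5'-most
    position is paired whenever pairing it attains the optimum, and among
    optimal partners the 3'-most is chosen.

    Not a thermodynamic model — this is a structural fallback for when no
    curated fold is supplied, sufficient to locate the stem and loop.
    """
    s = normalize_rna(sequence)
    n = len(s)
    if n < 2 + min_loop:
        raise ValueError(f"sequence of length {n} too short to fold (min_loop={min_loop})")

    # best[i][j] = max pairs on s[i..j], 0-based inclusive
    best = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            m = best[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(s[i], s[k]):
                    inner = best[i + 1][k - 1] if k - 1 > i + 1 else 0
                    right = best[k + 1][j] if k + 1 < j else 0
                    m = max(m, 1 + inner + right)
            best[i][j] = m

    partner = [0] * (n + 1)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < min_loop + 1:
            continue
        target = best[i][j]
        if target == 0:
            continue
        # prefer pairing the 5'-most position; among partners take the 3'-most
        chosen = -1
        for k in range(j, i + min_loop, -1):
            if _can_pair(s[i], s[k]):
                inner = best[i + 1][k - 1] if k - 1 > i + 1 else 0
                right = best[k + 1][j] if k + 1 < j else 0
                if 1 + inner + right == target:
                    chosen = k
                    break
        if chosen >= 0:
            partner[i + 1], partner[chosen + 1] = chosen + 1, i + 1
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))
    return PairTable(partner).render()


def load_annotations(
    rows: Iterable[Mapping[str, object] | Sequence[object]],
    precursors: Mapping[str, Precursor],
) -> dict[str, list[MatureAnnotation]]:
    """Attach mature miRNA/miRNA* annotations to precursors.

    Accepts mappings with keys (precursor_id, name, start, end, role) or
    plain 5-tuples in that order. Spans are validated against precursor
    length; annotations are also appended onto the precursor objects.
    """
    out: dict[str, list[MatureAnnotation]] = {pid: [] for pid in precursors}
    for idx, row in enumerate(rows, start=1):
        if isinstance(row, Mapping):
            pid = str(row["precursor_id"])
            name, start, end, role = (
                str(row["name"]),
                int(row["start"]),
                int(row["end"]),
                str(row["role"]),
            )
        else:
            pid, name, start, end, role = (
                str(row[0]),
                str(row[1]),
                int(row[2]),
                int(row[3]),
                str(row[4]),
            )
        if pid not in precursors:
            raise ValueError(f"annotation row {idx}: unknown precursor {pid!r}")
        pre = precursors[pid]
        if not 1 <= start <= end <= len(pre):
            raise ValueError(
                f"annotation row {idx}: span {start}..{end} for {name!r} outside "
                f"precursor {pid} (length {len(pre)})"
            )
        ann = MatureAnnotation(name=name, start=start, end=end, role=role)
        out[pid].append(ann)
        pre.matures.append(ann)
    return out


def load_annotation_table(
    path: str | Path, precursors: Mapping[str, Precursor]
) -> dict[str, list[MatureAnnotation]]:
    """Load a TSV with columns precursor_id, name, start, end, role."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "precursor_id":  # header
                continue
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            rows.append(tuple(parts[:5]))
    return load_annotations(rows, precursors)


def read_precursor_fasta(path: str | Path) -> dict[str, Precursor]:
    """Load precursors from FASTA, keyed and ordered by record id."""
    out: dict[str, Precursor] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = Precursor(id=rec.id, sequence=str(rec.seq))
    return out


def read_vienna(path: str | Path) -> dict[str, str]:
    """Read a Vienna-style file (>id / sequence / structure) to id->dot-bracket."""
    out: dict[str, str] = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected header at line {i + 1}")
        name = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated record {name}")
        structure = lines[i + 2].split()[0]  # strip any trailing energy
        out[name] = structure
        i += 3
    return out
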