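"""Synthetic hairpins, sequential-dicing products, and read libraries.

The generator emulates what a Dicer-like enzyme does to a long perfect
stem: starting from a fixed entry point it releases successive ~21-nt
duplexes, each with a 2-nt 3' overhang on both strands, walking one phase
interval at a time. Libraries sampled from those products carry the
hallmarks of real small-RNA data the pipeline must tolerate: strongly
skewed per-product abundances (log-normal), occasional 1-2-nt end jitter
from imprecise dicing, and background degradation fragments that map to
the precursor. Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .precursor import Precursor, revcomp_rna

__all__ = [
    "SimConfig",
    "SimProduct",
    "SimTruth",
    "make_hairpin",
    "sample_reads",
    "simulate_degradome",
    "simulate_dicing",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the dicing simulation.

    The defaults describe a long-stemmed precursor processed into three
    phased duplexes, sequenced to a depth of 2000 reads with mild end
    jitter and a 5% background of degradation fragments — the regime the
    discovery pipeline is expected to handle.
    """

    arm_len: int = 70
    loop_len: int = 8
    n_duplexes: int = 3
    product_len: int = 21
    phase_len: int = 21
    overhang: int = 2
    depth: int = 2000
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    end_jitter_prob: float = 0.1
    jitter_max: int = 2
    background_rate: float = 0.05
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.arm_len < self.n_duplexes * self.phase_len:
            raise ValueError(
                f"arm_len {self.arm_len} too short for {self.n_duplexes} duplexes "
                f"at phase {self.phase_len}"
            )
        for p in (self.end_jitter_prob, self.background_rate, self.gc_content):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SimProduct:
    arm: str  # "5p" | "3p"
    start: int  # 1-based inclusive on the precursor
    end: int
    sequence: str
    duplex_index: int


@dataclass
class SimTruth:
    precursor: Precursor
    structure: str
    products: list[SimProduct]
    abundances: list[float]  # parallel to products
    config: SimConfig = field(default=SimConfig())


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, salt]))


def make_hairpin(config: SimConfig, pid: str = "sim-pre") -> tuple[Precursor, str]:
    """Generate a perfect-stem hairpin precursor and its dot-bracket.

    The 3' arm is the exact reverse complement of the random 5' arm, so
    the structure is arm_len '(' + loop_len '.' + arm_len ')'. GC content
    of the 5' arm follows ``config.gc_content``.
    """
    rng = _rng(config.seed, 1)
    gc = config.gc_content
    alphabet = np.array(list("ACGU"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arm5 = "".join(alphabet[rng.choice(4, size=config.arm_len, p=p)])
    loop = "".join(alphabet[rng.choice(4, size=config.loop_len, p=p)])
    seq = arm5 + loop + revcomp_rna(arm5)
    db = "(" * config.arm_len + "." * config.loop_len + ")" * config.arm_len
    return Precursor(id=pid, sequence=seq, structure=db), db


def simulate_dicing(precursor: Precursor, config: SimConfig) -> SimTruth:
    """Lay sequential duplex products along the stem.

    5'-arm products start at a fixed offset and advance by ``phase_len``;
    each 3'-arm partner is placed so both strands carry exactly
    ``config.overhang`` unpaired 3' nucleotides on the perfect stem.
    Per-product abundances are log-normal(abundance_mu, abundance_sigma).
    """
    N = len(precursor)
    L = config.product_len
    entry = 3  # fixed dicing entry offset from the hairpin base
    products: list[SimProduct] = []
    for k in range(config.n_duplexes):
        a1 = entry + k * config.phase_len
        a2 = a1 + L - 1
        if a2 > config.arm_len:
            raise ValueError("stem too short for the requested duplexes")
        # partner placed for exact 3' overhangs on both strands
        b1 = N + 1 - a2 + config.overhang
        b2 = N + 1 - a1 + config.overhang
        if b2 > N:
            raise ValueError("3'-arm partner runs off the precursor")
        products.append(
            SimProduct("5p", a1, a2, precursor.subseq(a1, a2), duplex_index=k)
        )
        products.append(
            SimProduct("3p", b1, b2, precursor.subseq(b1, b2), duplex_index=k)
        )
    rng = _rng(config.seed, 2)
    abundances = list(
        rng.lognormal(config.abundance_mu, config.abundance_sigma, size=len(products))
    )
    return SimTruth(
        precursor=precursor,
        structure=precursor.structure or "",
        products=products,
        abundances=abundances,
        config=config,
    )


def sample_reads(truth: SimTruth, config: SimConfig | None = None) -> list[str]:
    """Draw a read library from the truth products.

    Each read is a background degradation fragment with probability
    ``background_rate`` (a uniform random 17-25-nt substring of the
    precursor), otherwise a product chosen proportionally to abundance.
    Product reads have each end independently shifted by +/-1..jitter_max
    with probability ``end_jitter_prob``. Returns raw (uncollapsed)
    sequences; total equals ``depth``.
    """
    cfg = config or truth.config
    rng = _rng(cfg.seed, 3)
    seq = truth.precursor.sequence
    N = len(seq)
    weights = np.array(truth.abundances)
    weights = weights / weights.sum()
    reads: list[str] = []
    for _ in range(cfg.depth):
        if cfg.background_rate > 0 and rng.random() < cfg.background_rate:
            ln = int(rng.integers(17, 26))
            start = int(rng.integers(1, N - ln + 2))
            reads.append(seq[start - 1 : start - 1 + ln])
            continue
        p = truth.products[int(rng.choice(len(truth.products), p=weights))]
        s, e = p.start, p.end
        if cfg.end_jitter_prob > 0 and cfg.jitter_max > 0:
            if rng.random() < cfg.end_jitter_prob:
                s += int(rng.integers(1, cfg.jitter_max + 1)) * (
                    1 if rng.random() < 0.5 else -1
                )
            if rng.random() < cfg.end_jitter_prob:
                e += int(rng.integers(1, cfg.jitter_max + 1)) * (
                    1 if rng.random() < 0.5 else -1
                )
        s = max(1, s)
        e = min(N, e)
        if e - s + 1 >= 15:  # jitter never collapses a read below mappable size
            reads.append(seq[s - 1 : e])
    return reads


def simulate_degradome(
    transcript: str,
    true_site: int,
    signal_reads: int,
    noise_positions: int,
    seed: int = 0,
) -> dict[int, int]:
    """Construct a degradome 5'-end count vector with one true signal.

    ``signal_reads`` counts are placed at ``true_site`` (1-based);
    ``noise_positions`` distinct random other positions get one count
    each. Deterministic given the seed.
    """
    n = len(transcript)
    if not 1 <= true_site <= n:
        raise ValueError(f"true_site {true_site} outside transcript of length {n}")
    rng = _rng(seed, 4)
    counts: dict[int, int] = {}
    if signal_reads > 0:
        counts[true_site] = signal_reads
    candidates = [p for p in range(1, n + 1) if p != true_site]
    k = min(noise_positions, len(candidates))
    for p in rng.choice(len(candidates), size=k, replace=False):
        counts[candidates[int(p)]] = 1
    return counts


def truth_products_detectable(
    truth: SimTruth, reads: Sequence[str], min_reads: int = 5
) -> list[SimProduct]:
    """Products whose neighborhood received >= min_reads sampled reads.

    A read supports a product when it is the exact product sequence or a
    jittered variant (within 3 nt of both ends at the product's locus).
    Products under the threshold cannot survive the block read cutoff and
    are excluded from recovery denominators.
    """
    seq = truth.precursor.sequence
    support = [0] * len(truth.products)
    for r in reads:
        pos = seq.find(r)
        occs = []
        while pos >= 0:
            occs.append(pos + 1)
            pos = seq.find(r, pos + 1)
        for start in occs:
            end = start + len(r) - 1
            for i, p in enumerate(truth.products):
                if abs(start - p.start) <= 3 and abs(end - p.end) <= 3:
                    support[i] += 1
                    break
            break  # count the 5'-most occurrence only
    return [p for i, p in enumerate(truth.products) if support[i] >= min_reads]
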