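"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written as directly as possible from the definition of the
operation it checks — exhaustive enumeration or naive scanning — and shares
no code with the package internals it validates.
"""

from __future__ import annotations

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def max_pairs_enumeration(seq: str, min_loop: int = 3) -> int:
    """Maximum pair count over all nested structures, by plain recursion.

    Enumerates: position i is unpaired, or pairs with each admissible j.
    No memoization — exponential, usable for n <= ~20.
    """
    s = seq.upper().replace("T", "U")

    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        m = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in _PAIRS:
                m = max(m, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return m

    return best(0, len(s) - 1)


def greedy_blocks_oracle(hits, overhang_tol: int = 3):
    """Greedy block partition, re-derived step by step from the rule.

    hits: list of (start, end, count, seq) tuples. Returns a list of
    (rep_start, rep_end, total_count, n_members) sorted by start.
    """
    remaining = list(hits)
    blocks = []
    while remaining:
        rep = remaining[0]
        for h in remaining[1:]:
            # higher count wins; ties: smaller start, shorter, lexicographic
            if h[2] > rep[2]:
                rep = h
            elif h[2] == rep[2]:
                if h[0] < rep[0]:
                    rep = h
                elif h[0] == rep[0]:
                    hl, rl = h[1] - h[0], rep[1] - rep[0]
                    if hl < rl or (hl == rl and h[3] < rep[3]):
                        rep = h
        members = []
        rest = []
        for h in remaining:
            if h[0] >= rep[0] - overhang_tol and h[1] <= rep[1] + overhang_tol:
                members.append(h)
            else:
                rest.append(h)
        blocks.append((rep[0], rep[1], sum(m[2] for m in members), len(members)))
        remaining = rest
    return sorted(blocks)


def window_scores_oracle(srna: str, transcript: str, seed_start=2, seed_end=7):
    """Score of every ungapped window, computed independently.

    The site is reverse-complemented and compared in parallel with the
    sRNA (equivalent to the antiparallel face-off), position weights
    applied from the sRNA's 5' end. Returns {window_start: score}.
    """
    s = srna.upper().replace("T", "U")
    t = transcript.upper().replace("T", "U")
    L = len(s)
    out = {}
    for w in range(len(t) - L + 1):
        site = t[w : w + L]
        site_rc = "".join(_COMPLEMENT[c] for c in reversed(site))
        score = 0.0
        for i, (a, b) in enumerate(zip(s, site_rc), start=1):
            if a == b:
                pen = 0.0
            # a vs site base it faces: site position L-i+1 -> site_rc is the
            # strand a hybridizes to, so a==b means Watson-Crick pairing
            elif (a, _COMPLEMENT[b]) in (("G", "U"), ("U", "G")):
                pen = 0.5
            else:
                pen = 1.0
            if seed_start <= i <= seed_end:
                pen *= 2.0
            score += pen
        out[w + 1] = score
    return out


def expected_duplexes_arithmetic(products, arm_len, loop_len, overhang=2):
    """Duplex set on a perfect stem, from coordinate arithmetic alone.

    products: list of (arm, start, end). On a perfect hairpin of total
    length N = 2*arm_len + loop_len, position i pairs with N - i + 1, so a
    5'-arm product [a1, a2] and 3'-arm product [b1, b2] form a duplex with
    both 3' overhangs equal to ``overhang`` exactly when
    b1 = N + 1 - a2 + overhang and b2 = N + 1 - a1 + overhang.
    Returns a set of ((a1, a2), (b1, b2)).
    """
    N = 2 * arm_len + loop_len
    fives = [(s, e) for arm, s, e in products if arm == "5p"]
    threes = [(s, e) for arm, s, e in products if arm == "3p"]
    out = set()
    for a1, a2 in fives:
        for b1, b2 in threes:
            if b1 == N + 1 - a2 + overhang and b2 == N + 1 - a1 + overhang:
                out.add(((a1, a2), (b1, b2)))
    return out
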