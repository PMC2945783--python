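import random

import pytest
from hypothesis import given, settings, strategies as st

from phasemir.precursor import revcomp_rna
from phasemir.targeting import (
    ScoringParams,
    complementarity_score,
    degradome_signature,
    map_degradome_tags,
    pair_class,
    scan_transcript,
)

from oracles import window_scores_oracle

SRNA = "UGAAGUGGAGUAGAGUAUAAU"  # 21 nt


def site_for(srna, mutations=None):
    """Perfectly complementary site (transcript orientation), then mutate.

    mutations: {srna_position: target_nt} — sets the target nucleotide
    facing the given sRNA position.
    """
    mutations = mutations or {}
    L = len(srna)
    site = list(revcomp_rna(srna))
    for pos, nt in mutations.items():
        site[L - pos] = nt
    return "".join(site)


class TestPairClass:
    @pytest.mark.parametrize(
        "a,b,cls",
        [
            ("A", "U", "match"),
            ("C", "G", "match"),
            ("G", "U", "wobble"),
            ("U", "G", "wobble"),
            ("G", "A", "mismatch"),
            ("A", "A", "mismatch"),
            ("N", "U", "mismatch"),
        ],
    )
    def test_classes(self, a, b, cls):
        assert pair_class(a, b) == cls


class TestComplementarityScore:
    def test_perfect_complement_scores_zero(self):
        assert complementarity_score(SRNA, site_for(SRNA)) == 0.0

    def test_single_nonseed_mismatch(self):
        # sRNA position 10 is A; facing target A is a mismatch
        site = site_for(SRNA, {10: "A"})
        assert complementarity_score(SRNA, site) == 1.0

    def test_seed_wobble(self):
        # position 3 sRNA A; make it G:U-style by checking a U-facing G
        srna = "UGGAGUGGAGUAGAGUAUAAU"  # position 3 = G
        site = site_for(srna, {3: "U"})  # G:U wobble in the seed
        assert complementarity_score(srna, site) == 1.0

    def test_seed_mismatch_doubled(self):
        site = site_for(SRNA, {2: "G"})  # sRNA position 2 G faces G
        assert complementarity_score(SRNA, site) == 2.0

    def test_mixed_positions_sum(self):
        # seed mismatch (1 x 2) + non-seed G:U wobble at position 15 (0.5)
        site = site_for(SRNA, {2: "G", 15: "U"})
        assert complementarity_score(SRNA, site) == 2.5

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            complementarity_score("ACGU" * 5, "ACGU")

    def test_monotone_in_mismatches(self):
        base = site_for(SRNA)
        prev = complementarity_score(SRNA, base)
        for pos in range(1, len(SRNA) + 1):
            worse = site_for(SRNA, {p: _mismatch_nt(SRNA, p) for p in range(1, pos + 1)})
            cur = complementarity_score(SRNA, worse)
            assert cur >= prev
            prev = cur

    def test_seed_penalty_is_double_nonseed(self):
        p = ScoringParams()
        seed = complementarity_score(SRNA, site_for(SRNA, {4: _mismatch_nt(SRNA, 4)}), p)
        nonseed = complementarity_score(
            SRNA, site_for(SRNA, {12: _mismatch_nt(SRNA, 12)}), p
        )
        assert seed == 2 * nonseed


def _mismatch_nt(srna, pos):
    """A target nucleotide that mismatches sRNA position pos (no wobble)."""
    nt = srna[pos - 1]
    return {"A": "C", "C": "A", "G": "G", "U": "C"}[nt]


class TestScanTranscript:
    def test_embedded_reverse_complement(self):
        transcript = "GCAU" * 10 + revcomp_rna(SRNA) + "AUGC" * 10
        hits = scan_transcript(SRNA, transcript)
        assert hits[0].score == 0.0
        assert hits[0].site_start == 41
        # cleavage opposite sRNA position 10
        assert hits[0].cleavage_pos == 41 + len(SRNA) - 10

    def test_no_window_below_cutoff(self):
        transcript = "A" * 200
        assert scan_transcript("G" * 21, transcript, ScoringParams(score_cutoff=0.0)) == []

    def test_matches_exhaustive_oracle(self):
        """Hit set equals per-window oracle scoring on random transcripts."""
        rng = random.Random(13)
        params = ScoringParams(score_cutoff=12.0)  # loose, exercise many windows
        for _ in range(15):
            srna = "".join(rng.choice("ACGU") for _ in range(21))
            transcript = "".join(rng.choice("ACGU") for _ in range(rng.randint(50, 500)))
            got = {h.site_start: h.score for h in scan_transcript(srna, transcript, params)}
            oracle = window_scores_oracle(srna, transcript)
            want = {w: s for w, s in oracle.items() if s <= params.score_cutoff}
            assert got == want

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_oracle_equivalence_property(self, seed):
        rng = random.Random(seed)
        srna = "".join(rng.choice("ACGU") for _ in range(rng.randint(19, 24)))
        transcript = "".join(rng.choice("ACGU") for _ in range(100))
        got = {h.site_start: h.score for h in scan_transcript(srna, transcript)}
        want = {
            w: s for w, s in window_scores_oracle(srna, transcript).items() if s <= 4.5
        }
        assert got == want


class TestDegradomeSignature:
    def _hit(self, cleavage_pos):
        from phasemir.targeting import TargetHit

        return TargetHit(
            srna_name="s", transcript_id="t", site_start=1, site_end=21,
            score=1.0, cleavage_pos=cleavage_pos,
        )

    def test_unique_maximum_rank(self):
        counts = {i: 1 for i in range(1, 12)}
        counts[50] = 30
        h = degradome_signature(self._hit(50), counts)
        assert h.degradome_count == 30
        assert h.p_value == pytest.approx(1 / 12)
        assert h.supported

    def test_zero_at_site(self):
        h = degradome_signature(self._hit(50), {1: 5, 2: 5})
        assert h.p_value == 1.0 and not h.supported

    def test_uniform_ties(self):
        counts = {i: 4 for i in [1, 5, 9, 13, 17, 21, 25, 29, 33, 50]}
        h = degradome_signature(self._hit(50), counts)
        assert h.p_value == 1.0

    def test_all_zero_vector(self):
        h = degradome_signature(self._hit(50), [0] * 100)
        assert h.p_value == 1.0 and not h.supported


def test_map_degradome_tags_exact():
    transcripts = {"t1": "AAAAGGGGCCCCUUUUAAAAGGGG"}
    counts = map_degradome_tags(["GGGGCCCC", "GGGG"], transcripts)
    assert counts["t1"][5] == 2  # both tags start at 5
    assert counts["t1"][21] == 1
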