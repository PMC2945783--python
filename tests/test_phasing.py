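import pytest

from phasemir.blocks import Block
from phasemir.phasing import (
    classify_positions,
    detect_phased_groups,
    duplex_overhangs,
    find_duplexes,
    partner_region,
)
from phasemir.precursor import MatureAnnotation, parse_dotbracket
from phasemir.reads import Hit, ReadRecord
from phasemir.simulate import SimConfig, make_hairpin, simulate_dicing

from conftest import make_block
from oracles import expected_duplexes_arithmetic


def blocks_from_truth(truth):
    out = []
    for p, a in zip(truth.products, truth.abundances):
        r = ReadRecord(p.sequence, max(1, int(a * 100)))
        h = Hit(r, truth.precursor.id, p.start, p.end)
        out.append(
            Block(truth.precursor.id, p.start, p.end, r, r.count, [h])
        )
    out.sort(key=lambda b: b.start)
    return out


class TestDetectPhasedGroups:
    def test_exact_tandem(self):
        blocks = [make_block(s, s + 20, 10) for s in (10, 31, 52)]
        groups = detect_phased_groups(blocks)
        assert len(groups) == 1
        assert [m.start for m in groups[0].members] == [10, 31, 52]
        assert groups[0].registers == [0, 0, 0]

    def test_one_skipped_slot(self):
        blocks = [make_block(10, 30, 10), make_block(53, 73, 10)]
        groups = detect_phased_groups(blocks)
        assert len(groups) == 1 and len(groups[0]) == 2

    def test_out_of_register_no_group(self):
        blocks = [make_block(10, 30, 10), make_block(25, 45, 10)]
        assert detect_phased_groups(blocks) == []

    def test_order_and_translation_invariance(self):
        starts = (10, 31, 52, 100)
        blocks = [make_block(s, s + 20, 10) for s in starts]
        fwd = detect_phased_groups(blocks)
        rev = detect_phased_groups(list(reversed(blocks)))
        assert [[m.start for m in g.members] for g in fwd] == [
            [m.start for m in g.members] for g in rev
        ]
        shifted = [make_block(s + 7, s + 27, 10) for s in starts]
        sh = detect_phased_groups(shifted)
        assert [[m.start - 7 for m in g.members] for g in sh] == [
            [m.start for m in g.members] for g in fwd
        ]

    def test_block_in_at_most_one_group(self):
        blocks = [make_block(s, s + 20, 10) for s in (10, 31, 52, 73, 120, 141)]
        groups = detect_phased_groups(blocks)
        seen = [m.start for g in groups for m in g.members]
        assert len(seen) == len(set(seen))


class TestPartnerRegion:
    def test_perfect_stem_read_off(self):
        pt = parse_dotbracket("(((((((...)))))))")
        assert partner_region(make_block(1, 5, 10), pt) == (13, 17)

    def test_loop_block_undefined(self):
        pt = parse_dotbracket("(((((((...)))))))")
        assert partner_region(make_block(8, 10, 10), pt) is None

    def test_involution_on_simulated_stems(self):
        """partner_region(partner_region(b)) recovers b's span on perfect stems."""
        for seed in range(10):
            cfg = SimConfig(seed=seed)
            pre, db = make_hairpin(cfg)
            pt = parse_dotbracket(db)
            truth = simulate_dicing(pre, cfg)
            for p in truth.products:
                b = make_block(p.start, p.end, 10, pid=pre.id)
                reg = partner_region(b, pt)
                assert reg is not None
                back = partner_region(make_block(reg[0], reg[1], 10, pid=pre.id), pt)
                assert back is not None
                assert abs(back[0] - p.start) <= 1 and abs(back[1] - p.end) <= 1


class TestFindDuplexes:
    def test_exact_two_nt_overhangs_detected(self, perfect_hairpin):
        pre, db, cfg = perfect_hairpin
        truth = simulate_dicing(pre, cfg)
        blocks = blocks_from_truth(truth)
        dups = find_duplexes(blocks, parse_dotbracket(db), tol=0)
        assert len(dups) == cfg.n_duplexes
        for d in dups:
            assert d.overhang_3p_on_5parm == 2
            assert d.overhang_3p_on_3parm == 2

    def test_five_nt_overhang_rejected(self, perfect_hairpin):
        pre, db, cfg = perfect_hairpin
        truth = simulate_dicing(pre, cfg)
        blocks = blocks_from_truth(truth)
        # shift one 3'-arm partner 3 nt 3'-ward: both overhangs leave 2 +/- 1
        shifted = []
        for b in blocks:
            if b.start == min(x.start for x in blocks if x.start > len(pre) // 2):
                shifted.append(make_block(b.start + 3, b.end + 3, b.total_count, pid=pre.id))
            else:
                shifted.append(b)
        dups = find_duplexes(shifted, parse_dotbracket(db), tol=1)
        assert len(dups) == cfg.n_duplexes - 1

    def test_matches_arithmetic_oracle_on_simulated_precursors(self):
        """Detected duplex coordinates equal the perfect-stem arithmetic set."""
        for seed in range(50):
            cfg = SimConfig(seed=seed)
            pre, db = make_hairpin(cfg)
            truth = simulate_dicing(pre, cfg)
            blocks = blocks_from_truth(truth)
            got = {
                ((d.block_5p.start, d.block_5p.end), (d.block_3p.start, d.block_3p.end))
                for d in find_duplexes(blocks, parse_dotbracket(db), tol=0)
            }
            want = expected_duplexes_arithmetic(
                [(p.arm, p.start, p.end) for p in truth.products],
                cfg.arm_len,
                cfg.loop_len,
                cfg.overhang,
            )
            assert got == want

    def test_reported_overhangs_within_bounds(self, perfect_hairpin):
        pre, db, cfg = perfect_hairpin
        truth = simulate_dicing(pre, cfg)
        blocks = blocks_from_truth(truth)
        for tol in (0, 1):
            for d in find_duplexes(blocks, parse_dotbracket(db), tol=tol):
                assert abs(d.overhang_3p_on_5parm - 2) <= tol
                assert abs(d.overhang_3p_on_3parm - 2) <= tol


class TestClassifyPositions:
    @staticmethod
    def _setup():
        cfg = SimConfig(seed=4)
        pre, db = make_hairpin(cfg)
        pt = parse_dotbracket(db)
        truth = simulate_dicing(pre, cfg)
        # annotate the middle duplex (index 1) as the miRNA/miRNA*
        mid5 = next(p for p in truth.products if p.duplex_index == 1 and p.arm == "5p")
        mid3 = next(p for p in truth.products if p.duplex_index == 1 and p.arm == "3p")
        matures = [
            MatureAnnotation("miR-sim", mid5.start, mid5.end, "miRNA"),
            MatureAnnotation("miR-sim*", mid3.start, mid3.end, "miRNA*"),
        ]
        return pre, pt, truth, matures

    def test_loop_and_base_sides(self):
        pre, pt, truth, matures = self._setup()
        blocks = blocks_from_truth(truth)
        pc = classify_positions(blocks, matures, pt)
        assert pc is not None
        # products 5' of the annotated duplex on the 5' arm are base-side;
        # products 3' of it (toward the loop) are loop-side
        d0_5p = next(p for p in truth.products if p.duplex_index == 0 and p.arm == "5p")
        d2_5p = next(p for p in truth.products if p.duplex_index == 2 and p.arm == "5p")
        assert pc.per_block[d0_5p.start] == "base"
        assert pc.per_block[d2_5p.start] == "loop"
        assert pc.label == "+/-"

    def test_exclusive_sides(self):
        pre, pt, truth, matures = self._setup()
        base_only = [
            b
            for b in blocks_from_truth(truth)
            if b.start <= 30 or b.end >= len(pre) - 30
        ]
        # keep annotated duplex blocks too
        ann = [b for b in blocks_from_truth(truth) if any(
            m.start == b.start for m in matures)]
        pc = classify_positions(base_only + ann, matures, pt)
        assert pc.label == "-"

    def test_missing_annotation_warns(self):
        pre, pt, truth, _ = self._setup()
        with pytest.warns(UserWarning):
            assert classify_positions(blocks_from_truth(truth), [], pt) is None
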