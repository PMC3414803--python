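import numpy as np
import pytest

from tbssr.elements import (
    ElementRules,
    GeneFeature,
    find_bim,
    find_rit,
    find_tn554_like,
    mirror_features,
    reverse_complement,
    scan_repeats,
    validate_call,
)


def feat(start, end, strand="+", fid="g", tbssr=True, famint=None, rep="r1"):
    return GeneFeature(
        replicon=rep, start=start, end=end, strand=strand, id=fid,
        is_tbssr=tbssr, famint=famint,
    )


def rit_trio(o1=5, o2=7, strands=("+", "+", "+"), l=(1200, 1200, 1200)):
    a = feat(1000, 1000 + l[0], strands[0], "a")
    b = feat(a.end - o1, a.end - o1 + l[1], strands[1], "b")
    c = feat(b.end - o2, b.end - o2 + l[2], strands[2], "c")
    return [a, b, c]


class TestFindRit:
    def test_valid_trio_called(self):
        calls = find_rit(rit_trio())
        assert len(calls) == 1
        assert calls[0].members == ["a", "b", "c"]
        assert validate_call(calls[0])

    def test_opposite_strand_middle_gene_rejected(self):
        assert find_rit(rit_trio(strands=("+", "-", "+"))) == []

    def test_overlap_outside_range_rejected(self):
        assert find_rit(rit_trio(o1=5, o2=12)) == []
        assert find_rit(rit_trio(o1=3, o2=5)) == []

    def test_span_outside_range_rejected(self):
        assert find_rit(rit_trio(l=(1400, 1400, 1400))) == []

    def test_minus_strand_members_labelled_in_transcription_order(self):
        calls = find_rit(rit_trio(strands=("-", "-", "-")))
        assert len(calls) == 1
        assert calls[0].members == ["c", "b", "a"]

    def test_unsorted_input_rejected(self):
        trio = rit_trio()
        with pytest.raises(ValueError):
            find_rit([trio[2], trio[0], trio[1]])


class TestFindTn554:
    def tandem(self, long_aa=700, short_aa=350, gap=80, strands=("+", "+"),
               tnpc_gap=100, tnpc=True):
        a = feat(1000, 1000 + 3 * (long_aa + 1), strands[0], "long")
        b = feat(a.end + gap, a.end + gap + 3 * (short_aa + 1), strands[1], "short")
        feats = [a, b]
        if tnpc:
            c = feat(b.end + tnpc_gap, b.end + tnpc_gap + 603, strands[1],
                     "acc", tbssr=False)
            feats.append(c)
        return feats

    def test_valid_tandem_with_tnpc(self):
        calls = find_tn554_like(self.tandem())
        assert len(calls) == 1
        assert calls[0].has_tnpC
        assert calls[0].members == ["long", "short", "acc"]
        assert validate_call(calls[0])

    def test_opposite_strands_rejected(self):
        assert find_tn554_like(self.tandem(strands=("+", "-"), tnpc=False)) == []

    def test_long_member_below_range_rejected(self):
        assert find_tn554_like(self.tandem(long_aa=500, tnpc=False)) == []

    def test_no_tnpc_when_next_gene_far(self):
        calls = find_tn554_like(self.tandem(tnpc_gap=900))
        assert len(calls) == 1
        assert not calls[0].has_tnpC

    def test_n_extension_flag(self):
        calls = find_tn554_like(self.tandem(long_aa=800, tnpc=False))
        assert calls[0].diagnostics["n_extension_aa"] == 450
        assert calls[0].diagnostics["n_extension_flag"]


class TestFindBim:
    def pair(self, gap=100, partner_famint=45):
        a = feat(1000, 2053, "+", "tbssr")
        b = feat(a.end + gap, a.end + gap + 753, "+", "partner",
                 tbssr=False, famint=partner_famint)
        return [a, b]

    def test_adjacent_pair_called(self):
        calls = find_bim(self.pair(), 45)
        assert len(calls) == 1
        assert calls[0].members == ["tbssr", "partner"]

    def test_distant_partner_rejected(self):
        assert find_bim(self.pair(gap=5000), 45) == []

    def test_unset_partner_family_is_configuration_error(self):
        with pytest.raises(ValueError):
            find_bim(self.pair(), None)

    def test_planted_suite_recovered_exactly(self, element_suite):
        calls = find_bim(element_suite.features, 45)
        planted = [c for c in element_suite.planted_elements if c.type == "BIM"]
        assert {frozenset(c.members) for c in calls} == {
            frozenset(c.members) for c in planted
        }


class TestSuiteRecovery:
    def test_sensitivity_and_precision_one(self, element_suite):
        calls = (
            find_rit(element_suite.features)
            + find_tn554_like(element_suite.features)
            + find_bim(element_suite.features, 45)
        )
        called = {(c.type, frozenset(c.members)) for c in calls}
        planted = {
            (c.type, frozenset(c.members)) for c in element_suite.planted_elements
        }
        assert called == planted  # sensitivity 1.0 and precision 1.0
        assert all(validate_call(c) for c in calls)

    def test_strand_mirror_symmetry(self, element_suite):
        mirrored = mirror_features(element_suite.features, element_suite.length)
        calls = (
            find_rit(element_suite.features)
            + find_tn554_like(element_suite.features)
            + find_bim(element_suite.features, 45)
        )
        mcalls = (
            find_rit(mirrored)
            + find_tn554_like(mirrored)
            + find_bim(mirrored, 45)
        )
        assert {(c.type, frozenset(c.members)) for c in calls} == {
            (c.type, frozenset(c.members)) for c in mcalls
        }
        flip = {"+": "-", "-": "+"}
        by_key = {(c.type, frozenset(c.members)): c for c in calls}
        for c in mcalls:
            assert c.strand == flip[by_key[(c.type, frozenset(c.members))].strand]


class TestScanRepeats:
    def test_planted_inverted_repeat_found(self):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 1000))
        seg = seq[100:128]
        planted = seq[:400] + seq[400:500] + reverse_complement(seg) + seq[500:]
        hits = scan_repeats(planted, min_len=9)
        inv = [h for h in hits if h.type == "inverted" and h.length >= 28]
        assert any(h.pos1 == 100 for h in inv)

    def test_planted_direct_repeat_found(self):
        rng = np.random.default_rng(6)
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 800))
        seg = seq[50:70]
        planted = seq[:300] + seg + seq[300:]
        hits = scan_repeats(planted, min_len=9)
        assert any(
            h.type == "direct" and h.length >= 20 and h.pos1 == 50 for h in hits
        )

    def test_homopolymer_suppressed(self):
        assert scan_repeats("A" * 100) == []
        flagged = scan_repeats("A" * 100, include_low_complexity=True)
        assert flagged and all(h.low_complexity for h in flagged)

    def test_random_sequence_null_rate(self):
        # empirical null: counting direct plus inverted matches over the
        # whole kilobase, 12/100 seeds in this range show a spurious
        # length-12 repeat; the rate is frozen here as the regression bound
        hits_seen = 0
        for seed in range(100):
            rng = np.random.default_rng(2000 + seed)
            seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 1000))
            if scan_repeats(seq, min_len=12, max_window=1000):
                hits_seen += 1
        assert hits_seen <= 12

    def test_invalid_nucleotides_rejected(self):
        with pytest.raises(ValueError):
            scan_repeats("ACGU" * 10)
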