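import numpy as np
import pytest

from tbssr.elements import find_bim, find_rit, find_tn554_like
from tbssr.similarity import sw_align
from tbssr.synthetic import (
    ElementPlan,
    SynthParams,
    default_element_suite,
    generate_annotated_replicon,
    generate_protein_set,
    mutate_sequence,
)


class TestMutateSequence:
    def test_identity_one_is_a_no_op(self, rng):
        assert mutate_sequence("ACDEF", 1.0, set(), rng) == "ACDEF"

    def test_protected_sites_never_change(self, rng):
        seq = "R" + "A" * 25 + "Y"
        out = mutate_sequence(seq, 0.0, {0, 26}, rng)
        assert out[0] == "R" and out[26] == "Y"

    def test_observed_identity_concentrates_on_target(self):
        # binomial concentration: 1000 sites, 50 seeds
        obs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            seq = "A" * 1000
            out = mutate_sequence(seq, 0.7, set(), rng)
            obs.append(sum(a == b for a, b in zip(seq, out)) / 1000)
        assert 0.66 <= np.mean(obs) <= 0.74
        assert all(0.6 <= x <= 0.8 for x in obs)

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            mutate_sequence("", 0.5, set(), rng)

    def test_out_of_range_protection_rejected(self, rng):
        with pytest.raises(ValueError):
            mutate_sequence("ACDE", 0.5, {10}, rng)


class TestGenerateProteinSet:
    def test_zero_mutation_family_is_identical(self):
        params = SynthParams(
            n_families=1, family_size_range=(3, 3), n_singletons=0,
            within_family_identity=1.0, motif_fraction=0.0, seed=0,
        )
        proteins, truth = generate_protein_set(params)
        assert len(proteins) == 3
        assert len({p.sequence for p in proteins}) == 1
        assert {truth.entries[p.id].true_family for p in proteins} == {0}

    def test_forced_motif_spacing(self):
        params = SynthParams(
            n_families=4, family_size_range=(5, 5), n_singletons=0,
            motif_fraction=1.0, motif_spacing_range=(30, 30), seed=2,
        )
        _proteins, truth = generate_protein_set(params)
        for e in truth.entries.values():
            r, y = e.motif_positions
            assert y - r == 30

    def test_motif_residues_planted_exactly(self):
        proteins, truth = generate_protein_set(SynthParams(seed=4))
        for p in proteins:
            e = truth.entries[p.id]
            if e.motif_positions:
                r, y = e.motif_positions
                assert p.sequence[r] == "R"
                assert p.sequence[y] == "Y"

    def test_within_family_identity_exceeds_between(self):
        """Site-level separation measured with the package aligner.

        With member-vs-ancestor identity 0.6, aligned identity between
        family members sits near 0.4 over the aligned region while
        unrelated pairs align only short segments: coverage-normalised
        identity (matches over the shorter sequence) separates cleanly.
        """
        params = SynthParams(
            n_families=8, family_size_range=(12, 40), n_singletons=20,
            within_family_identity=0.6, seed=1,
        )
        proteins, truth = generate_protein_set(params)
        rng = np.random.default_rng(0)
        fams = {}
        for p in proteins:
            fams.setdefault(truth.entries[p.id].true_family, []).append(p)
        members = [f for f in fams.values() if len(f) > 1]
        within, between = [], []
        for _ in range(50):
            fam = members[rng.integers(0, len(members))]
            i, j = rng.choice(len(fam), size=2, replace=False)
            a, b = fam[i], fam[j]
            score, ident, ((qs, qe), _) = sw_align(a.sequence, b.sequence)
            within.append(ident * (qe - qs) / min(a.length, b.length))
        for _ in range(50):
            f1, f2 = rng.choice(len(members), size=2, replace=False)
            a = members[f1][0]
            b = members[f2][0]
            score, ident, ((qs, qe), _) = sw_align(a.sequence, b.sequence)
            between.append(ident * (qe - qs) / min(a.length, b.length))
        assert min(within) > 0.3
        assert max(between) <= 0.2

    def test_seed_determinism(self):
        p1, t1 = generate_protein_set(SynthParams(seed=7))
        p2, t2 = generate_protein_set(SynthParams(seed=7))
        assert [(p.id, p.sequence, p.mge_type, p.host) for p in p1] == [
            (p.id, p.sequence, p.mge_type, p.host) for p in p2
        ]
        assert t1.entries == t2.entries

    def test_every_protein_in_truth_exactly_once(self):
        proteins, truth = generate_protein_set(SynthParams(seed=5))
        assert sorted(truth.entries) == sorted(p.id for p in proteins)

    def test_incompatible_identity_and_length_rejected(self):
        with pytest.raises(ValueError):
            SynthParams(
                seq_length_range=(60, 80),
                within_family_identity=0.3,
                motif_spacing_range=(28, 32),
            )

    def test_confounder_families_share_similarity(self):
        proteins, truth = generate_protein_set(
            SynthParams(
                confounder=True, seed=6, n_singletons=0,
                within_family_identity=0.95,
            )
        )
        by_fam = {}
        for p in proteins:
            by_fam.setdefault(truth.entries[p.id].true_family, []).append(p)
        confounded, _, _ = sw_align(by_fam[0][0].sequence, by_fam[1][0].sequence)
        unrelated, _, _ = sw_align(by_fam[0][0].sequence, by_fam[2][0].sequence)
        assert confounded > 100  # ~30% identity over the full length
        assert confounded > 2 * unrelated


class TestGenerateAnnotatedReplicon:
    def test_planted_rit_obeys_overlap_rule(self):
        rep = generate_annotated_replicon(ElementPlan(items=["rit"], seed=0))
        feats = rep.features
        assert len(feats) == 3
        o1 = feats[0].end - feats[1].start
        o2 = feats[1].end - feats[2].start
        assert 4 <= o1 <= 8 and 4 <= o2 <= 8
        assert all(f.strand == "+" for f in feats)
        span = feats[2].end - feats[0].start
        assert 3300 <= span <= 3700

    def test_strand_decoy_has_empty_truth(self):
        rep = generate_annotated_replicon(
            ElementPlan(items=["rit_decoy_strand"], seed=0)
        )
        assert rep.planted_elements == []
        assert rep.features[1].strand == "-"

    def test_tn554_long_member_in_range(self):
        rep = generate_annotated_replicon(ElementPlan(items=["tn554"], seed=0))
        long = max(rep.features, key=lambda f: f.product_len)
        assert 611 <= long.product_len <= 828
        assert long.length // 3 - 1 == long.product_len

    def test_features_sorted_and_truth_references_exist(self, element_suite):
        ids = {f.id for f in element_suite.features}
        starts = [f.start for f in element_suite.features]
        assert starts == sorted(starts)
        for call in element_suite.planted_elements:
            assert set(call.members) <= ids

    def test_each_decoy_violates_a_detector_rule(self, element_suite):
        """Decoys must not be recovered by any detector."""
        calls = (
            find_rit(element_suite.features)
            + find_tn554_like(element_suite.features)
            + find_bim(element_suite.features, 45)
        )
        called = {frozenset(c.members) for c in calls}
        planted = {frozenset(c.members) for c in element_suite.planted_elements}
        assert called == planted
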