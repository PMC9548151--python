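"""Training/test-set curation rules."""

from itertools import chain, combinations

import numpy as np
import pytest

from flankrnn.curation import (
    ClinicalRecord,
    CONFLICTING,
    TN,
    TP,
    VUS_ONLY,
    filter_training_indels,
    filter_training_snvs,
    is_rare,
    match_negatives_by_location,
    passes_presence_filter,
    resolve_clinical_label,
    split_train_val,
)

ASSERTIONS = ("pathogenic", "likely_pathogenic", "benign", "likely_benign", "vus")


def rec(assertions, presence=None, pos=0, key=None, **kw):
    return ClinicalRecord(
        variant_key=key or f"chr1:{pos}:A:C",
        assertions=frozenset(assertions),
        presence=presence or {},
        chrom="chr1",
        pos=pos,
        **kw,
    )


def oracle_resolution(subset):
    """Independent restatement of the conflict rules via side membership."""
    path = {"pathogenic", "likely_pathogenic"} & subset
    benign = {"benign", "likely_benign"} & subset
    vus = {"vus"} & subset
    sides = sum(map(bool, (path, benign, vus)))
    if sides > 1:
        return CONFLICTING
    if path:
        return TP
    if benign:
        return TN
    return VUS_ONLY


class TestResolveClinicalLabel:
    @pytest.mark.parametrize(
        "assertions,expected",
        [
            ({"pathogenic", "likely_pathogenic"}, TP),
            ({"benign", "likely_benign"}, TN),
            ({"benign", "vus"}, CONFLICTING),
            ({"pathogenic", "vus"}, CONFLICTING),
            ({"benign", "pathogenic"}, CONFLICTING),
            ({"vus"}, VUS_ONLY),
        ],
    )
    def test_named_scenarios(self, assertions, expected):
        assert resolve_clinical_label(rec(assertions)) == expected

    def test_exhaustive_over_all_31_nonempty_subsets(self):
        subsets = chain.from_iterable(
            combinations(ASSERTIONS, k) for k in range(1, 6)
        )
        count = 0
        for subset in subsets:
            s = set(subset)
            assert resolve_clinical_label(rec(s)) == oracle_resolution(s)
            count += 1
        assert count == 31

    def test_empty_assertion_set_rejected(self):
        with pytest.raises(ValueError):
            ClinicalRecord(variant_key="k", assertions=frozenset())


class TestPresenceFilter:
    @pytest.mark.parametrize("g1000", [False, True])
    @pytest.mark.parametrize("exac", [False, True])
    @pytest.mark.parametrize("gnomad", [False, True])
    def test_truth_table_all_8_combinations(self, g1000, exac, gnomad):
        presence = {"1000GP": g1000, "ExAC": exac, "gnomAD": gnomad}
        flags = [g1000, exac, gnomad]
        expected = any(flags) and not all(flags)
        assert passes_presence_filter(rec({"benign"}, presence)) == expected

    def test_filter_keeps_tp_tn_only_and_is_idempotent(self):
        records = [
            rec({"pathogenic"}, {"gnomAD": True}, pos=1, key="a"),  # kept, label 1
            rec({"benign"}, {"ExAC": True}, pos=2, key="b"),  # kept, label 0
            rec({"benign", "vus"}, {"ExAC": True}, pos=3, key="c"),  # conflicting
            rec({"vus"}, {"ExAC": True}, pos=4, key="d"),  # vus only
            rec({"pathogenic"}, {"1000GP": True, "ExAC": True, "gnomAD": True},
                pos=5, key="e"),  # present everywhere
            rec({"pathogenic"}, {}, pos=6, key="f"),  # absent everywhere
        ]
        out = filter_training_snvs(records)
        assert [(l.record.variant_key, l.label) for l in out] == [("a", 1), ("b", 0)]
        again = filter_training_snvs([l.record for l in out])
        assert [(l.record.variant_key, l.label) for l in again] == [("a", 1), ("b", 0)]


class TestIndelFilter:
    @pytest.mark.parametrize(
        "length,frameshift,kept",
        [
            (3, False, True),
            (48, False, True),
            (49, False, False),
            (1, False, False),
            (2, False, True),
            (6, True, False),
        ],
    )
    def test_length_and_frame_rules(self, length, frameshift, kept):
        r = rec({"pathogenic"}, indel_length=length, is_frameshift=frameshift)
        out = filter_training_indels([r])
        assert bool(out) == kept


class TestRareFilter:
    def test_rare_means_max_af_below_threshold(self):
        r1 = rec({"benign"}, max_af={"gnomAD": 0.005, "ExAC": 0.0})
        r2 = rec({"benign"}, max_af={"gnomAD": 0.02})
        assert is_rare(r1) and not is_rare(r2)


class TestMatchNegatives:
    def test_only_candidates_within_10kb_eligible(self):
        pos = [rec({"pathogenic"}, pos=50_000, key="p1")]
        cands = [
            rec({"benign"}, pos=55_000, key="n1"),
            rec({"benign"}, pos=70_000, key="n2"),
        ]
        m = match_negatives_by_location(pos, cands, seed=0)
        assert [n.variant_key for n in m.negatives] == ["n1"]
        assert not m.unmatched

    def test_positive_without_nearby_candidate_reported_unmatched(self):
        pos = [rec({"pathogenic"}, pos=50_000, key="p1")]
        cands = [rec({"benign"}, pos=70_000, key="n1")]
        m = match_negatives_by_location(pos, cands, seed=0)
        assert not m.pairs and [p.variant_key for p in m.unmatched] == ["p1"]

    def test_shared_candidate_used_once_without_replacement(self):
        pos = [
            rec({"pathogenic"}, pos=50_000, key="p1"),
            rec({"pathogenic"}, pos=51_000, key="p2"),
        ]
        cands = [rec({"benign"}, pos=50_500, key="n1")]
        m = match_negatives_by_location(pos, cands, seed=0)
        assert len(m.pairs) == 1 and len(m.unmatched) == 1

    def test_negatives_never_overlap_positive_set(self):
        rng = np.random.default_rng(0)
        pos = [rec({"pathogenic"}, pos=int(p), key=f"p{i}")
               for i, p in enumerate(rng.integers(0, 100_000, 30))]
        cands = pos[:10] + [
            rec({"benign"}, pos=int(p), key=f"n{i}")
            for i, p in enumerate(rng.integers(0, 100_000, 100))
        ]
        m = match_negatives_by_location(pos, cands, seed=1)
        pos_keys = {p.variant_key for p in pos}
        assert all(n.variant_key not in pos_keys for n in m.negatives)
        # without replacement: all matched negatives distinct
        keys = [n.variant_key for n in m.negatives]
        assert len(keys) == len(set(keys))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        pos = [rec({"pathogenic"}, pos=int(p), key=f"p{i}")
               for i, p in enumerate(rng.integers(0, 50_000, 20))]
        cands = [rec({"benign"}, pos=int(p), key=f"n{i}")
                 for i, p in enumerate(rng.integers(0, 50_000, 60))]
        m1 = match_negatives_by_location(pos, cands, seed=7)
        m2 = match_negatives_by_location(pos, cands, seed=7)
        assert [n.variant_key for n in m1.negatives] == [
            n.variant_key for n in m2.negatives
        ]


class TestSplit:
    def test_70_30_sizes(self):
        train, val = split_train_val(list(range(100)), [0, 1] * 50, seed=0)
        assert len(train) == 70 and len(val) == 30
        assert sorted(train + val) == list(range(100))

    def test_stratified_on_tiny_balanced_set(self):
        labels = [0] * 5 + [1] * 5
        train, val = split_train_val(list(range(10)), labels, seed=1)
        n_pos_train = sum(labels[i] for i in train)
        assert 3 <= n_pos_train <= 4
        assert 3 <= len(train) - n_pos_train <= 4

    def test_same_seed_identical_partition(self):
        labels = list(np.random.default_rng(3).integers(0, 2, 57))
        a = split_train_val(list(range(57)), labels, seed=9)
        b = split_train_val(list(range(57)), labels, seed=9)
        assert a == b

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_train_val(list(range(9)), [0, 1] * 4 + [0], seed=0)
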