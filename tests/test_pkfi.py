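"""Curation rules: filtering, cutoffs, duplicate voting, family labeling."""

import itertools
import math
import random

import numpy as np
import pytest

from pankinet.pkfi import (ACTIVE, EXCLUDED, INACTIVE, MIXED, BinaryActivity,
                           KinaseFamily, PKFISet, RawActivityRecord,
                           balance_ratio, binarize, build_pkfi_set,
                           consensus_calls, filter_records, is_eligible,
                           label_pkfi, split_set, vote_duplicates)


def rec(relation="=", measure="IC50_nM", value=100.0, cid="C1", kid="K1",
        **extra):
    return RawActivityRecord(compound_id=cid, smiles="c1ccccc1",
                             kinase_id=kid, measure=measure,
                             relation=relation, value=value, **extra)


class TestFilterRecords:
    def test_censored_relations_removed_order_preserved(self):
        records = [rec("="), rec("~"), rec("<"), rec(">>"), rec(">")]
        kept = filter_records(records)
        assert [r.relation for r in kept] == ["=", "<", ">"]

    def test_empty_input(self):
        assert filter_records([]) == []

    def test_counts_by_direct_filtering(self):
        records = [rec(">>")] * 3 + [rec("=")] * 7
        assert len(filter_records(records)) == 7

    def test_provenance_attributes_checked_when_present(self):
        good = rec(assay_type="Binding", target_type="SINGLE PROTEIN",
                   confidence=9)
        bad_assay = rec(assay_type="Functional")
        bad_conf = rec(confidence=8)
        absent = rec()  # no provenance attributes: passes
        assert filter_records([good, bad_assay, bad_conf, absent]) == \
            [good, absent]


class TestBinarize:
    @pytest.mark.parametrize("measure,value,expected", [
        ("IC50_nM", 100.0, ACTIVE),
        ("IC50_nM", 499.99, ACTIVE),
        ("IC50_nM", 500.0, INACTIVE),   # strict '<'
        ("IC50_nM", 5000.0, INACTIVE),
        ("pKi", 6.0, INACTIVE),         # strict '>'
        ("pKi", 6.01, ACTIVE),
        ("pKi", 8.5, ACTIVE),
    ])
    def test_strict_cutoffs(self, measure, value, expected):
        assert binarize(rec(measure=measure, value=value)) == expected

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            binarize(rec(measure="Kd_nM"))


class TestVoteDuplicates:
    @pytest.mark.parametrize("calls,expected", [
        ([ACTIVE] * 4 + [INACTIVE], ACTIVE),      # 4/5 = 0.80 kept
        ([ACTIVE], ACTIVE),
        ([ACTIVE, INACTIVE], EXCLUDED),
        ([INACTIVE] * 5, INACTIVE),
        ([ACTIVE] * 3 + [INACTIVE], EXCLUDED),    # 0.75 < 0.80
    ])
    def test_examples(self, calls, expected):
        assert vote_duplicates(calls) == expected

    def test_agrees_with_brute_force_on_all_multisets_up_to_6(self):
        for size in range(1, 7):
            for calls in itertools.product([ACTIVE, INACTIVE], repeat=size):
                frac_a = calls.count(ACTIVE) / size
                best = max(frac_a, 1 - frac_a)
                expected = (EXCLUDED if best < 0.8
                            else (ACTIVE if frac_a >= 0.5 else INACTIVE))
                assert vote_duplicates(list(calls)) == expected, calls

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vote_duplicates([])


def family(n, fid="F"):
    return KinaseFamily(family_id=fid, group="TK",
                        member_kinase_ids=frozenset(
                            f"{fid}_K{i}" for i in range(n)))


def family_tests(fam, n, label=ACTIVE):
    members = sorted(fam.member_kinase_ids)[:n]
    return [BinaryActivity("C1", k, label) for k in members]


class TestEligibility:
    @pytest.mark.parametrize("members,tested,expected", [
        (2, 1, False),    # floor of two kinases
        (2, 2, True),
        (3, 2, True),     # ceil(1.5) = 2
        (5, 2, False),    # ceil(2.5) = 3
        (46, 23, True),
    ])
    def test_half_membership_rule(self, members, tested, expected):
        fam = family(members)
        assert is_eligible(family_tests(fam, tested), fam) is expected

    def test_matches_brute_force_rule_on_all_small_cases(self):
        for m in range(1, 9):
            fam = family(m)
            for t in range(1, m + 1):
                expected = t >= max(math.ceil(m / 2), 2)
                assert is_eligible(family_tests(fam, t), fam) is expected

    def test_outside_family_kinases_rejected(self):
        fam = family(3)
        alien = [BinaryActivity("C1", "OTHER_K", ACTIVE)]
        with pytest.raises(ValueError):
            is_eligible(alien, fam)


class TestLabelPKFI:
    @pytest.mark.parametrize("labels,expected", [
        ([ACTIVE, ACTIVE, ACTIVE], ACTIVE),
        ([INACTIVE, INACTIVE], INACTIVE),
        ([ACTIVE, INACTIVE], MIXED),
    ])
    def test_unanimity_rule(self, labels, expected):
        tests = [BinaryActivity("C1", f"K{i}", lab)
                 for i, lab in enumerate(labels)]
        assert label_pkfi(tests) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            label_pkfi([])


def make_activities(spec):
    """spec: {cid: {kid: label}} -> BinaryActivity list."""
    return [BinaryActivity(cid, kid, lab)
            for cid, tests in spec.items() for kid, lab in tests.items()]


class TestBuildPKFISet:
    def setup_method(self):
        self.fam = family(3, "FAM")
        k = sorted(self.fam.member_kinase_ids)
        self.spec = {
            "pos1": {k[0]: ACTIVE, k[1]: ACTIVE},
            "pos2": {k[0]: ACTIVE, k[1]: ACTIVE, k[2]: ACTIVE},
            "neg1": {k[1]: INACTIVE, k[2]: INACTIVE},
            "mix1": {k[0]: ACTIVE, k[1]: INACTIVE},
            "inel": {k[0]: ACTIVE},  # only one member tested
        }

    def test_partition_of_compounds(self):
        s = build_pkfi_set(make_activities(self.spec), self.fam)
        assert s.positives == {"pos1", "pos2"}
        assert s.negatives == {"neg1"}
        assert s.positives & s.negatives == set()
        # every compound is accounted for: pos + neg + mixed + ineligible
        assert len(s.positives) + len(s.negatives) + 2 == len(self.spec)

    def test_balance(self):
        s = build_pkfi_set(make_activities(self.spec), self.fam)
        assert s.balance == len(s.positives) / len(s.negatives)
        assert balance_ratio(51, 396) == 51 / 396

    def test_record_order_invariance(self):
        acts = make_activities(self.spec)
        shuffled = acts[:]
        random.Random(3).shuffle(shuffled)
        a = build_pkfi_set(acts, self.fam)
        b = build_pkfi_set(shuffled, self.fam)
        assert (a.positives, a.negatives) == (b.positives, b.negatives)

    def test_no_negatives_flagged(self):
        spec = {"pos1": self.spec["pos1"]}
        s = build_pkfi_set(make_activities(spec), self.fam)
        assert np.isnan(s.balance)
        assert s.balance_flag

    def test_all_undertested_gives_empty_set(self):
        spec = {f"c{i}": {sorted(self.fam.member_kinase_ids)[0]: ACTIVE}
                for i in range(5)}
        s = build_pkfi_set(make_activities(spec), self.fam)
        assert not s.positives and not s.negatives

    def test_oversize_compound_dropped_when_structure_known(self):
        acts = make_activities(self.spec)
        structures = {"pos1": "C" * 60, "pos2": "CCO", "neg1": "CCO"}
        s = build_pkfi_set(acts, self.fam, structures=structures)
        assert "pos1" not in s.positives and "pos2" in s.positives


class TestConsensusCalls:
    def test_voting_applied_per_pair(self):
        records = [rec(value=10, cid="C1", kid="K1"),
                   rec(value=9000, cid="C1", kid="K1"),     # 50/50: excluded
                   rec(value=10, cid="C2", kid="K1"),
                   rec(value=20, cid="C2", kid="K1")]
        calls = consensus_calls(records)
        assert [(c.compound_id, c.label) for c in calls] == [("C2", ACTIVE)]

    def test_invariant_to_record_order(self):
        records = [rec(value=v, cid=c, kid=k)
                   for c in ("C1", "C2") for k in ("K1", "K2")
                   for v in (10, 20, 9000)]
        a = consensus_calls(records)
        b = consensus_calls(list(reversed(records)))
        assert a == b


class TestSplitSet:
    def make_set(self, n_pos, n_neg):
        return PKFISet("F", {f"p{i}" for i in range(n_pos)},
                       {f"n{i}" for i in range(n_neg)})

    def test_exact_stratification(self):
        split = split_set(self.make_set(100, 100), 0.8, seed=0)
        train_labels = [lab for _, lab in split.train]
        assert len(split.train) == 160 and len(split.test) == 40
        assert train_labels.count(ACTIVE) == 80

    def test_deterministic_given_seed(self):
        s = self.make_set(50, 80)
        a, b = split_set(s, 0.8, seed=4), split_set(s, 0.8, seed=4)
        assert a.train == b.train and a.test == b.test
        c = split_set(s, 0.8, seed=5)
        assert c.train != a.train

    def test_published_sized_set_bookkeeping(self):
        split = split_set(self.make_set(620, 808), 0.8, seed=0)
        assert abs(len(split.train) - 1142) <= 1
        assert len(split.train) + len(split.test) == 1428

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            split_set(self.make_set(1, 50), 0.8, seed=0)

    def test_no_leakage(self):
        split = split_set(self.make_set(30, 40), 0.8, seed=1)
        assert not {c for c, _ in split.train} & {c for c, _ in split.test}
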