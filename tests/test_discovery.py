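"""Combination discovery: grouping rule, oracle equivalence, flags."""

import random

import pytest

from combokg.claims import Claim
from combokg.discovery import (
    CandidateGroup,
    count_patterns,
    discover_combinations,
    flag_comparisons,
    pattern_label,
    read_candidates_tsv,
    summarize_groups,
    write_candidates_tsv,
)
from combokg.predications import Predication, PredicationSet, TypeConfig
from tests.test_predications import make_pred

DRUG_TYPES = frozenset({"phsu"})
DISEASE_TYPES = frozenset({"neop"})


# ---------------------------------------------------------------------------
# independent oracle: exhaustive subset enumeration with re-stated rules
# ---------------------------------------------------------------------------

def oracle_groups(preds, exclude_negated=True):
    """Brute force: enumerate every subset of the predication list, keep
    the maximal ones whose members all pass the eligibility clauses and
    share one (base predicate, object CUI) key with >=2 distinct
    subjects.  The filter clauses are restated here, independent of the
    implementation under test."""
    def eligible(p):
        base = p.predicate_raw
        negated = base.startswith("NEG_")
        if negated:
            base = base[4:]
        if base.endswith("(INFER)"):
            base = base[:-7]
        return (
            base in {"TREATS", "INHIBITS", "PREVENTS", "DISRUPTS"}
            and p.subject_semtypes & DRUG_TYPES
            and p.object_semtypes & DISEASE_TYPES
            and not (exclude_negated and negated)
        )

    def base_key(p):
        base = p.predicate_raw
        if base.startswith("NEG_"):
            base = base[4:]
        if base.endswith("(INFER)"):
            base = base[:-7]
        return (base, p.object_cui)

    pool = [p for p in preds if eligible(p)]
    n = len(pool)
    found = set()
    for mask in range(1, 2 ** n):
        subset = [pool[i] for i in range(n) if mask >> i & 1]
        keys = {base_key(p) for p in subset}
        if len(keys) != 1:
            continue
        key = next(iter(keys))
        # maximality: nothing eligible outside the subset shares the key
        if any(base_key(pool[i]) == key
               for i in range(n) if not mask >> i & 1):
            continue
        cuis = frozenset(p.subject_cui for p in subset)
        if len(cuis) >= 2:
            found.add((key[0], key[1], cuis))
    return found


def random_predication_set(rng, sid="1.ab.1", max_preds=6):
    subjects = [("S1", "drugA"), ("S2", "drugB"), ("S3", "drugC")]
    objects = [("O1", "disease1"), ("O2", "disease2"), ("P1", "Patients")]
    predicates = ["TREATS", "TREATS(INFER)", "NEG_TREATS", "INHIBITS",
                  "PROCESS_OF", "COMPARED_WITH"]
    preds = []
    for _ in range(rng.randint(1, max_preds)):
        s_cui, s_name = rng.choice(subjects)
        o_cui, o_name = rng.choice(objects)
        preds.append(Predication(
            pmid="1", sentence_id=sid,
            subject_cui=s_cui, subject_name=s_name,
            subject_semtypes=(
                DRUG_TYPES if rng.random() < 0.8 else frozenset({"topp"})
            ),
            predicate_raw=rng.choice(predicates),
            object_cui=o_cui, object_name=o_name,
            object_semtypes=(
                DISEASE_TYPES if o_cui.startswith("O") else frozenset({"podg"})
            ),
        ))
    return PredicationSet(sentence_id=sid, predications=preds)


def as_key_set(groups):
    return {
        (g.predicate_base, g.object_cui, g.subject_cuis) for g in groups
    }


CFG = TypeConfig(drug_semtypes=DRUG_TYPES, disease_semtypes=DISEASE_TYPES)


def run_oracle_comparison(n_trials, seed=20251001):
    rng = random.Random(seed)
    claim_text = "In conclusion, the tested combination was feasible."
    for _ in range(n_trials):
        pset = random_predication_set(rng)
        claim = Claim(pmid="1", sentence_index=1, text=claim_text)
        groups = discover_combinations(claim, pset, CFG)
        assert as_key_set(groups) == oracle_groups(pset.predications)


class TestDiscoverCombinations:
    def test_worked_example_single_group(self, gti_claim, gti_pset):
        groups = discover_combinations(gti_claim, gti_pset)
        assert len(groups) == 1
        g = groups[0]
        assert g.predicate_base == "TREATS"
        assert g.object_name == "Advanced Malignant Solid Neoplasm"
        assert {name for _, name in g.subjects} == {
            "GTI2040", "capecitabine", "oxaliplatin"
        }
        assert g.any_inferred
        assert g.source_predication_count == 3
        assert "combin*" in g.markers

    def test_single_predication_no_group(self):
        claim = Claim(pmid="1", sentence_index=1, text="In conclusion, x.")
        pset = PredicationSet("1.ab.1", [make_pred()])
        assert discover_combinations(claim, pset) == []

    def test_same_subject_different_objects_no_group(self):
        claim = Claim(pmid="1", sentence_index=1, text="In conclusion, x.")
        pset = PredicationSet("1.ab.1", [
            make_pred(o_cui="O1"), make_pred(o_cui="O2"),
        ])
        assert discover_combinations(claim, pset) == []

    def test_multiple_therapy_claim_surfaces_as_one_group(self):
        # "X plus either Y or Z" pattern: all three share the key, so a
        # single 3-drug group is emitted (flagged, never disambiguated)
        text = ("CONCLUSION: Custirsen plus either docetaxel or "
                "mitoxantrone was feasible in patients with mCRPC.")
        claim = Claim(pmid="2", sentence_index=1, text=text)
        preds = [
            make_pred(subject=n, s_cui=f"S{i}", obj="prostate cancer",
                      o_cui="O1", sid="2.ab.1")
            for i, n in enumerate(["Custirsen", "docetaxel", "Mitoxantrone"])
        ]
        pset = PredicationSet("2.ab.1", preds)
        groups = discover_combinations(claim, pset)
        assert len(groups) == 1
        assert groups[0].n_subjects == 3

    def test_sentence_id_mismatch_rejected(self, gti_pset):
        claim = Claim(pmid="999", sentence_index=1, text="In conclusion, x.")
        with pytest.raises(ValueError, match="does not belong"):
            discover_combinations(claim, gti_pset)

    def test_output_invariant_under_permutation(self, gti_claim, gti_pset):
        reversed_pset = PredicationSet(
            gti_pset.sentence_id, list(reversed(gti_pset.predications))
        )
        assert discover_combinations(gti_claim, reversed_pset) == \
            discover_combinations(gti_claim, gti_pset)

    def test_subjects_deduplicated_by_cui(self):
        claim = Claim(pmid="1", sentence_index=1, text="In conclusion, x.")
        pset = PredicationSet("1.ab.1", [
            make_pred(s_cui="S1"), make_pred(s_cui="S1", predicate="TREATS(INFER)"),
            make_pred(s_cui="S2"),
        ])
        groups = discover_combinations(claim, pset)
        assert len(groups) == 1
        assert groups[0].n_subjects == 2

    def test_oracle_equivalence_sample(self):
        run_oracle_comparison(n_trials=300)


class TestFlagComparisons:
    def make_group(self, cuis=("S1", "S2")):
        return CandidateGroup(
            sentence_id="1.ab.1", claim_text="c", predicate_base="TREATS",
            object_cui="O1", object_name="d",
            subjects=tuple((c, c.lower()) for c in cuis),
        )

    def pset_with(self, extra):
        preds = [make_pred(s_cui="S1"), make_pred(s_cui="S2")] + extra
        return PredicationSet("1.ab.1", preds)

    def test_compared_pair_inside_group_flags(self):
        cmp_pred = make_pred(s_cui="S1", predicate="COMPARED_WITH",
                             o_cui="S2", o_types=("phsu",))
        assert flag_comparisons(self.make_group(), self.pset_with([cmp_pred]))

    def test_no_comparison_no_flag(self):
        assert not flag_comparisons(self.make_group(), self.pset_with([]))

    def test_comparison_with_outsider_not_flagged(self):
        cmp_pred = make_pred(s_cui="S1", predicate="COMPARED_WITH",
                             o_cui="S9", o_types=("phsu",))
        assert not flag_comparisons(
            self.make_group(), self.pset_with([cmp_pred])
        )

    def test_discover_sets_flag(self):
        text = ("CONCLUSION: Both pemetrexed and erlotinib had comparable "
                "efficacy in patients with metastatic NSCLC.")
        claim = Claim(pmid="3", sentence_index=1, text=text)
        preds = [
            make_pred(subject="pemetrexed", s_cui="S1", sid="3.ab.1"),
            make_pred(subject="erlotinib", s_cui="S2", sid="3.ab.1"),
            make_pred(subject="pemetrexed", s_cui="S1",
                      predicate="COMPARED_WITH", obj="erlotinib",
                      o_cui="S2", o_types=("phsu",), sid="3.ab.1"),
        ]
        groups = discover_combinations(
            claim, PredicationSet("3.ab.1", preds)
        )
        assert len(groups) == 1
        assert groups[0].comparison_flag
        assert groups[0].markers == frozenset()


class TestSummaries:
    def group(self, n, sid="1.ab.1", markers=(), flag=False):
        return CandidateGroup(
            sentence_id=sid, claim_text="c", predicate_base="TREATS",
            object_cui="O1", object_name="d",
            subjects=tuple((f"S{i}", f"s{i}") for i in range(n)),
            markers=frozenset(markers), comparison_flag=flag,
        )

    def test_size_counts(self):
        table = summarize_groups([
            self.group(3, "1.ab.1"), self.group(2, "2.ab.1"),
            self.group(2, "3.ab.1"),
        ])
        assert table["by_size"] == {2: 2, 3: 1}
        assert table["n_groups"] == 3

    def test_empty_input(self):
        table = summarize_groups([])
        assert table["n_groups"] == 0
        assert table["by_size"] == {}
        assert table["markers"] == {}

    def test_regimen_counted_only_without_other_markers(self):
        table = summarize_groups([
            self.group(2, "1.ab.1", markers={"regimen"}),
            self.group(2, "2.ab.1", markers={"regimen", "combin*"}),
        ])
        assert table["markers"] == {"combin*": 1, "regimen": 1}

    def test_marker_tabulation_is_per_claim(self):
        # two groups from one claim count its markers once
        table = summarize_groups([
            self.group(2, "1.ab.1", markers={"combin*"}),
            CandidateGroup(
                sentence_id="1.ab.1", claim_text="c",
                predicate_base="TREATS", object_cui="O2", object_name="d2",
                subjects=(("S1", "s1"), ("S2", "s2")),
                markers=frozenset({"combin*"}),
            ),
        ])
        assert table["markers"] == {"combin*": 1}
        assert table["n_claims"] == 1


class TestPatterns:
    def test_pattern_counting(self):
        groups = [
            TestSummaries().group(2),
            CandidateGroup(
                sentence_id="2.ab.1", claim_text="c",
                predicate_base="TREATS", object_cui="O1", object_name="d",
                subjects=(("T1", "ta"), ("S0", "s0"), ("S1", "s1")),
            ),
        ]
        class_map = {"S0": "Cytotoxic", "S1": "Cytotoxic", "T1": "Targeted"}
        counts = count_patterns(groups, class_map)
        assert counts["Cytotoxic + Cytotoxic"] == 1
        assert counts["Targeted + Cytotoxic + Cytotoxic"] == 1

    def test_unmapped_drug_is_other(self):
        counts = count_patterns(
            [TestSummaries().group(2)], {"S0": "Cytotoxic"}
        )
        assert counts == {"Cytotoxic + Other": 1}

    def test_label_is_order_insensitive(self):
        assert pattern_label(["Cytotoxic", "Targeted", "Cytotoxic"]) == \
            pattern_label(["Targeted", "Cytotoxic", "Cytotoxic"]) == \
            "Targeted + Cytotoxic + Cytotoxic"

    def test_class_map_matches_by_name_too(self):
        counts = count_patterns(
            [TestSummaries().group(2)], {"s0": "Targeted", "s1": "Targeted"}
        )
        assert counts == {"Targeted + Targeted": 1}


class TestCandidateIO:
    def test_tsv_round_trip(self, tmp_path, gti_claim, gti_pset):
        groups = discover_combinations(gti_claim, gti_pset)
        path = tmp_path / "candidates.tsv"
        write_candidates_tsv(groups, path)
        restored = read_candidates_tsv(path)
        assert len(restored) == 1
        g0, g1 = groups[0], restored[0]
        assert (g1.subjects, g1.predicate_base, g1.object_cui,
                g1.markers, g1.any_inferred) == \
               (g0.subjects, g0.predicate_base, g0.object_cui,
                g0.markers, g0.any_inferred)
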