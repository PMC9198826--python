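"""Quality-control filtering and chronological tokenization."""

import math

import pytest
from hypothesis import given, strategies as st

from tcmrec.features import (ClinicalFact, Order, PatientRecord, extract_tokens,
                             fact_tokens, parse_cutoff, qc_filter,
                             read_records_jsonl, write_records_jsonl)
from tcmrec.synth import corrupt_records


def make_record(**kw):
    base = dict(
        patient_id="p1",
        demographics={"sex": "female", "age": 52, "height": 160,
                      "weight": 55, "bmi": 21.5},
        facts=[
            ClinicalFact(0.0, "chief_complaints", "fatigue"),
            ClinicalFact(0.0, "body_check", "temperature", "normal", "celsius"),
            ClinicalFact(30.0, "laboratory_reports", "glucose", "high", "mmolperl"),
        ],
        orders=[Order(0.0, ["leaf_000_01"]), Order(24.0, ["leaf_001_00"])],
    )
    base.update(kw)
    return PatientRecord(**base)


class TestQcFilter:
    def test_clean_cohort_all_kept(self, small_cohort):
        _, _, records = small_cohort
        kept, discarded = qc_filter(records)
        assert len(kept) == len(records) and not discarded

    def test_missing_demographics_discarded_as_incomplete(self):
        kept, discarded = qc_filter([make_record(demographics=None)])
        assert not kept
        assert discarded[0][1] == "incomplete"

    def test_no_admission_facts_is_incomplete(self):
        r = make_record(facts=[ClinicalFact(5.0, "nursing_notes", "heart_rate",
                                            "normal", "bpm")])
        assert qc_filter([r])[1][0][1] == "incomplete"

    def test_inconsistent_duplicate_discarded(self):
        r = make_record()
        r.facts.append(ClinicalFact(0.0, "body_check", "temperature", "high",
                                    "celsius"))
        assert qc_filter([r])[1][0][1] == "inconsistent"

    def test_nonstandard_description_discarded(self):
        r = make_record()
        r.facts.append(ClinicalFact(1.0, "treatment_process", "Freitext@Befund"))
        assert qc_filter([r])[1][0][1] == "nonstandard"

    def test_special_circumstance_discarded(self):
        r = make_record()
        r.facts.append(ClinicalFact(0.0, "treatment_process",
                                    "special_circumstance", "chemotherapy"))
        assert qc_filter([r])[1][0][1] == "special_circumstance"

    def test_idempotent(self, small_cohort):
        cfg, _, records = small_cohort
        corrupted = corrupt_records(records, cfg.with_(qc_corrupt_frac=0.5))
        kept, _ = qc_filter(corrupted)
        kept2, discarded2 = qc_filter(kept)
        assert kept2 == kept and not discarded2


class TestExtractTokens:
    def test_truncation_at_cutoff(self):
        seq = extract_tokens(make_record(), cutoff_hours=24.0)
        assert all(t <= 24.0 for t in seq.t_hours)
        assert "glucose" not in seq.tokens  # the t=30h lab

    def test_full_token_count(self):
        r = make_record()
        seq = extract_tokens(r, cutoff_hours=math.inf)
        n_demo = 5
        n_fact = sum(len(fact_tokens(f)) for f in r.facts)
        n_order = sum(len(o.drug_ids) for o in r.orders)  # both before inf
        assert len(seq) == n_demo + n_fact + n_order

    def test_demographics_lead_the_sequence(self):
        seq = extract_tokens(make_record(), cutoff_hours=0.0)
        assert seq.tokens[0] == "sex_female"
        assert seq.tokens[1] == "age_50s"

    def test_simultaneous_facts_follow_section_order(self):
        r = make_record(facts=[
            ClinicalFact(0.0, "laboratory_reports", "glucose", "high", "mmolperl"),
            ClinicalFact(0.0, "chief_complaints", "fatigue"),
            ClinicalFact(0.0, "body_check", "temperature", "normal", "celsius"),
        ], orders=[])
        seq = extract_tokens(r, cutoff_hours=0.0)
        toks = seq.tokens[5:]  # skip demographics
        assert toks.index("fatigue") < toks.index("temperature") < toks.index("glucose")

    def test_current_order_excluded_prior_orders_included(self):
        r = make_record()
        seq0 = extract_tokens(r, cutoff_hours=0.0)
        assert not any(t.startswith("taken:") for t in seq0.tokens)
        seq24 = extract_tokens(r, cutoff_hours=24.0)
        assert "taken:leaf_000_01" in seq24.tokens
        assert "taken:leaf_001_00" not in seq24.tokens  # the order being predicted

    def test_prior_orders_can_be_disabled(self):
        seq = extract_tokens(make_record(), 24.0, include_prior_orders=False)
        assert not any(t.startswith("taken:") for t in seq.tokens)

    def test_unknown_section_rejected(self):
        with pytest.raises(ValueError, match="section"):
            ClinicalFact(0.0, "astrology", "sign")

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            extract_tokens(make_record(), -1.0)

    @given(st.lists(st.sampled_from([0.0, 1.5, 24.0, 48.0, 100.0]),
                    min_size=2, max_size=2, unique=True).map(sorted))
    def test_earlier_cutoff_is_prefix_of_later(self, small_cohort, cutoffs):
        c1, c2 = cutoffs
        for r in small_cohort[2][:5]:
            s1 = extract_tokens(r, c1)
            s2 = extract_tokens(r, c2)
            assert s2.tokens[: len(s1)] == s1.tokens
            assert s2.t_hours[: len(s1)] == s1.t_hours


class TestRecordIO:
    def test_jsonl_roundtrip(self, small_cohort, tmp_path):
        _, _, records = small_cohort
        path = tmp_path / "r.jsonl"
        write_records_jsonl(records[:10], path)
        again = list(read_records_jsonl(path))
        assert again == records[:10]


@pytest.mark.parametrize("text,hours", [
    ("admission", 0.0), ("24h", 24.0), ("48h", 48.0), ("72h", 72.0),
    ("168h", 168.0), ("36", 36.0), ("12.5h", 12.5),
])
def test_parse_cutoff(text, hours):
    assert parse_cutoff(text) == hours
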