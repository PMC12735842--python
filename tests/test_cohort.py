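"""Deduplication, eligibility exclusions and case/exposure classification."""

from __future__ import annotations

import datetime
import json

import pytest

from pvsignal import (
    DrugEntry,
    GeneratorConfig,
    MedicalHistoryEntry,
    PartialDate,
    Role,
    apply_exclusions,
    build_cohort,
    classify,
    deduplicate,
    generate_frame,
    generate_cohort,
)
from conftest import make_report


class TestDeduplicate:
    def test_distinct_ids_unchanged(self, small_reports):
        kept, log = deduplicate(small_reports)
        assert kept == small_reports
        assert log.counts["duplicate"] == 0

    def test_earliest_complete_receipt_wins(self):
        late = make_report("X", receipt="2021-01-01", country="JP")
        early = make_report("X", receipt="2020-01-01", country="ES")
        kept, log = deduplicate([late, early])
        assert kept == [early]
        assert log.counts["duplicate"] == 1
        assert log.excluded_ids["duplicate"] == ["X"]

    def test_incomplete_receipt_loses_to_complete(self):
        partial = make_report("X", receipt="2019")
        complete = make_report("X", receipt="2021-05-01")
        kept, _ = deduplicate([partial, complete])
        assert kept == [complete]

    def test_two_duplicate_pairs_leave_three(self):
        reports = [
            make_report("A", receipt="2020-01-01"),
            make_report("B", receipt="2020-02-01"),
            make_report("A", receipt="2020-03-01"),
            make_report("C", receipt="2020-04-01"),
            make_report("B", receipt="2020-05-01"),
        ]
        kept, log = deduplicate(reports)
        assert [r.registration_id for r in kept] == ["A", "B", "C"]
        assert log.counts["duplicate"] == 2

    def test_idempotent(self, small_reports):
        once, _ = deduplicate(small_reports + [small_reports[0]])
        twice, log = deduplicate(once)
        assert twice == once and log.counts["duplicate"] == 0


class TestExclusions:
    def test_multi_gliptin_excluded(self, design):
        r = make_report(
            "M", drug="sitagliptin",
            extra_drugs=[DrugEntry(substance="vildagliptin", role=Role.suspect)],
        )
        kept, log = apply_exclusions([r], design)
        assert kept == [] and log.counts["multi_gliptin"] == 1

    def test_concomitant_second_gliptin_is_not_multi_exposure(self, design):
        r = make_report(
            "M", drug="sitagliptin",
            extra_drugs=[DrugEntry(substance="vildagliptin", role=Role.concomitant)],
        )
        kept, _ = apply_exclusions([r], design)
        assert kept == [r]

    def test_gliptin_plus_antihyperglycemic_excluded(self, design):
        r = make_report(
            "C", drug="vildagliptin",
            extra_drugs=[DrugEntry(substance="metformin", role=Role.concomitant)],
        )
        kept, log = apply_exclusions([r], design)
        assert kept == [] and log.counts["gliptin_plus_antihyperglycemic"] == 1

    def test_prior_event_history_excluded(self, design):
        r = make_report(
            "P", onset=PartialDate(2020, 3),
            history=[MedicalHistoryEntry("Pemphigoid", 2015)],
        )
        kept, log = apply_exclusions([r], design)
        assert kept == [] and log.counts["prior_bp_history"] == 1

    def test_history_after_onset_is_kept(self, design):
        r = make_report(
            "P", onset=PartialDate(2020, 3),
            history=[MedicalHistoryEntry("Pemphigoid", 2020)],
        )
        kept, _ = apply_exclusions([r], design)
        assert kept == [r]

    def test_outside_window_excluded(self, design):
        r = make_report("W", receipt="2006-12-01")
        kept, log = apply_exclusions([r], design)
        assert kept == [] and log.counts["outside_window"] == 1

    def test_one_report_may_trip_several_reasons(self, design):
        r = make_report(
            "Z", receipt="2025-01-01", drug="sitagliptin",
            extra_drugs=[DrugEntry(substance="vildagliptin", role=Role.suspect)],
        )
        kept, log = apply_exclusions([r], design)
        assert kept == []
        assert log.counts["outside_window"] == 1 and log.counts["multi_gliptin"] == 1
        assert log.n_removed == 1
        assert sum(log.counts.values()) >= log.n_removed

    def test_idempotent(self, design, small_reports):
        once, _ = apply_exclusions(small_reports, design)
        twice, log = apply_exclusions(once, design)
        assert twice == once and sum(log.counts.values()) == 0

    def test_log_serializes_to_json(self, design):
        _, log = apply_exclusions([make_report("W", receipt="2025-06-01")], design)
        payload = json.loads(log.to_json())
        assert payload["counts"]["outside_window"] == 1
        assert payload["excluded_ids"]["outside_window"] == ["W"]


class TestClassify:
    def test_case_exposed(self, design):
        [cr] = classify([make_report("A", drug="vildagliptin")], design)
        assert (cr.is_case, cr.exposed, cr.exposure_drug) == (True, True, "vildagliptin")

    def test_control_unexposed(self, design):
        [cr] = classify([make_report("B", drug="paracetamol", reaction="Nausea")], design)
        assert (cr.is_case, cr.exposed, cr.exposure_drug) == (False, False, None)

    def test_event_term_matching_is_case_insensitive(self, design):
        [cr] = classify([make_report("A", reaction="PEMPHIGOID")], design)
        assert cr.is_case

    def test_concomitant_gliptin_does_not_create_exposure(self, design):
        r = make_report("A", drug="omeprazole",
                        extra_drugs=[DrugEntry("sitagliptin", Role.concomitant)])
        [cr] = classify([r], design)
        assert not cr.exposed

    def test_unfiltered_multi_exposure_raises(self, design):
        r = make_report(
            "M", drug="sitagliptin",
            extra_drugs=[DrugEntry(substance="vildagliptin", role=Role.suspect)],
        )
        with pytest.raises(ValueError, match="apply_exclusions"):
            classify([r], design)

    def test_partition_is_total(self, design, small_reports):
        classified = classify(small_reports, design)
        strata = [
            sum(1 for c in classified if c.is_case and c.exposed),
            sum(1 for c in classified if c.is_case and not c.exposed),
            sum(1 for c in classified if not c.is_case and c.exposed),
            sum(1 for c in classified if not c.is_case and not c.exposed),
        ]
        assert sum(strata) == len(classified) == 4
        assert strata == [1, 1, 1, 1]


def test_pipeline_counts_match_generator_bookkeeping(design):
    """Cohort composition after the full pipeline equals what the generator
    injected, reconstructed from its bookkeeping columns."""
    cfg = GeneratorConfig(
        n_reports=2000, seed=11,
        drug_exposure_probs={"vildagliptin": 0.15, "sitagliptin": 0.1},
        baseline_event_prob=0.02,
        target_ror={"vildagliptin": 20.0, "sitagliptin": 5.0},
    )
    frame = generate_frame(cfg)
    classified, log = build_cohort(generate_cohort(cfg), design)

    assert log.counts["duplicate"] == int(frame["is_duplicate"].sum())
    base = frame[~frame.is_duplicate]
    window = (
        base.receipt_ord >= datetime.date(2007, 4, 1).toordinal()
    ) & (base.receipt_ord <= datetime.date(2024, 4, 30).toordinal())
    removed = (
        ~window
        | (base.second_gliptin != "")
        | base.combo_antihyperglycemic
        | base.prior_bp_history
    )
    survivors = base[~removed]
    assert len(classified) == len(survivors)
    assert sum(c.is_case for c in classified) == int(survivors.is_case.sum())
    assert (
        sum(c.exposed for c in classified)
        == int(survivors.is_gliptin.sum())
    )
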