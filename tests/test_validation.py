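"""Truth concordance, window grids, window optimization, cohort yields."""

import random

import pandas as pd
import pytest

from ppglval.afr import AfrWindow, alt_fraction
from ppglval.cascade import run_cascade
from ppglval.models import (
    InvalidRecordError,
    PpglValError,
    TruthRecord,
    TruthStatus,
    VariantCall,
)
from ppglval.validation import (
    compare_to_truth,
    count_novel,
    diagnostic_yield,
    optimize_window,
    window_grid,
)


def make_call(sample, pos, ref_reads=25, alt_reads=25, ref="A", alt="G"):
    return VariantCall(
        sample_id=sample, chrom="chr1", pos=pos, ref_allele=ref, alt_allele=alt,
        ref_reads=ref_reads, alt_reads=alt_reads,
    )


def make_truth(sample, pos, ref="A", alt="G"):
    return TruthRecord(
        sample_id=sample, chrom="chr1", pos=pos, ref_allele=ref, alt_allele=alt,
        status=TruthStatus.VARIANT_PRESENT,
    )


def brute_force_confusion(calls, truth, universe=None):
    """Independent double-loop oracle for per-variant confusion counts."""
    truth_present = [t for t in truth if t.status is TruthStatus.VARIANT_PRESENT]
    tp = fn = 0
    for t in truth_present:
        if any(c.locus_key() == t.locus_key() for c in calls):
            tp += 1
        else:
            fn += 1
    fp = sum(
        1
        for c in calls
        if not any(c.locus_key() == t.locus_key() for t in truth_present)
    )
    tn = 0
    for u in universe or []:
        is_truth = any(u.locus_key() == t.locus_key() for t in truth_present)
        survived = any(u.locus_key() == c.locus_key() for c in calls)
        if not is_truth and not survived:
            tn += 1
    return tp, fp, fn, tn


class TestCompareToTruth:
    def test_all_wes_mutations_detected_without_window(self, wes_fixture):
        summary = compare_to_truth(wes_fixture.calls, wes_fixture.truth)
        assert (summary.tp, summary.fn) == (13, 0)
        assert summary.sensitivity == 100.0

    def test_missed_variant_counts_as_false_negative(self):
        truth = [make_truth("S1", 100)]
        summary = compare_to_truth([], truth)
        assert (summary.fn, summary.sensitivity) == (1, 0.0)

    def test_duplicate_truth_records_rejected(self):
        truth = [make_truth("S1", 100), make_truth("S1", 100)]
        with pytest.raises(InvalidRecordError):
            compare_to_truth([], truth)

    def test_indel_representations_match_after_normalization(self):
        # an anchored deletion written with a trailing context base matches
        # its minimal representation after suffix/prefix trimming
        call = make_call("S1", 100, ref="CTT", alt="CT")
        truth = [make_truth("S1", 100, ref="CT", alt="C")]
        summary = compare_to_truth([call], truth)
        assert (summary.tp, summary.fp) == (1, 0)

    def test_per_position_mode_counts_wildtype_bases(self):
        truth = [
            make_truth("S1", 100),
            TruthRecord(
                sample_id="S1", chrom="chr1", pos=200, status="wildtype_confirmed",
                region_span=(200, 299),
            ),
        ]
        calls = [make_call("S1", 100), make_call("S1", 250)]  # 1 TP + 1 FP in span
        summary = compare_to_truth(calls, truth, mode="per_position")
        assert summary.tn == 100 - 1
        assert (summary.tp, summary.fp) == (1, 1)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = random.Random(11)
        for trial in range(20):
            n_truth = rng.randint(0, 12)
            truth = []
            used = set()
            for _ in range(n_truth):
                key = (f"S{rng.randint(1, 4)}", rng.randint(1, 30))
                if key in used:
                    continue
                used.add(key)
                truth.append(make_truth(*key))
            calls = [
                make_call(f"S{rng.randint(1, 4)}", rng.randint(1, 30))
                for _ in range(rng.randint(0, 30))
            ]
            # "surviving" = a random subset; remainder forms the universe
            survivors = [c for c in calls if rng.random() < 0.6]
            summary = compare_to_truth(survivors, truth, universe=calls)
            tp, fp, fn, tn = brute_force_confusion(survivors, truth, universe=calls)
            assert (summary.tp, summary.fp, summary.fn, summary.tn) == (tp, fp, fn, tn)


class TestWindowGrid:
    def test_cg_standard_window_has_exactly_one_false_negative(self, wes_fixture):
        rows = window_grid(
            wes_fixture.calls_by_platform(), wes_fixture.truth, [AfrWindow(30, 70)]
        )
        cg = next(r for r in rows if r.platform == "bgi_complete_genomics")
        assert cg.false_negative == 1  # the 24/9 call at fraction 0.27
        assert cg.detected == 7

    def test_vacuous_window_misses_nothing(self, wes_fixture):
        rows = window_grid(
            wes_fixture.calls_by_platform(), wes_fixture.truth, [AfrWindow(0, 100)]
        )
        assert all(r.false_negative == 0 for r in rows)

    def test_cg_narrow_window_misses_five_of_eight(self, wes_fixture):
        rows = window_grid(
            wes_fixture.calls_by_platform(), wes_fixture.truth,
            [AfrWindow(41.1, 58.8)],
        )
        cg = next(r for r in rows if r.platform == "bgi_complete_genomics")
        assert (cg.true_variants, cg.false_negative) == (8, 5)

    def test_sensitivity_monotone_under_window_narrowing(self, wes_fixture):
        """Nested windows give nested detected sets, so sensitivity cannot
        increase as the window narrows."""
        windows = [
            AfrWindow(50 - d, 50 + d) for d in (50, 25, 20, 15, 10, 5, 2, 0)
        ]
        rows = window_grid(wes_fixture.calls_by_platform(), wes_fixture.truth, windows)
        for platform in wes_fixture.calls_by_platform():
            sens = [r.sensitivity for r in rows if r.platform == platform]
            assert sens == sorted(sens, reverse=True)

    def test_monotonicity_on_random_fixture(self):
        rng = random.Random(3)
        calls, truth = [], []
        for i in range(30):
            depth = rng.randint(20, 120)
            alt = rng.randint(1, depth - 1)
            calls.append(make_call(f"S{i}", 100 + i, depth - alt, alt))
            truth.append(make_truth(f"S{i}", 100 + i))
        windows = [AfrWindow(50 - d, 50 + d) for d in range(50, -1, -5)]
        rows = window_grid({"sim": calls}, truth, windows)
        sens = [r.sensitivity for r in rows]
        assert sens == sorted(sens, reverse=True)

    def test_requires_at_least_one_window(self, wes_fixture):
        with pytest.raises(PpglValError):
            window_grid(wes_fixture.calls_by_platform(), wes_fixture.truth, [])


class TestOptimizeWindow:
    def test_agilent_window(self, wes_fixture):
        byp = wes_fixture.calls_by_platform()
        w = optimize_window(byp["agilent_sureselect"], wes_fixture.truth)
        assert (w.lower_pct, w.upper_pct) == (44.8, 55.2)

    def test_complete_genomics_window(self, wes_fixture):
        byp = wes_fixture.calls_by_platform()
        w = optimize_window(
            byp["bgi_complete_genomics"], wes_fixture.truth, rounding="integer"
        )
        assert (w.lower_pct, w.upper_pct) == (27.0, 73.0)

    def test_single_balanced_call(self):
        calls = [make_call("S1", 100, 30, 30)]
        truth = [make_truth("S1", 100)]
        w = optimize_window(calls, truth)
        assert (w.lower_pct, w.upper_pct) == (50.0, 50.0)

    def test_optimized_window_restores_full_sensitivity(self, wes_fixture):
        """At the optimized window sensitivity is 100%; one rounding step
        narrower it drops below 100%."""
        byp = wes_fixture.calls_by_platform()
        for platform, calls in byp.items():
            w = optimize_window(calls, wes_fixture.truth)
            rows = window_grid({platform: calls}, wes_fixture.truth, [w])
            assert rows[0].sensitivity == 100.0
            if w.lower_pct < w.upper_pct:
                narrower = AfrWindow(w.lower_pct + 0.1, w.upper_pct - 0.1)
                rows = window_grid({platform: calls}, wes_fixture.truth, [narrower])
                assert rows[0].sensitivity < 100.0


class TestDiagnosticYield:
    def test_v2_prospective_cohort(self, cohorts):
        summary = diagnostic_yield(cohorts.cohort("EP2.0"), "EP2.0")
        assert (summary.n_tested, summary.n_carriers) == (37, 10)
        assert round(summary.yield_pct) == 27

    def test_v1_prospective_gene_based_counting(self, cohorts):
        summary = diagnostic_yield(
            cohorts.cohort("EP1.0P"), "EP1.0P", mode="any_variant",
            genes=["SDHB", "NF1"],
        )
        assert (summary.n_tested, summary.n_carriers) == (24, 9)
        assert summary.yield_pct == 37.5
        assert summary.per_gene == {"SDHB": 2, "NF1": 7}

    def test_v1_validation_cohort_carriers(self, cohorts):
        summary = diagnostic_yield(cohorts.cohort("EP1.0V"), "EP1.0V")
        assert (summary.n_tested, summary.n_carriers) == (15, 10)

    def test_per_gene_breakdown_of_v2(self, cohorts):
        summary = diagnostic_yield(cohorts.cohort("EP2.0"), "EP2.0")
        assert summary.per_gene == {"SDHB": 3, "FH": 2, "NF1": 4, "VHL": 1}

    def test_empty_cohort_is_an_error(self):
        empty = pd.DataFrame(columns=["patient_id", "gene", "hgvs", "clinical_class"])
        with pytest.raises(PpglValError):
            diagnostic_yield(empty)


class TestCountNovel:
    def test_all_novel_against_empty_index(self, cohorts):
        pairs = list(
            zip(cohorts.novel_variants["hgvs"], cohorts.novel_variants["clinical_class"])
        )
        novel, tally = count_novel(pairs, known_index=[])
        assert len(novel) == 8
        assert tally["likely_pathogenic"] == 5
        assert tally["vus"] == 3

    def test_known_variants_excluded(self, cohorts):
        pairs = list(
            zip(cohorts.novel_variants["hgvs"], cohorts.novel_variants["clinical_class"])
        )
        known = [pairs[0][0]]
        novel, _ = count_novel(pairs, known_index=known)
        assert len(novel) == 7

    def test_empty_variant_list(self):
        novel, tally = count_novel([], known_index=["X(NM_1):c.1A>G"])
        assert novel == [] and not tally

    def test_unparseable_hgvs_raises(self):
        with pytest.raises(PpglValError):
            count_novel([("not a variant", "vus")], known_index=[])


class TestEndToEndValidation:
    def test_panel_v1_sensitivity_and_specificity(self, v1_fixture):
        survivors, _ = run_cascade(
            v1_fixture.calls, panel=v1_fixture.panel,
            profile=v1_fixture.profile, config=v1_fixture.config,
        )
        sens = compare_to_truth(survivors, v1_fixture.truth_pathogenic)
        assert sens.sensitivity == 100.0
        spec = compare_to_truth(survivors, v1_fixture.truth, universe=v1_fixture.calls)
        assert (spec.tn, spec.fp) == (113, 1)
        assert round(spec.specificity, 1) == 99.1
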