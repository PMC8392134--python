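"""Filter cascade: per-stage rules, audit accounting, order robustness."""

import itertools
import random

import pytest

from ppglval.afr import AfrWindow
from ppglval.cascade import (
    FilterConfig,
    apply_blacklist,
    filter_afr,
    filter_benign,
    filter_common,
    filter_consequence,
    filter_depth,
    filter_region,
    run_cascade,
)
from ppglval.models import (
    AcmgClass,
    BlacklistEntry,
    Consequence,
    PanelDesign,
    PlatformProfile,
    PolyphenCategory,
    Region,
    VariantCall,
    Zygosity,
)


def make_call(pos=150, chrom="chr1", consequence=Consequence.MISSENSE,
              maf=None, acmg=AcmgClass.UNKNOWN, polyphen=PolyphenCategory.UNKNOWN,
              sift=None, ref_reads=25, alt_reads=25, hgvs_c="", sample="S1",
              zygosity=Zygosity.HET, ref="A", alt="G"):
    return VariantCall(
        sample_id=sample, chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
        ref_reads=ref_reads, alt_reads=alt_reads, consequence=consequence,
        population_maf=maf, acmg_class=acmg, polyphen_category=polyphen,
        sift_score=sift, zygosity_claim=zygosity, hgvs_c=hgvs_c,
    )


PANEL = PanelDesign(
    name="toy", regions=(Region("chr1", 100, 200, "SDHB"),), intronic_padding_bp=30
)
PANEL_PROFILE = PlatformProfile(name="panel", min_reads_per_allele=20, mean_depth=150)
CG_PROFILE = PlatformProfile(name="cg", min_reads_per_allele=5, mean_depth=100)


class TestRegionFilter:
    def test_intronic_padding_is_inclusive(self):
        # exon ends at base 200 (1-based); 30 bp into the intron is kept,
        # 31 bp is removed
        inside = make_call(pos=230)
        outside = make_call(pos=231)
        kept, removed = filter_region([inside, outside], PANEL)
        assert kept == [inside]
        assert [r.call for r in removed] == [outside]

    def test_generated_placement_is_respected(self):
        calls = [make_call(pos=p) for p in range(101, 161)]  # 60 inside
        calls += [make_call(pos=p, chrom="chr9") for p in range(1000, 1040)]
        kept, removed = filter_region(calls, PANEL)
        assert len(kept) == 60
        assert len(removed) == 40


class TestConsequenceFilter:
    def test_splice_site_never_dropped_as_intronic(self):
        call = make_call(consequence=Consequence.INTRONIC, hgvs_c="c.286+2T>A")
        kept, removed = filter_consequence([call], FilterConfig())
        assert kept == [call]

    def test_synonymous_removed(self):
        call = make_call(consequence=Consequence.SYNONYMOUS)
        kept, removed = filter_consequence([call], FilterConfig())
        assert kept == [] and len(removed) == 1

    def test_unknown_consequence_kept_and_flagged(self):
        call = make_call(consequence=Consequence.UNKNOWN)
        survivors, audit = run_cascade([call], config=FilterConfig())
        assert survivors == [call]
        assert any(c is call for c, _ in audit.flags)


class TestCommonFilter:
    def test_threshold_is_strict(self):
        removed_call = make_call(maf=0.02)
        boundary = make_call(pos=151, maf=0.01)
        kept, removed = filter_common([removed_call, boundary], FilterConfig())
        assert kept == [boundary]

    def test_unknown_maf_retained(self):
        call = make_call(maf=None)
        kept, _ = filter_common([call], FilterConfig())
        assert kept == [call]

    def test_counts_by_construction(self):
        calls = [make_call(pos=100 + i, maf=0.05 if i < 3 else 0.001) for i in range(10)]
        kept, removed = filter_common(calls, FilterConfig())
        assert (len(kept), len(removed)) == (7, 3)


class TestBenignFilter:
    def test_full_conjunction_removes(self):
        call = make_call(acmg=AcmgClass.BENIGN, polyphen=PolyphenCategory.BENIGN,
                         sift=0.6)
        kept, removed = filter_benign([call], FilterConfig())
        assert kept == []

    def test_vus_kept(self):
        call = make_call(acmg=AcmgClass.VUS, polyphen=PolyphenCategory.BENIGN)
        kept, _ = filter_benign([call], FilterConfig())
        assert kept == [call]

    def test_polyphen_disagreement_keeps(self):
        call = make_call(acmg=AcmgClass.BENIGN,
                         polyphen=PolyphenCategory.PROBABLY_DAMAGING)
        kept, _ = filter_benign([call], FilterConfig())
        assert kept == [call]

    def test_deleterious_sift_vetoes_benign_by_default(self):
        call = make_call(acmg=AcmgClass.BENIGN, polyphen=PolyphenCategory.BENIGN,
                         sift=0.001)
        kept, _ = filter_benign([call], FilterConfig())
        assert kept == [call]
        # under the literal reading the same call is removed
        kept_lit, _ = filter_benign([call], FilterConfig(sift_literal=True))
        assert kept_lit == []


class TestDepthFilter:
    def test_het_requires_minimum_on_both_alleles(self):
        call = make_call(ref_reads=24, alt_reads=9)
        kept, removed = filter_depth([call], PANEL_PROFILE)
        assert kept == []  # 9 < 20 per-allele panel rule
        kept_cg, _ = filter_depth([call], CG_PROFILE)
        assert kept_cg == [call]  # 9 >= 5 under the exome profile

    def test_balanced_het_kept_under_lenient_profile(self):
        call = make_call(ref_reads=27, alt_reads=23)
        kept, _ = filter_depth([call], CG_PROFILE)
        assert kept == [call]

    def test_zero_alt_reads_removed_under_any_profile(self):
        call = make_call(ref_reads=50, alt_reads=0)
        for profile in (PANEL_PROFILE, CG_PROFILE):
            kept, _ = filter_depth([call], profile)
            assert kept == []

    def test_homozygote_tested_on_alt_only(self):
        call = make_call(ref_reads=0, alt_reads=45, zygosity=Zygosity.HOM)
        kept, _ = filter_depth([call], PANEL_PROFILE)
        assert kept == [call]


BLACK = BlacklistEntry("chr1", 150, "A", "G", note="reference-mismatch locus")


class TestBlacklist:
    def test_exact_match_removed_with_note(self):
        call = make_call(pos=150)
        kept, removed = apply_blacklist([call], FilterConfig(blacklist=(BLACK,)))
        assert kept == []
        assert removed[0].reason == "reference-mismatch locus"

    def test_different_alt_allele_kept(self):
        call = make_call(pos=150, alt="T")
        kept, _ = apply_blacklist([call], FilterConfig(blacklist=(BLACK,)))
        assert kept == [call]

    def test_empty_blacklist_is_identity(self):
        calls = [make_call(pos=150), make_call(pos=151)]
        kept, removed = apply_blacklist(calls, FilterConfig(blacklist=()))
        assert kept == calls and removed == []


class TestAfrFilter:
    def test_low_fraction_removed(self):
        call = make_call(ref_reads=24, alt_reads=9)  # 0.27
        kept, _ = filter_afr([call], FilterConfig())
        assert kept == []

    def test_balanced_kept_under_any_symmetric_window(self):
        call = make_call(ref_reads=30, alt_reads=30)
        for w in (AfrWindow(30, 70), AfrWindow(49, 51), AfrWindow(50, 50)):
            kept, _ = filter_afr([call], FilterConfig(afr_window=w))
            assert kept == [call]


class TestRunCascade:
    def test_validation_fixture_reproduces_published_accounting(self, v1_fixture):
        survivors, audit = run_cascade(
            v1_fixture.calls, panel=v1_fixture.panel,
            profile=v1_fixture.profile, config=v1_fixture.config,
        )
        counts = audit.counts()
        assert counts["region"][0] == 155          # coding calls entering
        assert counts["blacklist"][1] == 15        # reference-mismatch calls
        assert counts["afr"][1] == 98
        assert len(survivors) == 40
        by_class = {}
        for c in survivors:
            by_class[c.acmg_class] = by_class.get(c.acmg_class, 0) + 1
        assert by_class[AcmgClass.PATHOGENIC] + by_class[AcmgClass.LIKELY_PATHOGENIC] == 12
        assert by_class[AcmgClass.VUS] == 2
        assert by_class[AcmgClass.BENIGN] == 25
        assert by_class[AcmgClass.UNKNOWN] == 1    # the surviving artifact

    def test_empty_input_gives_empty_all_zero_audit(self):
        survivors, audit = run_cascade([], panel=PANEL, profile=PANEL_PROFILE)
        assert survivors == []
        assert all(s.n_in == 0 and s.n_removed == 0 for s in audit.stages)

    def test_disabled_cascade_is_identity(self, v1_fixture):
        survivors, audit = run_cascade(
            v1_fixture.calls, config=FilterConfig.disabled()
        )
        assert survivors == v1_fixture.calls
        assert audit.removals == []

    def test_conservation_every_call_in_exactly_one_bucket(self, v1_fixture):
        survivors, audit = run_cascade(
            v1_fixture.calls, panel=v1_fixture.panel,
            profile=v1_fixture.profile, config=v1_fixture.config,
        )
        assert len(survivors) + len(audit.removals) == len(v1_fixture.calls)
        seen = {id(c) for c in survivors} | {id(r.call) for r in audit.removals}
        assert len(seen) == len(v1_fixture.calls)

    def test_audit_telescopes(self, v1_fixture):
        _, audit = run_cascade(
            v1_fixture.calls, panel=v1_fixture.panel,
            profile=v1_fixture.profile, config=v1_fixture.config,
        )
        for prev, nxt in zip(audit.stages, audit.stages[1:]):
            assert prev.n_out == nxt.n_in
        total_removed = sum(s.n_removed for s in audit.stages)
        assert audit.stages[0].n_in == total_removed + len(audit.survivors)


def random_calls(rng, n=40):
    calls = []
    for i in range(n):
        calls.append(
            make_call(
                pos=rng.randint(50, 300),
                chrom=rng.choice(["chr1", "chr2"]),
                consequence=rng.choice(list(Consequence)),
                maf=rng.choice([None, 0.001, 0.05, 0.3]),
                acmg=rng.choice(list(AcmgClass)),
                polyphen=rng.choice(list(PolyphenCategory)),
                sift=rng.choice([None, 0.01, 0.5]),
                ref_reads=rng.randint(0, 80),
                alt_reads=rng.randint(1, 80),
                sample=f"S{i}",
            )
        )
    return calls


class TestOrderInvariance:
    def test_final_set_invariant_under_stage_permutations(self):
        """All stages are set-intersection predicates on single calls, so the
        surviving *set* must not depend on the order they are applied in."""
        rng = random.Random(7)
        config = FilterConfig(blacklist=(BLACK,))
        stages = {
            "region": lambda cs: filter_region(cs, PANEL)[0],
            "consequence": lambda cs: filter_consequence(cs, config)[0],
            "common": lambda cs: filter_common(cs, config)[0],
            "benign": lambda cs: filter_benign(cs, config)[0],
            "depth": lambda cs: filter_depth(cs, CG_PROFILE)[0],
            "blacklist": lambda cs: apply_blacklist(cs, config)[0],
            "afr": lambda cs: filter_afr(cs, config)[0],
        }
        for trial in range(5):
            calls = random_calls(rng)
            reference = None
            orders = list(itertools.permutations(stages))
            rng.shuffle(orders)
            for order in orders[:8]:
                current = calls
                for name in order:
                    current = stages[name](current)
                key = {id(c) for c in current}
                if reference is None:
                    reference = key
                assert key == reference
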