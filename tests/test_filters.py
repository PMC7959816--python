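"""DHFFC, per-site statistics, and the six-step filter cascade."""

import pytest

from svconfide.config import PipelineConfig
from svconfide.core import (
    DepthTrack,
    Genotype,
    RegionSet,
    SampleCall,
    SampleMeta,
    SVRecord,
    ValidationError,
)
from svconfide.filters import (
    allele_frequency,
    call_rate,
    compute_dhffc,
    run_cascade,
    step1_size,
    step2_regions,
    step3_dhffc,
    step4_dh_het,
    step5_af,
    step6_call_rate,
)


def sv(svid="s", start=5000, end=6000, svtype="DEL", gts=(), chrom="c"):
    rec = SVRecord(id=svid, chrom=chrom, start=start, end=end, svtype=svtype)
    for i, g in enumerate(gts):
        if isinstance(g, tuple):
            g, d = g
        else:
            d = None
        rec.calls[f"x{i}"] = SampleCall(g, d)
    return rec


def track(inner, flank=30.0, start=5000, end=6000, length=20_000):
    return DepthTrack(
        {"c": [(0, start, flank), (start, end, inner), (end, length, flank)]},
        {"c": length},
    )


class TestDhffc:
    def test_hom_alt_deletion_interior_zero(self):
        assert compute_dhffc(sv(), track(0.0)) == 0.0

    def test_het_deletion_half(self):
        assert compute_dhffc(sv(), track(15.0)) == 0.5

    def test_zero_flanks_undefined(self):
        assert compute_dhffc(sv(), track(10.0, flank=0.0)) is None

    def test_span_outside_track_errors(self):
        with pytest.raises(ValidationError, match="s"):
            compute_dhffc(sv(end=50_000), track(0.0))

    def test_flank_clipped_at_chromosome_start(self):
        t = DepthTrack({"c": [(0, 500, 10.0), (500, 3000, 40.0)]}, {"c": 3000})
        # SV at [0,500): only the right flank exists
        assert compute_dhffc(sv(start=0, end=500), t) == 0.25


class TestSiteStats:
    @pytest.mark.parametrize(
        "gts,expected",
        [
            ((Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT), 0.5),
            ((Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING, Genotype.HOM_REF), 0.5),
            ((Genotype.HOM_ALT, Genotype.HOM_ALT), 1.0),
            ((Genotype.MISSING,), None),
        ],
    )
    def test_allele_frequency(self, gts, expected):
        assert allele_frequency(sv(gts=gts)) == expected

    def test_call_rate(self):
        gts = (Genotype.HOM_REF,) * 8 + (Genotype.MISSING,) * 2
        assert call_rate(sv(gts=gts)) == 0.8


class TestSteps:
    def test_size_boundary(self):
        svs = [sv("a", 0, 299), sv("b", 0, 300)]
        kept, removed = step1_size(svs, 300)
        assert [x.id for x in kept] == ["b"] and [x.id for x in removed] == ["a"]

    def test_size_counts(self):
        svs = [sv(f"s{i}", 0, 200 + 50 * i) for i in range(10)]  # sizes 200..650
        kept, _ = step1_size(svs, 300)
        assert len(kept) == 8

    def test_region_single_base_overlap_removes(self):
        hc = RegionSet.from_pairs([("c", 5999, 6500)])
        kept, removed = step2_regions([sv()], hc, RegionSet())
        assert not kept and len(removed) == 1

    def test_region_halfopen_touch_keeps(self):
        gaps = RegionSet.from_pairs([("c", 6000, 6500)])
        kept, _ = step2_regions([sv()], RegionSet(), gaps)
        assert len(kept) == 1

    def test_empty_masks_keep_all(self):
        kept, _ = step2_regions([sv("a"), sv("b", 8000, 9000)], RegionSet(), RegionSet())
        assert len(kept) == 2

    @pytest.mark.parametrize(
        "svtype,carrier_dhffcs,kept_literal",
        [
            ("DEL", (0.4, 0.8), False),  # one carrier above 0.7 -> removed
            ("DEL", (0.3, 0.5), True),
            ("DEL", (0.7,), True),  # boundary: strict >
            ("DUP", (1.5, 1.2), False),
            ("DUP", (1.3,), True),
            ("INV", (1.0,), True),
            ("INV", (1.4,), False),
            ("INV", (0.6,), False),
        ],
    )
    def test_dhffc_literal_mode(self, svtype, carrier_dhffcs, kept_literal):
        gts = [(Genotype.HET, d) for d in carrier_dhffcs] + [(Genotype.HOM_REF, 1.0)]
        kept, _ = step3_dhffc([sv(svtype=svtype, gts=gts)], PipelineConfig())
        assert bool(kept) is kept_literal

    def test_dhffc_support_mode_keeps_if_any_carrier_supports(self):
        cfg = PipelineConfig(dhffc_mode="support")
        gts = [(Genotype.HET, 0.4), (Genotype.HET, 0.9)]
        kept, _ = step3_dhffc([sv(gts=gts)], cfg)
        assert len(kept) == 1

    def test_dhffc_undefined_carrier_is_violation(self):
        gts = [(Genotype.HET, None)]
        kept, _ = step3_dhffc([sv(gts=gts)], PipelineConfig())
        assert not kept

    def test_literal_retained_subset_of_support_retained(self, bundle, cfg):
        from svconfide.config import PipelineConfig

        lit, _ = step3_dhffc(bundle.records, cfg)
        sup, _ = step3_dhffc(bundle.records, PipelineConfig(dhffc_mode="support"))
        assert {s.id for s in lit} <= {s.id for s in sup}

    def test_dh_het_removes(self):
        meta = [SampleMeta("x0", "P"), SampleMeta("x1", "DH", True)]
        rec = sv(gts=(Genotype.HET, Genotype.HET))
        kept, _ = step4_dh_het([rec], meta)
        assert not kept

    def test_het_in_outbred_only_keeps(self):
        meta = [SampleMeta("x0", "P"), SampleMeta("x1", "DH", True)]
        rec = sv(gts=(Genotype.HET, Genotype.HOM_ALT))
        kept, _ = step4_dh_het([rec], meta)
        assert len(kept) == 1

    def test_no_dh_samples_keeps_all(self):
        meta = [SampleMeta("x0", "P")]
        kept, _ = step4_dh_het([sv(gts=(Genotype.HET,))], meta)
        assert len(kept) == 1

    @pytest.mark.parametrize(
        "af,kept_flag",
        [(0.04, False), (0.05, True), (0.5, True), (0.95, True), (0.96, False)],
    )
    def test_af_boundaries(self, af, kept_flag):
        # 50 samples -> AF granularity 0.01
        n_alt = round(af * 100)
        gts = [Genotype.HOM_ALT] * (n_alt // 2) + [Genotype.HET] * (n_alt % 2)
        gts += [Genotype.HOM_REF] * (50 - len(gts))
        kept, _ = step5_af([sv(gts=tuple(gts))], 0.05, 0.95)
        assert bool(kept) is kept_flag

    @pytest.mark.parametrize("n_called,kept_flag", [(8, True), (7, False), (10, True)])
    def test_call_rate_boundary(self, n_called, kept_flag):
        gts = [Genotype.HET] * n_called + [Genotype.MISSING] * (10 - n_called)
        kept, _ = step6_call_rate([sv(gts=tuple(gts))], 0.8)
        assert bool(kept) is kept_flag


class TestCascade:
    def test_empty_input(self, cfg):
        retained, audit = run_cascade([], RegionSet(), RegionSet(), [], cfg)
        assert retained == [] and audit.n_input == 0 and audit.n_retained == 0

    def test_truth_recovery_and_audit_conservation(self, bundle, cfg):
        from svconfide.regions import assembly_gaps, high_coverage_multi

        hc = high_coverage_multi(bundle.depths, cfg.high_cov_threshold)
        gaps = assembly_gaps(bundle.genome)
        retained, audit = run_cascade(
            bundle.records, hc, gaps, bundle.meta, cfg, depths=bundle.depths
        )
        assert {s.id for s in retained} == bundle.filter_pass_ids
        total_removed = sum(s.n_removed for s in audit.steps)
        assert total_removed + audit.n_retained == audit.n_input

    def test_cascade_idempotent(self, bundle, cfg):
        from svconfide.regions import assembly_gaps, high_coverage_multi

        hc = high_coverage_multi(bundle.depths, cfg.high_cov_threshold)
        gaps = assembly_gaps(bundle.genome)
        once, _ = run_cascade(bundle.records, hc, gaps, bundle.meta, cfg,
                              depths=bundle.depths)
        twice, _ = run_cascade(once, hc, gaps, bundle.meta, cfg)
        assert {s.id for s in twice} == {s.id for s in once}

    def test_order_independence(self, bundle, cfg):
        from svconfide.regions import assembly_gaps, high_coverage_multi

        hc = high_coverage_multi(bundle.depths, cfg.high_cov_threshold)
        gaps = assembly_gaps(bundle.genome)
        fwd, _ = run_cascade(bundle.records, hc, gaps, bundle.meta, cfg)
        rev, _ = run_cascade(list(reversed(bundle.records)), hc, gaps, bundle.meta, cfg)
        assert {s.id for s in fwd} == {s.id for s in rev}

    def test_tightening_min_size_shrinks_retained(self, bundle, cfg):
        from svconfide.config import PipelineConfig
        from svconfide.regions import assembly_gaps, high_coverage_multi

        hc = high_coverage_multi(bundle.depths, cfg.high_cov_threshold)
        gaps = assembly_gaps(bundle.genome)
        base, _ = run_cascade(bundle.records, hc, gaps, bundle.meta, cfg)
        tight, _ = run_cascade(
            bundle.records, hc, gaps, bundle.meta, PipelineConfig(min_sv_size=1000)
        )
        assert {s.id for s in tight} <= {s.id for s in base}
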