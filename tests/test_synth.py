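"""The synthetic generator: determinism, planted content, internal consistency."""

import numpy as np
import pytest

from svconfide.core import Genotype, GenomicInterval
from svconfide.filters import compute_dhffc
from svconfide.io import cigar_reference_span, parse_cigar
from svconfide.synth import (
    build_genome,
    implant_truth_svs,
    make_bundle,
    make_te_library,
    simulate_cohort,
    simulate_depth,
    simulate_long_reads,
)


class TestTeLibrary:
    def test_same_seed_identical(self):
        a, b = make_te_library(7), make_te_library(7)
        assert [(f.name, f.sequence, f.ltr) for f in a] == [
            (f.name, f.sequence, f.ltr) for f in b]

    def test_family_lengths(self):
        lib = {f.name: f for f in make_te_library(7)}
        assert len(lib["tc1m_analog"].sequence) == 1621
        assert len(lib["gypsy_analog"].ltr) == 380
        assert 1460 <= len(lib["unk_analog"].sequence) <= 1470

    def test_ltr_is_prefix(self):
        gypsy = next(f for f in make_te_library(3) if f.ltr)
        assert gypsy.sequence.startswith(gypsy.ltr)


class TestGenome:
    def test_gap_count_and_maximal_runs(self):
        lib = make_te_library(0)
        genome, _reps, gaps, _pl = build_genome(lib, n_chrom=2, chrom_len=60_000,
                                                te_density=0.02, n_gaps=2, seed=5)
        import re

        found = [
            (c, m.start(), m.end())
            for c, seq in genome.items()
            for m in re.finditer("N+", seq)
        ]
        assert len(found) == 2
        assert sorted(found) == [(i.chrom, i.start, i.end) for i in gaps.intervals()]

    def test_zero_te_density_only_lowcomplexity(self):
        lib = make_te_library(0)
        _g, reps, _gaps, planted = build_genome(lib, n_chrom=1, chrom_len=60_000,
                                                te_density=0.0, n_gaps=0, seed=5)
        assert planted == []
        assert {cls for _iv, cls, _f in reps} <= {"Low_complexity", "Simple_repeat"}

    def test_planted_copies_match_annotation_and_sequence(self):
        lib = {f.name: f for f in make_te_library(0)}
        genome, reps, _gaps, planted = build_genome(
            list(lib.values()), n_chrom=1, chrom_len=100_000, te_density=0.05, seed=5)
        ann = {(iv.chrom, iv.start, iv.end, fam) for iv, _c, fam in reps if fam}
        for chrom, s, e, fam, kind in planted:
            assert (chrom, s, e, fam) in ann
            expected = lib[fam].ltr if kind == "ltr" else lib[fam].sequence
            assert genome[chrom][s:e] == expected


class TestTruthAndCohort:
    def test_decoy_plan(self, bundle):
        labels = [t.decoy_label for t in bundle.truth if t.is_cascade_decoy]
        assert sorted(labels) == [
            "step1_size", "step2_regions", "step3_dhffc",
            "step4_dh_het", "step5_af", "step6_call_rate"]
        assert len(bundle.truth) == 113

    def test_te_deletions_have_library_sizes(self, bundle):
        sizes = {t.te_origin: set() for t in bundle.truth if t.te_origin}
        for t in bundle.truth:
            if t.te_origin:
                sizes[t.te_origin].add(t.size)
        assert sizes["tc1m_analog"] == {1621}
        assert sizes["gypsy_analog"] == {380}  # solo-LTR deletions

    def test_same_seed_identical_truth(self, bundle):
        again = make_bundle(seed=1)
        assert [(t.id, t.chrom, t.start, t.end, t.svtype, t.decoy_label)
                for t in again.truth] == [
            (t.id, t.chrom, t.start, t.end, t.svtype, t.decoy_label)
            for t in bundle.truth]

    def test_dh_lines_have_no_hets_outside_decoy(self, bundle):
        dh = [m.sample_id for m in bundle.meta if m.is_doubled_haploid]
        for t in bundle.truth:
            if t.decoy_label == "step4_dh_het":
                continue
            for s in dh:
                assert bundle.genotypes[t.id][s] is not Genotype.HET

    def test_hardy_weinberg_het_fraction(self):
        # at AF 0.5 the expected outbred het fraction is 2pq = 0.5
        from svconfide.synth import TruthSV

        t = TruthSV("t", "c", 0, 1000, "DEL", {"P": 0.5})
        g, _meta = simulate_cohort([t], {"P": 200}, n_dh=0, seed=3,
                                   af_min=0.0, af_max=1.0)
        hets = sum(1 for x in g["t"].values() if x is Genotype.HET)
        assert abs(hets / 200 - 0.5) < 0.12  # ~3.4 sigma at n=200

    def test_call_rate_decoy_missing_count(self, bundle):
        g = bundle.genotypes["decoy_step6_call_rate"]
        n_missing = sum(1 for x in g.values() if x is Genotype.MISSING)
        assert n_missing == int(np.ceil(0.3 * len(bundle.meta)))

    def test_af_decoy_frequency(self, bundle):
        g = bundle.genotypes["decoy_step5_af"]
        alt = sum(x.alt_count for x in g.values() if x.alt_count is not None)
        assert alt / (2 * len(g)) < 0.05


class TestDepth:
    def test_noiseless_copy_number_closed_forms(self, bundle):
        # find a het DUP and a hom-alt DEL carrier in the bundle
        probes = {"DUP": Genotype.HET, "DEL": Genotype.HOM_ALT}
        seen = set()
        for t in bundle.truth:
            want = probes.get(t.svtype)
            if want is None or t.is_cascade_decoy or t.svtype in seen:
                continue
            carrier = next(
                (s for s, g in bundle.genotypes[t.id].items() if g is want), None)
            if carrier is None:
                continue
            track = bundle.depths[carrier]
            inner = track.median([t.span])
            flank = track.median(
                [GenomicInterval(t.chrom, t.start - 1000, t.start)])
            assert flank == 30.0
            assert inner == {"DUP": 45.0, "DEL": 0.0}[t.svtype]
            seen.add(t.svtype)
        assert seen == {"DUP", "DEL"}

    def test_highcov_decoy_region_everywhere(self, bundle):
        hc = bundle.highcov_region
        for track in bundle.depths.values():
            assert track.median([hc]) >= 200.0

    def test_dhffc_consistency_invariant(self, bundle):
        # recomputing DHFFC from noiseless depth equals the copy-number
        # closed form for every carrier of a clean deletion
        closed = {Genotype.HET: 0.5, Genotype.HOM_ALT: 0.0}
        checked = 0
        for rec in bundle.records[:30]:
            t = bundle.truth_by_id(rec.id)
            if t.svtype != "DEL" or t.is_cascade_decoy:
                continue
            for s, call in rec.calls.items():
                g = call.genotype
                if g in closed:
                    assert compute_dhffc(rec, bundle.depths[s]) == closed[g]
                    assert call.dhffc == closed[g]
                    checked += 1
        assert checked > 10


class TestCandidateRecords:
    def test_record_count_and_genotype_round_trip(self, bundle, tmp_path):
        from svconfide import io as fmt

        assert len(bundle.records) == len(bundle.truth)
        path = tmp_path / "c.vcf"
        fmt.write_sv_vcf(bundle.records, path,
                         sample_ids=[m.sample_id for m in bundle.meta],
                         contigs=bundle.chrom_lengths)
        back = fmt.read_sv_vcf(path, bundle.meta)
        by_id = {r.id: r for r in back}
        for rec in bundle.records:
            for s, call in rec.calls.items():
                assert by_id[rec.id].calls[s].genotype == call.genotype


class TestLongReads:
    def test_noiseless_del_cigar_spans_exact_size(self, bundle):
        aln = simulate_long_reads(
            bundle.truth, bundle.genotypes, bundle.designated_dh,
            reads_per_sv=3, jitter_sd=0.0, seed=0,
            single_read_ids=bundle.single_read_ids)
        dels = {t.id: t for t in bundle.truth if t.svtype == "DEL"}
        by_sv: dict[str, list] = {}
        for a in aln:
            sv_id = a.read_id.split("_rd")[0].split("_sp")[0]
            by_sv.setdefault(sv_id, []).append(a)
        n_checked = 0
        for sv_id, recs in by_sv.items():
            if sv_id not in dels or sv_id in bundle.single_read_ids:
                continue
            d_lens = [n for r in recs for n, op in parse_cigar(r.cigar) if op == "D"]
            if d_lens:
                assert len(d_lens) == 3
                assert set(d_lens) == {dels[sv_id].size}
                n_checked += 1
        assert n_checked > 5

    def test_dup_evidence_has_no_cigar_indel(self, bundle):
        dups = {t.id for t in bundle.truth if t.svtype == "DUP"}
        for a in bundle.alignments:
            sv_id = a.read_id.rsplit("_", 1)[0]
            if sv_id in dups:
                assert all(op != "D" for _n, op in parse_cigar(a.cigar))

    def test_uncovered_svs_have_no_reads(self, bundle):
        for a in bundle.alignments:
            sv_id = a.read_id.rsplit("_", 1)[0]
            assert sv_id not in bundle.uncovered_ids

    def test_single_read_svs_have_exactly_one_read(self, bundle):
        assert len(bundle.single_read_ids) == 2
        for sv_id in bundle.single_read_ids:
            reads = {a.read_id for a in bundle.alignments
                     if a.read_id.rsplit("_", 1)[0] == sv_id}
            assert len(reads) == 1

    def test_only_hom_alt_svs_of_designated_line_covered(self, bundle):
        for a in bundle.alignments:
            sv_id = a.read_id.rsplit("_", 1)[0]
            gt = bundle.genotypes[sv_id][bundle.designated_dh]
            assert gt is Genotype.HOM_ALT
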