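"""Profiling: counts, spacing, size peaks, repeat content, TE identity, PCA."""

import numpy as np
import pytest

import _oracle as oracle
from svconfide.core import Genotype, GenomicInterval, SampleCall, SampleMeta, SVRecord
from svconfide.profiles import (
    chromosome_spacing,
    classify_vs_te_library,
    pca_genotypes,
    per_sample_counts,
    repeat_content,
    size_histogram,
    sv_sequence,
)
from svconfide.synth import make_te_library, simulate_genotype_cohort


def mk_sv(svid, start, end, svtype="DEL", chrom="c", gts=None):
    rec = SVRecord(id=svid, chrom=chrom, start=start, end=end, svtype=svtype)
    for sid, g in (gts or {}).items():
        rec.calls[sid] = SampleCall(g)
    return rec


class TestCountsAndSpacing:
    def test_counts_tally_carriers(self):
        meta = [SampleMeta("a", "P"), SampleMeta("b", "P"), SampleMeta("d", "DH", True)]
        svs = [
            mk_sv("s1", 0, 500, gts={"a": Genotype.HOM_REF, "b": Genotype.HET,
                                     "d": Genotype.HOM_ALT}),
            mk_sv("s2", 1000, 1500, gts={"a": Genotype.HOM_REF, "b": Genotype.HOM_REF,
                                         "d": Genotype.HOM_ALT}),
        ]
        assert per_sample_counts(svs, meta) == {"a": 0, "b": 1, "d": 2}

    def test_dh_counts_on_bundle_equal_hom_alt_sites(self, bundle):
        counts = per_sample_counts(bundle.records, bundle.meta)
        dh = bundle.designated_dh
        expected = sum(
            1 for t in bundle.truth
            if bundle.genotypes[t.id][dh] in (Genotype.HOM_ALT, Genotype.HET))
        assert counts[dh] == expected

    def test_spacing_definition(self):
        svs = [mk_sv(f"s{i}", 10_000 * i, 10_000 * i + 500) for i in range(10)]
        out = chromosome_spacing(svs, {"c": 1_000_000, "c2": 5_000})
        assert out["c"] == 100.0  # 1 Mb / 10 SVs = 100 kb per SV
        assert out["c2"] is None  # no SVs: undefined


class TestSizeHistogram:
    def test_planted_te_peak_flagged(self, bundle):
        dels = [r for r in bundle.records
                if r.svtype == "DEL" and r.id in bundle.filter_pass_ids]
        h = size_histogram(dels, 20)
        assert h.total == len(dels)
        peak_ranges = [h.bin_range(i) for i in h.peak_bins]
        assert any(lo <= 1621 < hi for lo, hi in peak_ranges)
        assert h.counts[h.bin_of(1621)] >= 15

    def test_uniform_sizes_no_peaks(self):
        svs = [mk_sv(f"s{i}", 0, 300 + i) for i in range(100)]  # flat spectrum
        h = size_histogram(svs, 20)
        assert h.peak_bins == []

    def test_single_sv(self):
        h = size_histogram([mk_sv("s", 0, 500)], 20)
        assert h.counts == [1] and h.total == 1


class TestRepeatContent:
    def test_simple_fraction(self):
        svs = [mk_sv("s", 0, 1000)]
        reps = [(GenomicInterval("c", 0, 500), "DNA_transposon", "f")]
        rep = repeat_content(svs, reps)
        assert rep.overall["fraction"] == 0.5

    def test_overlapping_repeats_not_double_counted(self):
        svs = [mk_sv("s", 0, 1000)]
        reps = [
            (GenomicInterval("c", 0, 400), "DNA_transposon", "f"),
            (GenomicInterval("c", 300, 600), "LTR_retrotransposon", "g"),
        ]
        rep = repeat_content(svs, reps)
        assert rep.overall["masked_bp"] == 600
        assert rep.overall["fraction"] == 0.6

    def test_no_repeats(self):
        rep = repeat_content([mk_sv("s", 0, 1000)], [])
        assert rep.overall["fraction"] == 0.0

    def test_bundle_fraction_matches_per_base_oracle(self, bundle):
        svs = [r for r in bundle.records if r.id in bundle.filter_pass_ids][:40]
        rep = repeat_content(svs, bundle.repeats)
        # per-base oracle over the genome
        masks = {c: np.zeros(L, dtype=bool)
                 for c, L in bundle.chrom_lengths.items()}
        for iv, _cls, _fam in bundle.repeats:
            masks[iv.chrom][iv.start:iv.end] = True
        masked = sum(int(masks[sv.chrom][sv.start:sv.end].sum()) for sv in svs)
        total = sum(sv.span.length for sv in svs)
        assert rep.overall["masked_bp"] == masked
        assert rep.overall["fraction"] == masked / total


@pytest.fixture(scope="module")
def lib():
    return make_te_library(7)


class TestTeClassification:
    def test_exact_copy_full_element(self, lib):
        fam, kind, ident = classify_vs_te_library(lib[0].sequence, lib)
        assert (fam, kind, ident) == ("tc1m_analog", "full", 1.0)

    def test_mutated_copy_still_full(self, lib):
        rng = np.random.default_rng(0)
        seq = list(lib[0].sequence)
        for i in rng.choice(len(seq), size=int(0.04 * len(seq)), replace=False):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        fam, kind, ident = classify_vs_te_library("".join(seq), lib)
        assert fam == "tc1m_analog" and kind == "full" and ident >= 0.95

    def test_solo_ltr_called_ltr_not_full(self, lib):
        gypsy = next(f for f in lib if f.ltr)
        fam, kind, ident = classify_vs_te_library(gypsy.ltr, lib)
        assert (fam, kind) == ("gypsy_analog", "ltr") and ident == 1.0

    def test_random_sequence_unclassified(self, lib):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 1621))
        assert classify_vs_te_library(seq, lib) is None

    def test_planted_te_deletion_sequence_classifies(self, bundle):
        t = next(t for t in bundle.truth if t.te_origin == "tc1m_analog")
        rec = next(r for r in bundle.records if r.id == t.id)
        hit = classify_vs_te_library(
            sv_sequence(bundle.genome, rec), bundle.te_library)
        assert hit == ("tc1m_analog", "full", 1.0)


class TestPca:
    def _cohort(self, seed=0):
        return simulate_genotype_cohort(n_svs=120, seed=seed)

    def test_duplicated_samples_identical_coordinates(self):
        svs, meta = self._cohort()
        twin_meta = meta + [SampleMeta("twin", meta[0].population, False)]
        for sv in svs:
            sv.calls["twin"] = SampleCall(sv.calls[meta[0].sample_id].genotype)
        coords = pca_genotypes(svs, twin_meta, 5)
        np.testing.assert_allclose(
            coords.loc[meta[0].sample_id], coords.loc["twin"], atol=1e-9)

    def test_single_polymorphic_sv_one_pc(self):
        meta = [SampleMeta(f"s{i}", "P") for i in range(4)]
        gts = [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.HOM_REF]
        svs = [mk_sv("only", 0, 500, gts=dict(zip([m.sample_id for m in meta], gts)))]
        coords = pca_genotypes(svs, meta, 10)
        assert coords.shape[1] == 1

    def test_invariant_to_sample_and_sv_order(self):
        svs, meta = self._cohort()
        a = pca_genotypes(svs, meta, 4)
        b = pca_genotypes(list(reversed(svs)), list(reversed(meta)), 4)
        np.testing.assert_allclose(
            a.sort_index().values, b.sort_index().values, atol=1e-8)

    def test_missing_values_mean_imputed(self):
        svs, meta = self._cohort()
        svs[0].calls[meta[0].sample_id] = SampleCall(Genotype.MISSING)
        coords = pca_genotypes(svs, meta, 3)
        assert np.isfinite(coords.values).all()

    def test_dh_lines_excluded_by_flag(self):
        svs, meta = self._cohort()
        meta2 = meta + [SampleMeta("DHX", "DH", True)]
        for sv in svs:
            sv.calls["DHX"] = SampleCall(Genotype.HOM_REF)
        coords = pca_genotypes(svs, meta2, 3, exclude_dh=True)
        assert "DHX" not in coords.index
        assert "DHX" in pca_genotypes(svs, meta2, 3, exclude_dh=False).index

    def test_three_population_structure_recovered(self):
        from scipy.optimize import linear_sum_assignment
        from sklearn.cluster import KMeans
        import pandas as pd

        svs, meta = simulate_genotype_cohort(n_svs=500, divergence=0.1, seed=21)
        coords = pca_genotypes(svs, meta, 10)
        km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(
            coords[["PC1", "PC2"]])
        labels = pd.Series([m.population for m in meta],
                           index=[m.sample_id for m in meta])
        ct = pd.crosstab(km.labels_, labels)
        r, c = linear_sum_assignment(-ct.values)
        assert ct.values[r, c].sum() / len(meta) >= 0.95
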