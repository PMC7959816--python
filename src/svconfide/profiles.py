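"""Downstream characterization of a retained SV set.

Per-sample carrier counts, per-chromosome spacing, size-distribution peaks,
repeat/TE content of SV intervals, identity-based classification against a
TE library, and genotype PCA for population structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .core import GenomicInterval, Genotype, RegionSet, SampleMeta, SVRecord, normalize_regions
from .synth import TEFamily

log = logging.getLogger("svconfide")


def per_sample_counts(svs: Sequence[SVRecord], meta: Sequence[SampleMeta]) -> dict[str, int]:
    """Number of SVs with a non-reference (het or hom-alt) genotype per sample."""
    counts = {m.sample_id: 0 for m in meta}
    for sv in svs:
        for sid, call in sv.calls.items():
            if sid in counts and call.genotype.is_carrier:
                counts[sid] += 1
    return counts


def chromosome_spacing(
    svs: Sequence[SVRecord], chrom_lengths: Mapping[str, int]
) -> dict[str, float | None]:
    """kb of chromosome per SV; None (undefined) for chromosomes with no SVs."""
    n = {c: 0 for c in chrom_lengths}
    for sv in svs:
        if sv.chrom in n:
            n[sv.chrom] += 1
    return {
        c: (chrom_lengths[c] / 1000.0 / n[c]) if n[c] else None for c in chrom_lengths
    }


@dataclass
class SizeHistogram:
    bin_width: int
    origin: int  # left edge of the first bin
    counts: list[int]
    peak_bins: list[int] = field(default_factory=list)

    def bin_range(self, i: int) -> tuple[int, int]:
        lo = self.origin + i * self.bin_width
        return lo, lo + self.bin_width

    def bin_of(self, size: int) -> int:
        return (size - self.origin) // self.bin_width

    @property
    def total(self) -> int:
        return sum(self.counts)


def size_histogram(
    svs: Sequence[SVRecord], bin_width: int = 20, peak_factor: float = 3.0
) -> SizeHistogram:
    """Fixed-width size histogram with peak calling.

    Bins start at the minimum observed size rounded down to a bin-width
    multiple. A bin is a peak iff its count strictly exceeds both neighbours
    (missing neighbour counts as 0) and exceeds peak_factor times the median
    bin count.
    """
    sizes = [sv.size for sv in svs]
    if not sizes:
        return SizeHistogram(bin_width, 0, [])
    origin = (min(sizes) // bin_width) * bin_width
    n_bins = (max(sizes) - origin) // bin_width + 1
    counts = [0] * n_bins
    for s in sizes:
        counts[(s - origin) // bin_width] += 1
    med = float(np.median(counts))
    peaks = []
    for i, c in enumerate(counts):
        left = counts[i - 1] if i > 0 else 0
        right = counts[i + 1] if i + 1 < n_bins else 0
        if c > left and c > right and c > peak_factor * med:
            peaks.append(i)
    return SizeHistogram(bin_width, origin, counts, peaks)


@dataclass
class RepeatContentReport:
    by_type: dict[str, dict]  # svtype -> {total_bp, masked_bp, fraction}
    overall: dict
    by_class: dict[str, dict]  # repeat class -> {masked_bp, fraction_of_sv_bp}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"group": t, **v} for t, v in self.by_type.items()]
        rows.append({"group": "Total", **self.overall})
        return pd.DataFrame(rows)


def repeat_content(
    svs: Sequence[SVRecord],
    repeats: Iterable[tuple[GenomicInterval, str, str]],
) -> RepeatContentReport:
    """Fraction of SV nucleotides covered by repeat annotation.

    Repeat intervals are unioned before intersecting so overlapping features
    are not double-counted; per-class fractions use the per-class unions.
    """
    repeats = list(repeats)
    union_all = normalize_regions([iv for iv, _c, _f in repeats])
    by_class_union: dict[str, RegionSet] = {}
    for iv, cls, _fam in repeats:
        by_class_union.setdefault(cls, None)
    for cls in by_class_union:
        by_class_union[cls] = normalize_regions(
            [iv for iv, c, _f in repeats if c == cls]
        )
    by_type: dict[str, dict] = {}
    by_class_masked: dict[str, int] = {cls: 0 for cls in by_class_union}
    tot_bp = 0
    tot_masked = 0
    for sv in svs:
        total = sv.span.length
        masked = union_all.intersect_length(sv.span)
        row = by_type.setdefault(sv.svtype, {"total_bp": 0, "masked_bp": 0})
        row["total_bp"] += total
        row["masked_bp"] += masked
        tot_bp += total
        tot_masked += masked
        for cls, u in by_class_union.items():
            by_class_masked[cls] += u.intersect_length(sv.span)
    for row in by_type.values():
        row["fraction"] = row["masked_bp"] / row["total_bp"] if row["total_bp"] else 0.0
    overall = {
        "total_bp": tot_bp,
        "masked_bp": tot_masked,
        "fraction": tot_masked / tot_bp if tot_bp else 0.0,
    }
    by_class = {
        cls: {
            "masked_bp": m,
            "fraction_of_sv_bp": m / tot_bp if tot_bp else 0.0,
        }
        for cls, m in by_class_masked.items()
    }
    return RepeatContentReport(by_type=by_type, overall=overall, by_class=by_class)


def sv_sequence(genome: Mapping[str, str], sv: SVRecord) -> str:
    return genome[sv.chrom][sv.start : sv.end]


def _identity(aligner: Align.PairwiseAligner, query: str, target: str) -> float:
    """Matches over alignment columns (terminal gap columns included) for the
    best-scoring end-gap-free alignment.

    Counting terminal gaps in the denominator makes the score reflect
    coverage of the library sequence: a solo LTR aligned to a full-length
    element scores low against the full sequence but high against the LTR
    itself.
    """
    aln = aligner.align(query, target)[0]
    matches = 0
    columns = max(aln.shape[1], len(query), len(target))
    for (qs, qe), (ts, te) in zip(aln.aligned[0], aln.aligned[1]):
        q = query[qs:qe]
        t = target[ts:te]
        matches += sum(1 for x, y in zip(q, t) if x == y)
    return matches / columns


def classify_vs_te_library(
    seq: str,
    library: Sequence[TEFamily],
    full_thr: float = 0.95,
    part_thr: float = 0.80,
) -> tuple[str, str, float] | None:
    """Assign an SV sequence to a TE family by alignment identity.

    Returns (family name, 'full' | 'ltr', identity) or None. A best hit with
    identity >= full_thr against a family's full sequence is a full-element
    call; otherwise a best hit >= part_thr against an LTR sub-sequence is a
    solo-LTR call. Identity uses end-gap-free global alignment (match +1,
    mismatch -1, gap open -2, extend -1), matches / alignment columns. Ties
    break toward higher identity then library order.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    aligner.end_gap_score = 0  # end-gap-free (semi-global)
    best_full: tuple[float, int] | None = None
    best_ltr: tuple[float, int] | None = None
    for i, fam in enumerate(library):
        ident = _identity(aligner, seq, fam.sequence)
        if best_full is None or ident > best_full[0]:
            best_full = (ident, i)
        if fam.ltr:
            ident_l = _identity(aligner, seq, fam.ltr)
            if best_ltr is None or ident_l > best_ltr[0]:
                best_ltr = (ident_l, i)
    if best_full and best_full[0] >= full_thr:
        return library[best_full[1]].name, "full", best_full[0]
    if best_ltr and best_ltr[0] >= part_thr:
        return library[best_ltr[1]].name, "ltr", best_ltr[0]
    return None


def dosage_matrix(
    svs: Sequence[SVRecord], sample_ids: Sequence[str]
) -> np.ndarray:
    """Samples x SVs alt-allele dosage (0/1/2), NaN for missing."""
    X = np.full((len(sample_ids), len(svs)), np.nan)
    for j, sv in enumerate(svs):
        for i, sid in enumerate(sample_ids):
            c = sv.calls.get(sid)
            if c is not None and c.genotype.alt_count is not None:
                X[i, j] = c.genotype.alt_count
    return X


def pca_genotypes(
    svs: Sequence[SVRecord],
    meta: Sequence[SampleMeta],
    n_pcs: int = 10,
    exclude_dh: bool = True,
    scale: bool = True,
) -> pd.DataFrame:
    """Genotype PCA in the variance-standardized convention of genetics
    tooling.

    Dosages are mean-imputed per SV, centered, and (by default) scaled by
    sqrt(2p(1-p)) with p the alt-allele frequency; zero-variance SVs are
    dropped. Coordinates are leading left singular vectors scaled by their
    singular values; each PC's sign is fixed so its largest-magnitude SV
    loading is positive. DH lines are excluded by default, mirroring the
    practice of running structure analyses on outbred samples only.
    """
    use = [m for m in meta if not (exclude_dh and m.is_doubled_haploid)]
    if len(use) < 2:
        raise ValueError("PCA needs at least two samples")
    sample_ids = [m.sample_id for m in use]
    X = dosage_matrix(svs, sample_ids)
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(col_mean, idx[1])
    var = X.var(axis=0)
    keep = var > 0
    if not keep.any():
        raise ValueError("no polymorphic SVs")
    X = X[:, keep]
    p = X.mean(axis=0) / 2.0
    X = X - 2.0 * p
    if scale:
        X = X / np.sqrt(2.0 * p * (1.0 - p))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-9)) if S.size else 0
    k = min(n_pcs, rank)
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    coords = U[:, :k] * S[:k]
    return pd.DataFrame(
        coords, index=sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
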