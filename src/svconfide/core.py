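"""Domain types and exact genomic-interval algebra.

All internal coordinates are 0-based half-open (BED convention). VCF records
are converted on read (POS-1) and restored on write. The interval algebra
(normalize, union, subtract, gap-merge, overlap queries) is exact integer
arithmetic; tests check it against a per-base boolean-mask oracle.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class Genotype(Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def alt_count(self) -> int | None:
        """Alternate-allele dosage; None for a missing call."""
        return {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": None}[self.value]

    @property
    def is_carrier(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


@dataclass
class SampleCall:
    """One sample's call at one SV: genotype plus depth fold change.

    dhffc is the median read depth inside the variant divided by the median
    depth of its flanking regions; None when undefined (zero-depth flanks)
    or not yet annotated.
    """

    genotype: Genotype
    dhffc: float | None = None

    def __post_init__(self) -> None:
        if self.dhffc is not None and self.dhffc < 0:
            raise ValidationError(f"negative DHFFC {self.dhffc}")


SV_TYPES = ("DEL", "DUP", "INV")


@dataclass
class SVRecord:
    """One candidate structural variant.

    start/end are internal 0-based half-open; ``pos``/``vcf_end`` expose the
    1-based VCF convention. size = end - start unless SVLEN overrode it.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    calls: dict[str, SampleCall] = field(default_factory=dict)
    size: int | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValidationError(f"unsupported SVTYPE {self.svtype!r} in {self.id}")
        if self.end < self.start:
            raise ValidationError(f"end < start in {self.id}")
        if self.size is None:
            self.size = self.end - self.start

    @property
    def pos(self) -> int:
        """1-based VCF POS."""
        return self.start + 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def carriers(self) -> dict[str, SampleCall]:
        return {s: c for s, c in self.calls.items() if c.genotype.is_carrier}


@dataclass(frozen=True)
class BreakpointPair:
    """A paired-end breakpoint: two intervals bracketing the two junction
    coordinates of an SV, typed DEL/DUP/INV, with the originating read or SV id."""

    chrom: str
    left: GenomicInterval
    right: GenomicInterval
    svtype: str
    source: str

    def __post_init__(self) -> None:
        if self.left.start > self.right.start:
            raise ValidationError(f"unsorted breakpoint pair from {self.source}")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    population: str
    is_doubled_haploid: bool = False


class RegionSet:
    """Per-chromosome sorted, disjoint, non-adjacent half-open intervals.

    The currency of all masking and overlap logic. Construct via
    :func:`normalize_regions` or ``RegionSet.from_pairs``.
    """

    __slots__ = ("_by_chrom",)

    def __init__(self, by_chrom: Mapping[str, list[tuple[int, int]]] | None = None):
        # trusted constructor: caller guarantees normalization
        self._by_chrom: dict[str, list[tuple[int, int]]] = dict(by_chrom or {})

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int, int]]) -> "RegionSet":
        return normalize_regions(
            [GenomicInterval(c, s, e) for c, s, e in pairs]
        )

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._by_chrom):
            for s, e in self._by_chrom[chrom]:
                yield GenomicInterval(chrom, s, e)

    def pairs(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._by_chrom.get(chrom, []))

    @property
    def chromosomes(self) -> list[str]:
        return sorted(c for c, ivs in self._by_chrom.items() if ivs)

    @property
    def total_length(self) -> int:
        return sum(e - s for ivs in self._by_chrom.values() for s, e in ivs)

    def __len__(self) -> int:
        return sum(len(ivs) for ivs in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        a = {c: ivs for c, ivs in self._by_chrom.items() if ivs}
        b = {c: ivs for c, ivs in other._by_chrom.items() if ivs}
        return a == b

    def __repr__(self) -> str:
        n = len(self)
        return f"RegionSet({n} intervals, {self.total_length} bp)"

    # -- queries ---------------------------------------------------------

    def overlapping(self, iv: GenomicInterval) -> list[tuple[int, int]]:
        """Intervals sharing >=1 base with iv, clipped to iv."""
        ivs = self._by_chrom.get(iv.chrom)
        if not ivs:
            return []
        starts = [s for s, _ in ivs]
        i = bisect.bisect_right(starts, iv.start) - 1
        if i < 0:
            i = 0
        out = []
        for s, e in ivs[i:]:
            if s >= iv.end:
                break
            if e > iv.start:
                out.append((max(s, iv.start), min(e, iv.end)))
        return out

    def intersect_length(self, iv: GenomicInterval) -> int:
        return sum(e - s for s, e in self.overlapping(iv))

    def overlaps(self, iv: GenomicInterval) -> bool:
        return bool(self.overlapping(iv))

    # -- algebra ---------------------------------------------------------

    def union(self, other: "RegionSet") -> "RegionSet":
        merged: dict[str, list[tuple[int, int]]] = {}
        for chrom in set(self._by_chrom) | set(other._by_chrom):
            ivs = sorted(self._by_chrom.get(chrom, []) + other._by_chrom.get(chrom, []))
            merged[chrom] = _coalesce(ivs, gap=0)
        return RegionSet(merged)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in self._by_chrom.items():
            hole = other._by_chrom.get(chrom, [])
            kept: list[tuple[int, int]] = []
            j = 0
            for s, e in ivs:
                cur = s
                while j < len(hole) and hole[j][1] <= cur:
                    j += 1
                k = j
                while k < len(hole) and hole[k][0] < e:
                    hs, he = hole[k]
                    if hs > cur:
                        kept.append((cur, hs))
                    cur = max(cur, he)
                    k += 1
                if cur < e:
                    kept.append((cur, e))
            out[chrom] = kept
        return RegionSet(out)


def _coalesce(sorted_ivs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Join consecutive sorted intervals whose separation is < gap, or which
    overlap/abut (separation <= 0)."""
    out: list[tuple[int, int]] = []
    for s, e in sorted_ivs:
        if out and (s - out[-1][1] < gap or s <= out[-1][1]):
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def normalize_regions(raw: Iterable[GenomicInterval]) -> RegionSet:
    """Sort and coalesce overlapping or adjacent intervals per chromosome.

    Total covered bases are preserved. Invalid intervals (end <= start) are
    rejected by GenomicInterval itself with a ValidationError naming the
    offender.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in raw:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return RegionSet({c: _coalesce(sorted(ivs), gap=0) for c, ivs in by_chrom.items()})


def merge_within_gap(rs: RegionSet, max_gap: int) -> RegionSet:
    """Join consecutive intervals separated by strictly less than max_gap bp.

    Idempotent; models the "separated by less than 1,000 bp were merged"
    region-combining rule.
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    return RegionSet(
        {c: _coalesce(ivs, gap=max_gap) for c, ivs in rs._by_chrom.items()}
    )


def overlaps(span: GenomicInterval, rs: RegionSet) -> bool:
    """True iff span shares at least one base with rs (half-open semantics)."""
    return rs.overlaps(span)


class DepthTrack:
    """Run-length encoded per-base read depth for one sample.

    Segments tile each chromosome [0, length) without overlap; uncovered
    stretches are depth 0.
    """

    __slots__ = ("segments", "chrom_lengths")

    def __init__(
        self,
        segments: Mapping[str, list[tuple[int, int, float]]],
        chrom_lengths: Mapping[str, int] | None = None,
    ):
        self.segments: dict[str, list[tuple[int, int, float]]] = {}
        self.chrom_lengths: dict[str, int] = {}
        for chrom, segs in segments.items():
            segs = sorted(segs)
            length = (chrom_lengths or {}).get(chrom) or (segs[-1][1] if segs else 0)
            filled: list[tuple[int, int, float]] = []
            cur = 0
            for s, e, d in segs:
                if d < 0:
                    raise ValidationError(f"negative depth at {chrom}:{s}-{e}")
                if s < cur:
                    prev = filled[-1] if filled else None
                    if prev and prev[2] != d:
                        raise ValidationError(
                            f"overlapping depth intervals with conflicting values at {chrom}:{s}"
                        )
                    s = cur
                    if s >= e:
                        continue
                if s > cur:
                    filled.append((cur, s, 0.0))
                filled.append((s, e, float(d)))
                cur = e
            if cur < length:
                filled.append((cur, length, 0.0))
            # merge equal-depth neighbours for a canonical form
            merged: list[tuple[int, int, float]] = []
            for s, e, d in filled:
                if merged and merged[-1][2] == d and merged[-1][1] == s:
                    merged[-1] = (merged[-1][0], e, d)
                else:
                    merged.append((s, e, d))
            self.segments[chrom] = merged
            self.chrom_lengths[chrom] = max(length, cur)

    def covers(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self.segments and iv.end <= self.chrom_lengths[iv.chrom]

    def pieces(self, iv: GenomicInterval) -> list[tuple[int, float]]:
        """(length, depth) runs intersecting iv."""
        out = []
        for s, e, d in self.segments.get(iv.chrom, []):
            if e <= iv.start:
                continue
            if s >= iv.end:
                break
            out.append((min(e, iv.end) - max(s, iv.start), d))
        return out

    def median(self, intervals: Iterable[GenomicInterval]) -> float:
        """Per-base median depth over the union of intervals (weighted median
        over run lengths; intervals assumed disjoint)."""
        pieces: list[tuple[float, int]] = []
        for iv in intervals:
            pieces.extend((d, n) for n, d in self.pieces(iv))
        n_total = sum(n for _, n in pieces)
        if n_total == 0:
            raise ValidationError("median over empty depth region")
        pieces.sort()
        lo_idx = (n_total - 1) // 2
        hi_idx = n_total // 2
        lo = hi = None
        cum = 0
        for d, n in pieces:
            if lo is None and cum + n > lo_idx:
                lo = d
            if cum + n > hi_idx:
                hi = d
                break
            cum += n
        return (lo + hi) / 2.0

    def runs_at_least(self, threshold: float) -> RegionSet:
        """Maximal runs with depth >= threshold, as a normalized RegionSet."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, segs in self.segments.items():
            ivs = [(s, e) for s, e, d in segs if d >= threshold]
            out[chrom] = _coalesce(ivs, gap=0)
        return RegionSet(out)
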