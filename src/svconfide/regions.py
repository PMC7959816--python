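"""Problematic-region masks: extreme coverage, low complexity, assembly gaps.

Three masks are built independently and combined with a gap-merge, mirroring
the pre-calling exclusion mask of the published pipeline. SV-level filtering
(step 2 of the cascade) uses only the high-coverage and gap sets; the
combined mask is exported for audit and consumed by the synthetic generator
to avoid planting pass-variants inside it.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

from .core import (
    DepthTrack,
    GenomicInterval,
    RegionSet,
    merge_within_gap,
    normalize_regions,
)

_N_RUN = re.compile(r"[Nn]+")


def high_coverage_regions(depth: DepthTrack, threshold: float = 200.0) -> RegionSet:
    """Maximal runs with depth >= threshold ('equal or above 200x')."""
    return depth.runs_at_least(threshold)


def high_coverage_multi(
    tracks: Mapping[str, DepthTrack], threshold: float = 200.0, mode: str = "union"
) -> RegionSet:
    """Combine per-sample high-coverage regions across a cohort.

    mode='union': a base is masked if any sample reaches the threshold
    (default). mode='mean': threshold is applied to the across-sample mean
    depth.
    """
    if mode == "union":
        out = RegionSet()
        for track in tracks.values():
            out = out.union(high_coverage_regions(track, threshold))
        return out
    if mode != "mean":
        raise ValueError(f"unknown high-coverage mode {mode!r}")
    out_pairs: list[tuple[str, int, int]] = []
    chroms = sorted({c for t in tracks.values() for c in t.segments})
    n = len(tracks)
    for chrom in chroms:
        cuts = sorted({x for t in tracks.values() for s, e, _ in t.segments.get(chrom, []) for x in (s, e)})
        for a, b in zip(cuts, cuts[1:]):
            total = 0.0
            for t in tracks.values():
                for s, e, d in t.segments.get(chrom, []):
                    if s <= a and e >= b:
                        total += d
                        break
            if total / n >= threshold:
                out_pairs.append((chrom, a, b))
    return RegionSet.from_pairs(out_pairs)


def low_complexity_regions(
    repeats: Iterable[tuple[GenomicInterval, str, str]],
    merge_gap: int = 1000,
    min_len: int = 200,
    classes: tuple[str, ...] = ("Low_complexity", "Simple_repeat"),
) -> RegionSet:
    """Low-complexity mask: select annotated low-complexity features, merge
    features closer than merge_gap, keep merged intervals strictly longer
    than min_len."""
    selected = [iv for iv, cls, _fam in repeats if cls in classes]
    merged = merge_within_gap(normalize_regions(selected), merge_gap)
    kept = [iv for iv in merged.intervals() if iv.length > min_len]
    return normalize_regions(kept)


def assembly_gaps(genome: Mapping[str, str]) -> RegionSet:
    """Maximal runs of N (case-insensitive) per chromosome."""
    pairs = []
    for chrom, seq in genome.items():
        for m in _N_RUN.finditer(seq):
            pairs.append((chrom, m.start(), m.end()))
    return RegionSet.from_pairs(pairs)


def combine_problem_regions(
    high_cov: RegionSet,
    low_cplx: RegionSet,
    gaps: RegionSet,
    merge_gap: int = 1000,
) -> RegionSet:
    """Union of the three masks, then gap-merge — the read-exclusion mask."""
    return merge_within_gap(high_cov.union(low_cplx).union(gaps), merge_gap)
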