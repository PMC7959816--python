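"""Long-read validation of candidate SVs.

Breakpoint pairs are extracted from alignments two ways: long deletion
(D) operations inside a single alignment's CIGAR, and junctions between the
split segments of one read. A candidate matches a read pair when the types
agree and either both breakpoints fall within a slop window (100 bp) or the
read-implied span and the SV span overlap reciprocally by >=90%. An SV is
validated when at least two distinct reads support it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .config import PipelineConfig
from .core import BreakpointPair, GenomicInterval, SVRecord
from .io import AlignmentRecord, group_by_read, parse_cigar

log = logging.getLogger("svconfide")


def _point(chrom: str, x: int) -> GenomicInterval:
    return GenomicInterval(chrom, x, x + 1)


def cigar_breakpoints(
    aln: AlignmentRecord, min_len: int = 50
) -> list[BreakpointPair]:
    """DEL-type breakpoint pairs from CIGAR deletions strictly longer than
    min_len; each pair's point intervals sit at the deletion's reference
    start and end."""
    out = []
    ref = aln.ref_start
    for n, op in parse_cigar(aln.cigar):
        if op in "M=XN":
            ref += n
        elif op == "D":
            if n > min_len:
                out.append(
                    BreakpointPair(
                        chrom=aln.chrom,
                        left=_point(aln.chrom, ref),
                        right=_point(aln.chrom, ref + n),
                        svtype="DEL",
                        source=aln.read_id,
                    )
                )
            ref += n
    return out


def count_large_insertions(aln: AlignmentRecord, min_len: int = 50) -> int:
    """Insertion (I) CIGAR operations strictly longer than min_len.

    Recorded for reporting only: insertion evidence is never matched against
    DEL/DUP/INV candidates."""
    return sum(1 for n, op in parse_cigar(aln.cigar) if op == "I" and n > min_len)


def split_breakpoints(segments: Sequence[AlignmentRecord]) -> list[BreakpointPair]:
    """Breakpoint pairs from the junctions of a split read.

    Segments must share a read id and be given in read order. Each adjacent
    pair yields one breakpoint pair typed by geometry: same strand with a
    forward reference jump -> DEL; same strand with a backward jump (the
    later segment maps before the earlier one ends) -> DUP; strand flip ->
    INV. The pair is (reference end of the earlier segment, reference start
    of the later segment), stored sorted. Segments on different chromosomes
    are skipped (translocations are out of scope).
    """
    out = []
    for a, b in zip(segments, segments[1:]):
        if a.chrom != b.chrom:
            log.info("read %s: inter-chromosomal split skipped", a.read_id)
            continue
        if a.strand != b.strand:
            svtype = "INV"
        elif b.ref_start >= a.ref_end:
            svtype = "DEL"
        else:
            svtype = "DUP"
        x, y = sorted((a.ref_end, b.ref_start))
        if x == y:
            continue  # abutting segments: no junction gap
        out.append(
            BreakpointPair(
                chrom=a.chrom, left=_point(a.chrom, x), right=_point(a.chrom, y),
                svtype=svtype, source=a.read_id,
            )
        )
    return out


def _ivals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def match_sv(
    sv: SVRecord, bp: BreakpointPair, slop: int = 100, frac: float = 0.9
) -> bool:
    """Does a read breakpoint pair support a candidate SV?

    Requires type concordance plus either (A) both breakpoint intervals,
    expanded by slop, overlapping the SV's breakpoint points, or (B)
    reciprocal overlap >= frac between the read-implied outer span and the
    SV span. Strand-insensitive.
    """
    if sv.chrom != bp.chrom or sv.svtype != bp.svtype:
        return False
    sv_left = (sv.start, sv.start + 1)
    sv_right = (sv.end, sv.end + 1)
    a = (
        _ivals_overlap(bp.left.start - slop, bp.left.end + slop, *sv_left) > 0
        and _ivals_overlap(bp.right.start - slop, bp.right.end + slop, *sv_right) > 0
    )
    if a:
        return True
    span = (bp.left.start, bp.right.end)
    ov = _ivals_overlap(span[0], span[1], sv.start, sv.end)
    len_bp = span[1] - span[0]
    len_sv = sv.end - sv.start
    return ov >= frac * len_bp and ov >= frac * len_sv


@dataclass
class SVSupport:
    n_indel_support: int = 0
    n_split_support: int = 0
    n_support_reads: int = 0  # distinct reads across both evidence classes
    validated: bool = False


@dataclass
class ValidationReport:
    """Per-SV support tallies plus per-type aggregate counts.

    ``by_type`` maps svtype -> dict with n_candidates, n_validated_by_indel
    (None where the evidence class does not apply), n_validated_by_split and
    n_validated.
    """

    per_sv: dict[str, SVSupport] = field(default_factory=dict)
    by_type: dict[str, dict] = field(default_factory=dict)
    min_support_reads: int = 2
    n_insertion_evidence: int = 0

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, dict], min_support_reads: int = 2
    ) -> "ValidationReport":
        """Build a report directly from aggregate per-type counts (keys:
        n_candidates, n_validated, optionally n_validated_by_indel and
        n_validated_by_split)."""
        by_type = {
            t: {
                "n_candidates": int(c["n_candidates"]),
                "n_validated": int(c["n_validated"]),
                "n_validated_by_indel": c.get("n_validated_by_indel"),
                "n_validated_by_split": c.get("n_validated_by_split"),
            }
            for t, c in counts.items()
        }
        return cls(by_type=by_type, min_support_reads=min_support_reads)


def extract_breakpoints(
    alignments: Sequence[AlignmentRecord], min_cigar_indel: int = 50
) -> tuple[list[BreakpointPair], list[BreakpointPair], int]:
    """All (indel_pairs, split_pairs, n_insertion_evidence) in the alignment set."""
    indel: list[BreakpointPair] = []
    split: list[BreakpointPair] = []
    n_ins = 0
    for read_id, segs in group_by_read(alignments).items():
        for seg in segs:
            indel.extend(cigar_breakpoints(seg, min_cigar_indel))
            n_ins += count_large_insertions(seg, min_cigar_indel)
        if len(segs) >= 2:
            split.extend(split_breakpoints(segs))
    return indel, split, n_ins


def validate(
    candidates: Sequence[SVRecord],
    alignments: Sequence[AlignmentRecord],
    cfg: PipelineConfig | None = None,
) -> ValidationReport:
    """Validate a candidate set (SVs hom-alt in the designated homozygous
    line) against long-read alignments.

    A read supports an SV when any of its breakpoint pairs matches; a read
    counts once toward the >=2-read threshold even if it contributes both
    CIGAR-indel and split evidence. Indel and split support are tallied
    separately for the report.
    """
    cfg = cfg or PipelineConfig()
    indel, split, n_ins = extract_breakpoints(alignments, cfg.min_cigar_indel)
    report = ValidationReport(min_support_reads=cfg.min_support_reads,
                              n_insertion_evidence=n_ins)
    for sv in candidates:
        indel_reads = {
            bp.source for bp in indel
            if match_sv(sv, bp, cfg.slop, cfg.reciprocal_fraction)
        }
        split_reads = {
            bp.source for bp in split
            if match_sv(sv, bp, cfg.slop, cfg.reciprocal_fraction)
        }
        support = indel_reads | split_reads
        report.per_sv[sv.id] = SVSupport(
            n_indel_support=len(indel_reads),
            n_split_support=len(split_reads),
            n_support_reads=len(support),
            validated=len(support) >= cfg.min_support_reads,
        )
    # aggregate per type
    for sv in candidates:
        row = report.by_type.setdefault(
            sv.svtype,
            {
                "n_candidates": 0,
                "n_validated": 0,
                "n_validated_by_indel": 0 if sv.svtype == "DEL" else None,
                "n_validated_by_split": 0,
            },
        )
        sup = report.per_sv[sv.id]
        row["n_candidates"] += 1
        row["n_validated"] += int(sup.validated)
        if row["n_validated_by_indel"] is not None:
            row["n_validated_by_indel"] += int(
                sup.n_indel_support >= cfg.min_support_reads
            )
        row["n_validated_by_split"] += int(
            sup.n_split_support >= cfg.min_support_reads
        )
    return report


def _rate(validated: int, candidates: int) -> float:
    """Percentage with one-decimal half-up rounding (98.0-style)."""
    if candidates == 0:
        return 0.0
    pct = Decimal(100 * validated) / Decimal(candidates)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize(report: ValidationReport) -> list[dict]:
    """Per-type and Total validation-rate table.

    Each row: svtype, n_candidates, n_validated_by_indel (None = not
    applicable), n_validated_by_split, n_validated, rate (percent, one
    decimal, half-up), empty flag when there are no candidates.
    """
    rows = []
    order = [t for t in ("DEL", "DUP", "INV") if t in report.by_type]
    order += [t for t in report.by_type if t not in order]
    tot = {"n_candidates": 0, "n_validated": 0}
    for t in order:
        r = report.by_type[t]
        rows.append(
            {
                "svtype": t,
                **r,
                "rate": _rate(r["n_validated"], r["n_candidates"]),
                "empty": r["n_candidates"] == 0,
            }
        )
        tot["n_candidates"] += r["n_candidates"]
        tot["n_validated"] += r["n_validated"]
    def _total(key: str) -> int | None:
        vals = [r[key] for r in rows if r[key] is not None]
        return sum(vals) if vals else None

    rows.append(
        {
            "svtype": "Total",
            "n_candidates": tot["n_candidates"],
            "n_validated": tot["n_validated"],
            "n_validated_by_indel": _total("n_validated_by_indel"),
            "n_validated_by_split": _total("n_validated_by_split"),
            "rate": _rate(tot["n_validated"], tot["n_candidates"]),
            "empty": tot["n_candidates"] == 0,
        }
    )
    return rows
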