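"""The six-step high-confidence SV filter cascade, with per-step audit.

Steps, in fixed published order:

1. size — SVs shorter than 300 bp removed;
2. regions — SVs sharing any base with a high-coverage (>=200x) region or
   an assembly gap removed;
3. DHFFC — depth-fold-change consistency of carrier samples with the SV
   type (deletions deplete, duplications amplify, inversions are neutral);
4. DH het — SVs called heterozygous in any doubled-haploid line removed
   (DH lines are homozygous by construction, so a het there is an error);
5. AF — sites with allele frequency < 0.05 or > 0.95 removed;
6. call rate — sites genotyped in fewer than 80% of samples removed.

DHFFC conditions are evaluated over carrier samples only: a literal
all-samples reading would remove every deletion, because hom-ref samples sit
at DHFFC ~= 1 > 0.7. The default "literal" mode removes an SV when any
carrier violates the type's condition; the alternative "support" mode
removes it only when no carrier meets the condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config import PipelineConfig
from .core import DepthTrack, GenomicInterval, Genotype, RegionSet, SampleMeta, SVRecord, ValidationError

log = logging.getLogger("svconfide")

STEP_NAMES = (
    "step1_size",
    "step2_regions",
    "step3_dhffc",
    "step4_dh_het",
    "step5_af",
    "step6_call_rate",
)


@dataclass
class FilterStepAudit:
    name: str
    n_in: int
    n_removed: int
    n_out: int
    removed_ids: list[str] = field(default_factory=list)


@dataclass
class FilterAudit:
    steps: list[FilterStepAudit] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return self.steps[0].n_in if self.steps else 0

    @property
    def n_retained(self) -> int:
        return self.steps[-1].n_out if self.steps else 0

    def removed_at(self, step_name: str) -> list[str]:
        for s in self.steps:
            if s.name == step_name:
                return s.removed_ids
        raise KeyError(step_name)

    def check(self) -> None:
        prev_out = None
        for s in self.steps:
            assert s.n_out == s.n_in - s.n_removed, f"audit arithmetic broken at {s.name}"
            if prev_out is not None:
                assert s.n_in == prev_out, f"audit chaining broken at {s.name}"
            prev_out = s.n_out

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "name": s.name,
                    "n_in": s.n_in,
                    "n_removed": s.n_removed,
                    "n_out": s.n_out,
                    "removed_ids": sorted(s.removed_ids),
                }
                for s in self.steps
            ],
            "n_input": self.n_input,
            "n_retained": self.n_retained,
        }


# ---------------------------------------------------------------------------
# DHFFC


def compute_dhffc(
    sv: SVRecord, depth: DepthTrack, flank: int = 1000
) -> float | None:
    """Depth fold change: median per-base depth inside the SV span divided by
    the median over the union of the two flanking regions.

    Flanks are ``flank`` bp on each side, clipped at chromosome ends.
    Returns None (undefined) when the flank median is zero.
    """
    if not depth.covers(sv.span):
        raise ValidationError(f"SV {sv.id} span outside the depth track")
    chrom_len = depth.chrom_lengths[sv.chrom]
    flanks = []
    if sv.start > 0:
        flanks.append(GenomicInterval(sv.chrom, max(0, sv.start - flank), sv.start))
    if sv.end < chrom_len:
        flanks.append(GenomicInterval(sv.chrom, sv.end, min(chrom_len, sv.end + flank)))
    if not flanks:
        return None
    flank_med = depth.median(flanks)
    if flank_med == 0:
        return None
    return depth.median([sv.span]) / flank_med


def annotate_dhffc(
    svs: Sequence[SVRecord],
    depths: Mapping[str, DepthTrack],
    flank: int = 1000,
    overwrite: bool = True,
) -> None:
    """Fill per-sample DHFFC on every call from per-sample depth tracks.

    Recomputed values win over values already present in the VCF; a
    disagreement is logged."""
    for sv in svs:
        for sample_id, call in sv.calls.items():
            val = compute_dhffc(sv, depths[sample_id], flank)
            # VCF serializes DHFFC to 6 significant digits; only a
            # disagreement beyond that precision is a real conflict
            if (
                call.dhffc is not None
                and val is not None
                and abs(call.dhffc - val) > 1e-4 * max(1.0, abs(val))
            ):
                log.warning(
                    "DHFFC conflict for %s/%s: VCF %.4g vs recomputed %.4g; using recomputed",
                    sv.id, sample_id, call.dhffc, val,
                )
            if overwrite or call.dhffc is None:
                call.dhffc = val


# ---------------------------------------------------------------------------
# per-site statistics


def allele_frequency(sv: SVRecord) -> float | None:
    """Alt-allele count over 2x the number of non-missing calls; None if all
    calls are missing."""
    alt = 0
    called = 0
    for call in sv.calls.values():
        c = call.genotype.alt_count
        if c is None:
            continue
        alt += c
        called += 1
    if called == 0:
        return None
    return alt / (2 * called)


def call_rate(sv: SVRecord) -> float:
    """Fraction of samples with a non-missing genotype."""
    if not sv.calls:
        return 0.0
    called = sum(1 for c in sv.calls.values() if c.genotype is not Genotype.MISSING)
    return called / len(sv.calls)


# ---------------------------------------------------------------------------
# filter steps; each returns (kept, removed)

Split = tuple[list[SVRecord], list[SVRecord]]


def _split(svs: Sequence[SVRecord], keep) -> Split:
    kept, removed = [], []
    for sv in svs:
        (kept if keep(sv) else removed).append(sv)
    return kept, removed


def step1_size(svs: Sequence[SVRecord], min_size: int = 300) -> Split:
    """Remove SVs with size strictly less than min_size."""
    return _split(svs, lambda sv: sv.size >= min_size)


def step2_regions(
    svs: Sequence[SVRecord], high_cov: RegionSet, gaps: RegionSet
) -> Split:
    """Remove SVs sharing >=1 base with a high-coverage region or a gap."""
    return _split(
        svs, lambda sv: not (high_cov.overlaps(sv.span) or gaps.overlaps(sv.span))
    )


def _dhffc_consistent(svtype: str, d: float | None, cfg: PipelineConfig) -> bool:
    """Does one carrier's DHFFC support (not violate) the SV type?

    Undefined DHFFC (None) is conservative: a violation in literal mode,
    non-support in support mode — both directions count it as False here."""
    if d is None:
        return False
    if svtype == "DEL":
        return d <= cfg.dhffc_del_max
    if svtype == "DUP":
        return d >= cfg.dhffc_dup_min
    return cfg.dhffc_inv_low <= d <= cfg.dhffc_inv_high  # INV


def step3_dhffc(svs: Sequence[SVRecord], cfg: PipelineConfig) -> Split:
    """Depth-consistency filter over carrier samples.

    literal mode (default): removed if any carrier violates the type's
    condition. support mode: removed if no carrier meets it."""

    def keep(sv: SVRecord) -> bool:
        carriers = sv.carriers().values()
        if not carriers:
            return True
        flags = [_dhffc_consistent(sv.svtype, c.dhffc, cfg) for c in carriers]
        if cfg.dhffc_mode == "literal":
            return all(flags)
        return any(flags)

    return _split(svs, keep)


def step4_dh_het(svs: Sequence[SVRecord], meta: Sequence[SampleMeta]) -> Split:
    """Remove SVs heterozygous in at least one doubled-haploid line."""
    dh_ids = [m.sample_id for m in meta if m.is_doubled_haploid]
    return _split(
        svs,
        lambda sv: not any(
            sv.calls[s].genotype is Genotype.HET for s in dh_ids if s in sv.calls
        ),
    )


def step5_af(svs: Sequence[SVRecord], af_min: float = 0.05, af_max: float = 0.95) -> Split:
    """Remove sites with AF < af_min or AF > af_max (strict inequalities)."""

    def keep(sv: SVRecord) -> bool:
        af = allele_frequency(sv)
        return af is not None and af_min <= af <= af_max

    return _split(svs, keep)


def step6_call_rate(svs: Sequence[SVRecord], min_rate: float = 0.8) -> Split:
    """Remove sites with genotype call rate strictly below min_rate."""
    return _split(svs, lambda sv: call_rate(sv) >= min_rate)


def run_cascade(
    svs: Sequence[SVRecord],
    high_cov: RegionSet,
    gaps: RegionSet,
    meta: Sequence[SampleMeta],
    cfg: PipelineConfig | None = None,
    depths: Mapping[str, DepthTrack] | None = None,
) -> tuple[list[SVRecord], FilterAudit]:
    """Apply steps 1-6 in published order and return (retained, audit).

    If depth tracks are supplied and cfg.recompute_dhffc is set, per-sample
    DHFFC is recomputed from depth before step 3 (recomputed values win over
    VCF annotations)."""
    cfg = cfg or PipelineConfig()
    if depths is not None and cfg.recompute_dhffc:
        annotate_dhffc(svs, depths, cfg.flank_size)
    audit = FilterAudit()
    current = list(svs)
    steps = [
        ("step1_size", lambda x: step1_size(x, cfg.min_sv_size)),
        ("step2_regions", lambda x: step2_regions(x, high_cov, gaps)),
        ("step3_dhffc", lambda x: step3_dhffc(x, cfg)),
        ("step4_dh_het", lambda x: step4_dh_het(x, meta)),
        ("step5_af", lambda x: step5_af(x, cfg.af_min, cfg.af_max)),
        ("step6_call_rate", lambda x: step6_call_rate(x, cfg.min_call_rate)),
    ]
    for name, fn in steps:
        kept, removed = fn(current)
        audit.steps.append(
            FilterStepAudit(
                name=name,
                n_in=len(current),
                n_removed=len(removed),
                n_out=len(kept),
                removed_ids=[sv.id for sv in removed],
            )
        )
        current = kept
    audit.check()
    return current, audit
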