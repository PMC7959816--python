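"""Seeded generator of a toy genome, TE library, truth SVs, cohort,
depth tracks, candidate VCF and long-read evidence.

Every downstream stage gets a known answer: the generator plants a genome
with embedded transposable-element copies (a 1,621 bp Tc1-mariner-like DNA
transposon, an LTR retrotransposon with a ~380 bp LTR, and a ~1,465 bp
unclassified element), implants DEL/DUP/INV variants segregating in three
diverged populations plus strictly homozygous doubled-haploid (DH) lines,
derives copy-number-consistent depth, and synthesizes split-read and
CIGAR-indel alignments for one designated DH line.

Labeled decoys are appended to the truth set, each constructed to fail
exactly one step of the filter cascade; two further labels mark variants
without long-read coverage and variants with single-read support, for
negative validation tests. Everything is deterministic under the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .config import PipelineConfig
from .core import (
    DepthTrack,
    Genotype,
    GenomicInterval,
    RegionSet,
    SampleCall,
    SampleMeta,
    SVRecord,
    normalize_regions,
)
from .filters import compute_dhffc
from .io import AlignmentRecord
from .regions import combine_problem_regions, low_complexity_regions

log = logging.getLogger("svconfide")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CASCADE_DECOY_LABELS = (
    "step1_size",
    "step2_regions",
    "step3_dhffc",
    "step4_dh_het",
    "step5_af",
    "step6_call_rate",
)
UNCOVERED_LABEL = "uncovered_by_longreads"


@dataclass
class TEFamily:
    name: str
    te_class: str  # DNA_transposon | LTR_retrotransposon | unclassified
    sequence: str
    ltr: str | None = None

    def __post_init__(self) -> None:
        assert len(self.sequence) >= 50
        if self.ltr is not None:
            assert self.sequence.startswith(self.ltr)


@dataclass
class TruthSV:
    id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    svtype: str
    pop_afs: dict[str, float]
    te_origin: str | None = None
    decoy_label: str | None = None

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def is_cascade_decoy(self) -> bool:
        return self.decoy_label in CASCADE_DECOY_LABELS


@dataclass
class SyntheticBundle:
    """Internally consistent toy data set for the whole pipeline."""

    genome: dict[str, str]
    chrom_lengths: dict[str, int]
    te_library: list[TEFamily]
    repeats: list[tuple[GenomicInterval, str, str]]
    gaps: RegionSet
    planted: list[tuple[str, int, int, str, str]]  # chrom,start,end,family,kind
    truth: list[TruthSV]
    meta: list[SampleMeta]
    genotypes: dict[str, dict[str, Genotype]]  # sv_id -> sample -> gt
    depths: dict[str, DepthTrack]
    records: list[SVRecord]  # candidate call set with GT + DHFFC
    alignments: list[AlignmentRecord]
    designated_dh: str
    single_read_ids: set[str] = field(default_factory=set)
    highcov_region: GenomicInterval | None = None

    @property
    def uncovered_ids(self) -> set[str]:
        return {t.id for t in self.truth if t.decoy_label == UNCOVERED_LABEL}

    @property
    def filter_pass_ids(self) -> set[str]:
        """Truth ids expected to survive the cascade (everything that is not
        one of the six cascade decoys)."""
        return {t.id for t in self.truth if not t.is_cascade_decoy}

    def truth_by_id(self, sv_id: str) -> TruthSV:
        return next(t for t in self.truth if t.id == sv_id)


# ---------------------------------------------------------------------------
# TE library and genome


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def make_te_library(seed: int) -> list[TEFamily]:
    """Three-family TE library: a 1,621 bp DNA-transposon analog, an LTR
    retrotransposon analog with a 380 bp LTR, and a 1,465 bp unclassified
    element. Deterministic under seed."""
    rng = np.random.default_rng(seed)
    tc1m = TEFamily("tc1m_analog", "DNA_transposon", _random_seq(rng, 1621))
    ltr = _random_seq(rng, 380)
    gypsy = TEFamily(
        "gypsy_analog", "LTR_retrotransposon", ltr + _random_seq(rng, 3420), ltr=ltr
    )
    unk = TEFamily("unk_analog", "unclassified", _random_seq(rng, 1465))
    return [tc1m, gypsy, unk]


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    chrom_len: int,
    length: int,
    margin: int = 50,
    retries: int = 2000,
    lo: int = 2000,
) -> int | None:
    """Find a start for a non-overlapping placement, or None."""
    hi = chrom_len - length - 2000
    if hi <= lo:
        return None
    for _ in range(retries):
        s = int(rng.integers(lo, hi))
        e = s + length
        if all(e + margin <= os or s >= oe + margin for os, oe in occupied):
            occupied.append((s, e))
            return s
    return None


def build_genome(
    te_library: list[TEFamily],
    n_chrom: int = 3,
    chrom_len: int = 500_000,
    te_density: float = 0.08,
    n_gaps: int = 3,
    seed: int = 0,
    n_lowcplx_per_chrom: int = 6,
) -> tuple[dict[str, str], list[tuple[GenomicInterval, str, str]], RegionSet, list]:
    """Random background with planted TE copies, low-complexity runs, and
    N-gaps. Returns (genome, repeat annotation, gaps, planting log).

    te_density is the target fraction of each chromosome covered by TE
    copies. The annotation exactly matches the planted content; for the LTR
    family both full-length and solo-LTR copies are planted (solo LTRs
    dominate, as in fish genomes where most LTR elements persist as solo
    LTRs)."""
    if chrom_len < 50_000:
        raise ValueError("chrom_len must be >= 50,000")
    rng = np.random.default_rng(seed)
    fams = {f.name: f for f in te_library}
    gypsy = fams["gypsy_analog"]
    # (family, kind, sequence) placement menu with sampling weights
    menu = [
        ("tc1m_analog", "full", fams["tc1m_analog"].sequence, 0.50),
        ("gypsy_analog", "ltr", gypsy.ltr, 0.25),
        ("gypsy_analog", "full", gypsy.sequence, 0.05),
        ("unk_analog", "full", fams["unk_analog"].sequence, 0.20),
    ]
    weights = np.array([m[3] for m in menu])
    weights = weights / weights.sum()

    genome: dict[str, str] = {}
    repeats: list[tuple[GenomicInterval, str, str]] = []
    gap_pairs: list[tuple[str, int, int]] = []
    planted: list[tuple[str, int, int, str, str]] = []
    gaps_left = n_gaps
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        arr = np.frombuffer(_random_seq(rng, chrom_len).encode(), dtype=np.uint8).copy()
        occupied: list[tuple[int, int]] = []
        # TE copies up to the density target
        target = te_density * chrom_len
        placed_bp = 0
        fails = 0
        while placed_bp < target:
            fam, kind, seq, _w = menu[int(rng.choice(len(menu), p=weights))]
            s = _place(rng, occupied, chrom_len, len(seq))
            if s is None:
                fails += 1
                if fails > 50:
                    raise RuntimeError(
                        f"TE placement failed on {chrom}: density {te_density} too high"
                    )
                continue
            arr[s : s + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)
            cls = fams[fam].te_class
            repeats.append((GenomicInterval(chrom, s, s + len(seq)), cls, fam))
            planted.append((chrom, s, s + len(seq), fam, kind))
            placed_bp += len(seq)
        # low-complexity runs: poly-A and AT/CAG microsatellites
        motifs = ["A", "AT", "CAG"]
        for i in range(n_lowcplx_per_chrom):
            length = int(rng.integers(80, 400))
            motif = motifs[int(rng.integers(0, len(motifs)))]
            s = _place(rng, occupied, chrom_len, length)
            if s is None:
                continue
            run = (motif * (length // len(motif) + 1))[:length]
            arr[s : s + length] = np.frombuffer(run.encode(), dtype=np.uint8)
            cls = "Low_complexity" if motif == "A" else "Simple_repeat"
            repeats.append((GenomicInterval(chrom, s, s + length), cls, ""))
        # assembly gaps (N runs)
        if gaps_left > 0:
            n_here = max(1, n_gaps // n_chrom) if ci < n_chrom - 1 else gaps_left
            n_here = min(n_here, gaps_left)
            for _ in range(n_here):
                length = int(rng.integers(500, 1000))
                s = _place(rng, occupied, chrom_len, length)
                if s is None:
                    continue
                arr[s : s + length] = ord("N")
                gap_pairs.append((chrom, s, s + length))
                gaps_left -= 1
        genome[chrom] = arr.tobytes().decode()
    repeats.sort(key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    return genome, repeats, RegionSet.from_pairs(gap_pairs), planted


# ---------------------------------------------------------------------------
# truth SVs and decoys


def _balding_nichols(
    rng: np.random.Generator, p_anc: float, fst: float, n_pops: int
) -> np.ndarray:
    """Per-population allele frequencies from the Balding-Nichols model."""
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return np.clip(rng.beta(a, b, n_pops), 0.02, 0.98)


def implant_truth_svs(
    genome: Mapping[str, str],
    te_library: list[TEFamily],
    planted: Sequence[tuple[str, int, int, str, str]],
    avoid: RegionSet,
    pop_names: Sequence[str],
    counts: Mapping[str, int] | None = None,
    te_del_fraction: float = 0.4,
    divergence: float = 0.1,
    seed: int = 0,
    highcov_region: GenomicInterval | None = None,
    with_decoys: bool = True,
    spacing: int = 2200,
    margin: int = 1100,
) -> list[TruthSV]:
    """Implant truth SVs: mostly deletions (mirroring the ~95/5/<1 per cent
    DEL/DUP/INV proportions of high-confidence short-read call sets), a
    configurable fraction of which delete exactly one full planted TE copy,
    driving transposon-length size peaks.

    Implants keep ``margin`` bp clear of the avoid mask and ``spacing`` bp
    from each other so that depth flanks stay at baseline. Six labeled
    decoys are appended, each constructed to fail exactly one cascade step.
    """
    counts = dict(counts or {"DEL": 100, "DUP": 5, "INV": 2})
    rng = np.random.default_rng(seed)
    chrom_lens = {c: len(s) for c, s in genome.items()}
    taken: list[GenomicInterval] = []
    if highcov_region is not None:
        taken.append(highcov_region)

    def clear(chrom: str, s: int, e: int, pad: int) -> bool:
        iv = GenomicInterval(chrom, max(0, s - margin), e + margin)
        if avoid.overlaps(iv):
            return False
        return all(
            t.chrom != chrom or e + pad <= t.start or s >= t.end + pad for t in taken
        )

    svs: list[TruthSV] = []
    sv_i = 0

    def add(chrom: str, s: int, e: int, svtype: str, te: str | None = None,
            label: str | None = None, af: float | None = None) -> TruthSV:
        nonlocal sv_i
        sv_i += 1
        if af is None:
            p_anc = float(rng.uniform(0.25, 0.75))
            pop_af = _balding_nichols(rng, p_anc, divergence, len(pop_names))
        else:
            pop_af = np.full(len(pop_names), af)
        t = TruthSV(
            id=f"sv{sv_i:04d}" if label is None else f"decoy_{label}",
            chrom=chrom, start=s, end=e, svtype=svtype,
            pop_afs={p: float(a) for p, a in zip(pop_names, pop_af)},
            te_origin=te, decoy_label=label,
        )
        svs.append(t)
        taken.append(t.span)
        return t

    def random_site(length: int, label: str | None = None, svtype: str = "DEL",
                    te: str | None = None, af: float | None = None) -> TruthSV:
        for _ in range(3000):
            chrom = f"chr{int(rng.integers(1, len(chrom_lens) + 1))}"
            s = int(rng.integers(3000, chrom_lens[chrom] - length - 3000))
            if clear(chrom, s, s + length, spacing):
                return add(chrom, s, s + length, svtype, te=te, label=label, af=af)
        raise RuntimeError("implant placement failed: genome too crowded")

    # --- TE-origin deletions: delete exactly one full planted copy
    n_del = counts.get("DEL", 0)
    n_te = int(round(te_del_fraction * n_del))
    fam_quota = {"tc1m_analog": n_te // 2, "gypsy_analog": n_te // 4}
    fam_quota["unk_analog"] = n_te - sum(fam_quota.values())
    order = rng.permutation(len(planted))
    candidates = [planted[i] for i in order]
    placed_te = 0
    for chrom, s, e, fam, kind in candidates:
        if fam_quota.get(fam, 0) <= 0:
            continue
        if fam == "gypsy_analog" and kind != "ltr":
            continue  # solo-LTR deletions only: full-length Gypsy losses are not seen
        if not clear(chrom, s, e, spacing):
            continue
        add(chrom, s, e, "DEL", te=fam)
        fam_quota[fam] -= 1
        placed_te += 1
    # --- background deletions: sizes from a shifted exponential so ~90%
    # fall under 3 kb
    for _ in range(n_del - placed_te):
        size = 300 + int(rng.exponential(1172.0))
        size = min(size, 20_000)
        random_site(size)
    for _ in range(counts.get("DUP", 0)):
        size = 500 + int(rng.exponential(1500.0))
        random_site(min(size, 20_000), svtype="DUP")
    for _ in range(counts.get("INV", 0)):
        size = 500 + int(rng.exponential(2000.0))
        random_site(min(size, 20_000), svtype="INV")

    if with_decoys:
        random_site(299, label="step1_size")
        if highcov_region is None:
            raise ValueError("decoys requested but no high-coverage region given")
        hc = highcov_region
        add(hc.chrom, hc.start + 200, hc.start + 1200, "DEL", label="step2_regions")
        random_site(1000, label="step3_dhffc")
        random_site(1000, label="step4_dh_het")
        random_site(1000, label="step5_af", af=0.02)
        random_site(1000, label="step6_call_rate")
    svs.sort(key=lambda t: (t.chrom, t.start, t.id))
    return svs


# ---------------------------------------------------------------------------
# cohort genotypes


def simulate_cohort(
    truth: Sequence[TruthSV],
    pops: Mapping[str, int],
    n_dh: int = 4,
    seed: int = 0,
    af_min: float = 0.05,
    af_max: float = 0.95,
) -> tuple[dict[str, dict[str, Genotype]], list[SampleMeta]]:
    """Draw genotypes: outbred samples Hardy-Weinberg from their population
    AF, DH lines strictly homozygous (a doubled gamete). Non-decoy sites are
    redrawn until the realized AF passes the frequency filter and at least
    one carrier exists, honouring the truth-set invariant that unlabeled
    variants pass every filter by construction."""
    rng = np.random.default_rng(seed)
    meta: list[SampleMeta] = []
    for pop, n in pops.items():
        meta += [SampleMeta(f"{pop}_{i + 1:02d}", pop, False) for i in range(n)]
    meta += [SampleMeta(f"DH{i + 1:02d}", "DH", True) for i in range(n_dh)]
    n_samples = len(meta)
    dh_ids = [m.sample_id for m in meta if m.is_doubled_haploid]

    gts_by_code = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)

    def draw(t: TruthSV) -> dict[str, Genotype]:
        af_mean = float(np.mean(list(t.pop_afs.values())))
        out: dict[str, Genotype] = {}
        for m in meta:
            if m.is_doubled_haploid:
                out[m.sample_id] = (
                    Genotype.HOM_ALT if rng.random() < af_mean else Genotype.HOM_REF
                )
            else:
                p = t.pop_afs[m.population]
                out[m.sample_id] = gts_by_code[int(rng.binomial(2, p))]
        return out

    def realized_af(g: Mapping[str, Genotype]) -> float:
        alts = [x.alt_count for x in g.values() if x.alt_count is not None]
        return sum(alts) / (2 * len(alts)) if alts else 0.0

    genotypes: dict[str, dict[str, Genotype]] = {}
    for t in truth:
        if t.decoy_label == "step5_af":
            k = int(round(0.02 * 2 * n_samples))  # target AF 0.02
            g = {m.sample_id: Genotype.HOM_REF for m in meta}
            outbred = [m.sample_id for m in meta if not m.is_doubled_haploid]
            for sid in rng.choice(outbred, size=k, replace=False):
                g[sid] = Genotype.HET
        elif t.decoy_label == "step6_call_rate":
            n_missing = int(np.ceil(0.3 * n_samples))
            for _ in range(500):
                g = draw(t)
                drop = rng.choice(n_samples, size=n_missing, replace=False)
                for i in drop:
                    g[meta[i].sample_id] = Genotype.MISSING
                if af_min <= realized_af(g) <= af_max:
                    break
        elif t.decoy_label == "step4_dh_het":
            for _ in range(500):
                g = draw(t)
                g[dh_ids[0]] = Genotype.HET
                if af_min <= realized_af(g) <= af_max:
                    break
        else:
            ok = False
            for _ in range(500):
                g = draw(t)
                af = realized_af(g)
                if af_min <= af <= af_max and any(x.is_carrier for x in g.values()):
                    ok = True
                    break
            if not ok:
                raise RuntimeError(f"could not realize a passing genotype vector for {t.id}")
        genotypes[t.id] = g
    return genotypes, meta


# ---------------------------------------------------------------------------
# depth


_COPY_NUMBER = {
    ("DEL", Genotype.HET): 1,
    ("DEL", Genotype.HOM_ALT): 0,
    ("DUP", Genotype.HET): 3,
    ("DUP", Genotype.HOM_ALT): 4,
}


def _overlay(
    segs: list[tuple[int, int, float]], patch: tuple[int, int, float]
) -> list[tuple[int, int, float]]:
    ps, pe, pd = patch
    out: list[tuple[int, int, float]] = []
    for s, e, d in segs:
        if e <= ps or s >= pe:
            out.append((s, e, d))
            continue
        if s < ps:
            out.append((s, ps, d))
        if e > pe:
            out.append((pe, e, d))
    out.append((ps, pe, pd))
    out.sort()
    return out


def simulate_depth(
    truth: Sequence[TruthSV],
    genotypes: Mapping[str, Mapping[str, Genotype]],
    meta: Sequence[SampleMeta],
    chrom_lengths: Mapping[str, int],
    baseline_cov: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    highcov_region: GenomicInterval | None = None,
    highcov_depth: float = 250.0,
    noise_window: int = 100,
) -> dict[str, DepthTrack]:
    """Per-sample depth = baseline x local copy number / 2 (DEL het 1 copy,
    hom-alt 0; DUP het 3, hom-alt 4; INV copy-neutral), with optional
    window-level truncated Gaussian noise.

    The DHFFC-decoy variant gets copy-neutral depth in every sample; the
    high-coverage decoy region is forced to ``highcov_depth`` in all
    samples."""
    if baseline_cov <= 0:
        raise ValueError("baseline_cov must be positive")
    rng = np.random.default_rng(seed)
    tracks: dict[str, DepthTrack] = {}
    for m in meta:
        segs: dict[str, list[tuple[int, int, float]]] = {
            c: [(0, L, float(baseline_cov))] for c, L in chrom_lengths.items()
        }
        for t in truth:
            if t.decoy_label == "step3_dhffc":
                continue  # copy-neutral on purpose: DHFFC will contradict the call
            gt = genotypes[t.id][m.sample_id]
            cn = _COPY_NUMBER.get((t.svtype, gt))
            if cn is None:
                continue  # hom-ref, missing, or copy-neutral INV
            segs[t.chrom] = _overlay(
                segs[t.chrom], (t.start, t.end, baseline_cov * cn / 2.0)
            )
        if highcov_region is not None:
            segs[highcov_region.chrom] = _overlay(
                segs[highcov_region.chrom],
                (highcov_region.start, highcov_region.end, float(highcov_depth)),
            )
        if noise_sd > 0:
            noisy: dict[str, list[tuple[int, int, float]]] = {}
            for chrom, lst in segs.items():
                acc = []
                for s, e, d in lst:
                    for ws in range(s, e, noise_window):
                        we = min(e, ws + noise_window)
                        nd = max(0.0, round(d + rng.normal(0.0, noise_sd)))
                        acc.append((ws, we, nd))
                noisy[chrom] = acc
            segs = noisy
        tracks[m.sample_id] = DepthTrack(segs, chrom_lengths)
    return tracks


# ---------------------------------------------------------------------------
# candidate VCF records


def emit_candidate_records(
    truth: Sequence[TruthSV],
    genotypes: Mapping[str, Mapping[str, Genotype]],
    depths: Mapping[str, DepthTrack],
    meta: Sequence[SampleMeta],
    flank: int = 1000,
) -> list[SVRecord]:
    """One candidate SVRecord per truth variant, with per-sample genotype
    and DHFFC computed from the simulated depth. Ids carry truth ids so
    evaluations can join back."""
    records = []
    for t in truth:
        rec = SVRecord(id=t.id, chrom=t.chrom, start=t.start, end=t.end, svtype=t.svtype)
        for m in meta:
            gt = genotypes[t.id][m.sample_id]
            rec.calls[m.sample_id] = SampleCall(
                genotype=gt, dhffc=compute_dhffc(rec, depths[m.sample_id], flank)
            )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# long reads


def simulate_long_reads(
    truth: Sequence[TruthSV],
    genotypes: Mapping[str, Mapping[str, Genotype]],
    sample_id: str,
    reads_per_sv: int = 3,
    jitter_sd: float = 20.0,
    seed: int = 0,
    slop: int = 100,
    uncovered_ids: set[str] | frozenset = frozenset(),
    single_read_ids: set[str] | frozenset = frozenset(),
    adversarial: bool = False,
    segment_len: int = 500,
) -> list[AlignmentRecord]:
    """Synthesize alignments carrying breakpoint evidence for every SV that
    is hom-alt in ``sample_id``.

    Deletions get CIGAR-deletion reads (one record with a D op spanning the
    event) plus split-read pairs; duplications and inversions get split-read
    pairs only. Breakpoints are jittered by a rounded Gaussian clamped to
    +/-(slop-1) so matching succeeds by the slop criterion by construction;
    with ``adversarial=True`` both breakpoints are shifted beyond slop and
    beyond the reciprocal-overlap tolerance, so nothing should match.
    Uncovered SVs get no reads; single-read SVs get exactly one.
    """
    rng = np.random.default_rng(seed)
    out: list[AlignmentRecord] = []

    def jit(size: int) -> int:
        if adversarial:
            return max(slop + 1, size // 8 + 1)
        j = int(round(rng.normal(0.0, jitter_sd)))
        return max(-(slop - 1), min(slop - 1, j))

    for t in sorted(truth, key=lambda t: t.id):
        if t.id in uncovered_ids or t.decoy_label == UNCOVERED_LABEL:
            continue
        if genotypes[t.id][sample_id] is not Genotype.HOM_ALT:
            continue
        n_reads = 1 if t.id in single_read_ids else reads_per_sv
        for i in range(n_reads):
            rid = f"{t.id}_rd{i + 1}"
            j1, j2 = jit(t.size), jit(t.size)
            if t.svtype == "DEL":
                d = (t.end + j2) - (t.start + j1)
                out.append(
                    AlignmentRecord(
                        read_id=rid, chrom=t.chrom,
                        pos=t.start + j1 - segment_len + 1, strand="+",
                        cigar=f"{segment_len}M{d}D{segment_len}M",
                    )
                )
                continue
            if t.svtype == "DUP":
                # read crosses the tandem junction: copy ends at t.end then
                # restarts at t.start (backward reference jump)
                a = (t.end + j1 - segment_len, "+", False)
                b = (t.start + j2, "+", True)
            else:  # INV: strand flip at the junction
                a = (t.start + j1 - segment_len, "+", False)
                b = (t.end + j2, "-", True)
            sa_a = (t.chrom, a[0] + 1, a[1], f"{segment_len}M")
            sa_b = (t.chrom, b[0] + 1, b[1], f"{segment_len}M")
            out.append(
                AlignmentRecord(
                    read_id=rid, chrom=t.chrom, pos=a[0] + 1, strand=a[1],
                    cigar=f"{segment_len}M", is_supplementary=a[2],
                    supplementary_tags=[sa_b],
                )
            )
            out.append(
                AlignmentRecord(
                    read_id=rid, chrom=t.chrom, pos=b[0] + 1, strand=b[1],
                    cigar=f"{segment_len}M", is_supplementary=b[2],
                    supplementary_tags=[sa_a],
                )
            )
        # split-read pairs for covered deletions as well (in addition to
        # the CIGAR reads): emitted as separate reads
        if t.svtype == "DEL" and t.id not in single_read_ids:
            for i in range(reads_per_sv):
                rid = f"{t.id}_sp{i + 1}"
                j1, j2 = jit(t.size), jit(t.size)
                a_pos = t.start + j1 - segment_len
                b_pos = t.end + j2
                out.append(
                    AlignmentRecord(
                        read_id=rid, chrom=t.chrom, pos=a_pos + 1, strand="+",
                        cigar=f"{segment_len}M",
                        supplementary_tags=[(t.chrom, b_pos + 1, "+", f"{segment_len}M")],
                    )
                )
                out.append(
                    AlignmentRecord(
                        read_id=rid, chrom=t.chrom, pos=b_pos + 1, strand="+",
                        cigar=f"{segment_len}M", is_supplementary=True,
                        supplementary_tags=[(t.chrom, a_pos + 1, "+", f"{segment_len}M")],
                    )
                )
    return out


# ---------------------------------------------------------------------------
# bundle assembly


def make_bundle(
    seed: int = 0,
    n_chrom: int = 3,
    chrom_len: int = 500_000,
    counts: Mapping[str, int] | None = None,
    pops: Mapping[str, int] | None = None,
    n_dh: int = 4,
    baseline_cov: float = 30.0,
    noise_sd: float = 0.0,
    divergence: float = 0.1,
    te_density: float = 0.08,
    n_gaps: int = 3,
    te_del_fraction: float = 0.4,
    reads_per_sv: int = 3,
    jitter_sd: float = 20.0,
    n_uncovered: int = 2,
    n_single_read: int = 2,
    adversarial_reads: bool = False,
    cfg: PipelineConfig | None = None,
) -> SyntheticBundle:
    """Build the full default study bundle (deterministic under seed)."""
    cfg = cfg or PipelineConfig()
    pops = dict(pops or {"POP1": 20, "POP2": 20, "POP3": 20})
    root = np.random.default_rng(seed)
    sub = [int(s) for s in root.integers(0, 2**31 - 1, 8)]

    te_library = make_te_library(sub[0])
    genome, repeats, gaps, planted = build_genome(
        te_library, n_chrom=n_chrom, chrom_len=chrom_len,
        te_density=te_density, n_gaps=n_gaps, seed=sub[1],
    )
    chrom_lengths = {c: len(s) for c, s in genome.items()}

    # pick the planted >=200x decoy region on chr1, clear of gaps/implant sites
    rng_hc = np.random.default_rng(sub[2])
    highcov = None
    for _ in range(1000):
        s = int(rng_hc.integers(5000, chrom_lengths["chr1"] - 7000))
        iv = GenomicInterval("chr1", s, s + 2000)
        probe = GenomicInterval("chr1", s - 1500, s + 3500)
        if not gaps.overlaps(probe):
            highcov = iv
            break
    assert highcov is not None

    low_cplx = low_complexity_regions(
        repeats, cfg.region_merge_gap, cfg.min_lowcomplexity_len, cfg.lowcomplexity_classes
    )
    avoid = combine_problem_regions(
        normalize_regions([highcov]), low_cplx, gaps, cfg.region_merge_gap
    )

    truth = implant_truth_svs(
        genome, te_library, planted, avoid, list(pops),
        counts=counts, te_del_fraction=te_del_fraction,
        divergence=divergence, seed=sub[3], highcov_region=highcov,
    )
    genotypes, meta = simulate_cohort(
        truth, pops, n_dh=n_dh, seed=sub[4], af_min=cfg.af_min, af_max=cfg.af_max
    )
    designated_dh = next(m.sample_id for m in meta if m.is_doubled_haploid)

    # flag long-read-uncovered and single-read variants among the designated
    # line's hom-alt non-decoy set
    homalt = sorted(
        t.id for t in truth
        if t.decoy_label is None and genotypes[t.id][designated_dh] is Genotype.HOM_ALT
    )
    for sv_id in homalt[:n_uncovered]:
        next(t for t in truth if t.id == sv_id).decoy_label = UNCOVERED_LABEL
    single_read_ids = set(homalt[n_uncovered : n_uncovered + n_single_read])

    depths = simulate_depth(
        truth, genotypes, meta, chrom_lengths,
        baseline_cov=baseline_cov, noise_sd=noise_sd, seed=sub[5],
        highcov_region=highcov,
    )
    records = emit_candidate_records(truth, genotypes, depths, meta, cfg.flank_size)
    alignments = simulate_long_reads(
        truth, genotypes, designated_dh,
        reads_per_sv=reads_per_sv, jitter_sd=jitter_sd, seed=sub[6],
        slop=cfg.slop, single_read_ids=single_read_ids,
        adversarial=adversarial_reads,
    )
    return SyntheticBundle(
        genome=genome, chrom_lengths=chrom_lengths, te_library=te_library,
        repeats=repeats, gaps=gaps, planted=planted, truth=truth, meta=meta,
        genotypes=genotypes, depths=depths, records=records,
        alignments=alignments, designated_dh=designated_dh,
        single_read_ids=single_read_ids, highcov_region=highcov,
    )


def simulate_genotype_cohort(
    n_svs: int = 500,
    pops: Mapping[str, int] | None = None,
    divergence: float = 0.1,
    seed: int = 0,
) -> tuple[list[SVRecord], list[SampleMeta]]:
    """Light-weight genotype-only cohort (no genome) for population-structure
    work: Balding-Nichols population AFs, Hardy-Weinberg genotypes."""
    pops = dict(pops or {"POP1": 20, "POP2": 20, "POP3": 20})
    rng = np.random.default_rng(seed)
    meta = [
        SampleMeta(f"{pop}_{i + 1:02d}", pop, False)
        for pop, n in pops.items()
        for i in range(n)
    ]
    gts = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)
    records = []
    for i in range(n_svs):
        p_anc = float(rng.uniform(0.1, 0.9))
        pop_af = dict(zip(pops, _balding_nichols(rng, p_anc, divergence, len(pops))))
        rec = SVRecord(
            id=f"pca{i:04d}", chrom="chrP", start=1000 + 2000 * i,
            end=2000 + 2000 * i, svtype="DEL",
        )
        for m in meta:
            rec.calls[m.sample_id] = SampleCall(
                genotype=gts[int(rng.binomial(2, pop_af[m.population]))]
            )
        records.append(rec)
    return records, meta


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, str]:
    """Emit every bundle artifact as text files; returns a manifest."""
    from . import io as fmt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fmt.write_fasta(bundle.genome, out / "genome.fasta")
    fmt.write_fasta(
        {f.name: f.sequence for f in bundle.te_library}, out / "te_library.fasta"
    )
    fmt.write_repeats(bundle.repeats, out / "repeats.tsv")
    fmt.write_bed(bundle.gaps, out / "gaps.bed")
    fmt.write_sample_meta(bundle.meta, out / "samples.tsv")
    depth_dir = out / "depth"
    depth_dir.mkdir(exist_ok=True)
    for sid, track in bundle.depths.items():
        fmt.write_depth(track, depth_dir / f"{sid}.bedgraph")
    fmt.write_sv_vcf(
        bundle.records, out / "candidates.vcf",
        sample_ids=[m.sample_id for m in bundle.meta],
        contigs=bundle.chrom_lengths,
    )
    fmt.write_sam(bundle.alignments, out / "longreads.sam", bundle.chrom_lengths)
    lines = ["id\tchrom\tstart\tend\tsvtype\tsize\tte_origin\tdecoy_label"]
    for t in bundle.truth:
        lines.append(
            f"{t.id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.svtype}\t{t.size}"
            f"\t{t.te_origin or '.'}\t{t.decoy_label or '.'}"
        )
    fmt._write_text(out / "truth.tsv", lines)
    return {
        "genome": str(out / "genome.fasta"),
        "te_library": str(out / "te_library.fasta"),
        "repeats": str(out / "repeats.tsv"),
        "gaps": str(out / "gaps.bed"),
        "samples": str(out / "samples.tsv"),
        "depth_dir": str(depth_dir),
        "vcf": str(out / "candidates.vcf"),
        "sam": str(out / "longreads.sam"),
        "truth": str(out / "truth.tsv"),
    }
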