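"""Readers and writers for the formats the pipeline touches.

VCF is read through cyvcf2 and SAM through pysam; BED, BEDPE, bedgraph
depth, repeat tables and sample metadata are simple tab-separated dialects
written by deterministic emitters so pipeline outputs are byte-stable and
diffable.
"""

from __future__ import annotations

import logging
import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    BreakpointPair,
    DepthTrack,
    Genotype,
    GenomicInterval,
    RegionSet,
    SampleCall,
    SampleMeta,
    SVRecord,
    SV_TYPES,
    ValidationError,
)

log = logging.getLogger("svconfide")

_CIGAR_RE = re.compile(r"^(?:\d+[MIDNSHP=X])+$")


@dataclass
class AlignmentRecord:
    """One SAM alignment line (columns 1-6 plus the SA tag).

    ``supplementary_tags`` lists (chrom, pos, strand, cigar) of the other
    segments of a split alignment as declared by the SA tag.
    """

    read_id: str
    chrom: str
    pos: int  # 1-based leftmost mapped position
    strand: str
    cigar: str
    is_supplementary: bool = False
    supplementary_tags: list[tuple[str, int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not _CIGAR_RE.match(self.cigar):
            raise ValidationError(f"unparsable CIGAR {self.cigar!r} for read {self.read_id}")

    @property
    def ref_start(self) -> int:
        """0-based reference start."""
        return self.pos - 1

    @property
    def ref_end(self) -> int:
        """0-based exclusive reference end (start + span of M/D/N/=/X ops)."""
        return self.ref_start + cigar_reference_span(self.cigar)


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    if not _CIGAR_RE.match(cigar):
        raise ValidationError(f"unparsable CIGAR {cigar!r}")
    return [(int(n), op) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)]


def cigar_reference_span(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in "MDN=X")


# ---------------------------------------------------------------------------
# VCF


def read_sv_vcf(path: str | Path, samples: list[SampleMeta]) -> list[SVRecord]:
    """Read a multi-sample SV VCF into SVRecords (internal half-open coords).

    Unsupported SVTYPEs (BND, INS, ...) are skipped with a logged count.
    Genotypes map 0/0->hom_ref, 0/1|1/0->het, 1/1->hom_alt, ./.->missing;
    half-calls are rejected. A per-sample DHFFC FORMAT field is read when
    present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    expected = [m.sample_id for m in samples]
    if list(vcf.samples) != expected:
        raise ValidationError(
            f"VCF sample columns {list(vcf.samples)} do not match metadata {expected}"
        )
    records: list[SVRecord] = []
    skipped: dict[str, int] = {}
    for v in vcf:
        svtype = v.INFO.get("SVTYPE")
        if svtype is None:
            log.warning("record at %s:%s has no SVTYPE; rejected", v.CHROM, v.POS)
            skipped["missing_SVTYPE"] = skipped.get("missing_SVTYPE", 0) + 1
            continue
        if svtype not in SV_TYPES:
            skipped[svtype] = skipped.get(svtype, 0) + 1
            continue
        start = v.POS - 1
        end = v.INFO.get("END")
        svlen = v.INFO.get("SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        if end is None:
            if svlen is None:
                log.warning("record %s has neither END nor SVLEN; rejected", v.ID)
                skipped["missing_END"] = skipped.get("missing_END", 0) + 1
                continue
            end = start + abs(int(svlen))
        size = end - start
        if svlen is not None and abs(int(svlen)) != size:
            log.warning(
                "record %s: SVLEN %s disagrees with END-derived size %d; using SVLEN",
                v.ID, svlen, size,
            )
            size = abs(int(svlen))
        try:
            dh = v.format("DHFFC")
        except KeyError:  # field absent from the header
            dh = None
        calls: dict[str, SampleCall] = {}
        for i, meta in enumerate(samples):
            a = v.genotypes[i][:-1]
            alleles = [x for x in a]
            if any(x < 0 for x in alleles):
                if not all(x < 0 for x in alleles):
                    raise ValidationError(f"half-call at {v.ID} sample {meta.sample_id}")
                gt = Genotype.MISSING
            else:
                n_alt = sum(1 for x in alleles if x > 0)
                gt = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n_alt]
            dval = None
            if dh is not None:
                x = float(dh[i][0])
                if np.isfinite(x) and x >= 0:
                    dval = x
            calls[meta.sample_id] = SampleCall(genotype=gt, dhffc=dval)
        records.append(
            SVRecord(
                id=v.ID or f"{v.CHROM}_{v.POS}_{svtype}",
                chrom=v.CHROM, start=start, end=int(end), svtype=svtype,
                calls=calls, size=int(size),
            )
        )
    if skipped:
        log.info("read_sv_vcf: skipped records by reason: %s", skipped)
    return records


_GT_STR = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_sv_vcf(
    svs: list[SVRecord],
    path: str | Path,
    sample_ids: list[str] | None = None,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write SVRecords as a sorted VCF 4.2 subset (byte-stable)."""
    if sample_ids is None:
        sample_ids = list(svs[0].calls) if svs else []
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DHFFC,Number=1,Type=Float,Description="Depth fold change relative to flanks">',
    ]
    for chrom in sorted(contigs or {}):
        lines.append(f"##contig=<ID={chrom},length={(contigs or {})[chrom]}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    for sv in sorted(svs, key=lambda s: (s.chrom, s.start, s.id)):
        svlen = -sv.size if sv.svtype == "DEL" else sv.size
        info = f"SVTYPE={sv.svtype};END={sv.end};SVLEN={svlen}"
        cols = [
            sv.chrom, str(sv.pos), sv.id, "N", f"<{sv.svtype}>", ".", "PASS",
            info, "GT:DHFFC",
        ]
        for sid in sample_ids:
            call = sv.calls[sid]
            d = "." if call.dhffc is None else f"{call.dhffc:.6g}"
            cols.append(f"{_GT_STR[call.genotype]}:{d}")
        lines.append("\t".join(cols))
    _write_text(path, lines)


# ---------------------------------------------------------------------------
# BED / BEDPE / depth / repeats / metadata


def _write_text(path: str | Path, lines: list[str]) -> None:
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    except OSError as exc:
        raise ValidationError(f"cannot write {path}: {exc}") from exc


def write_bed(rs: RegionSet, path: str | Path) -> None:
    _write_text(path, [f"{iv.chrom}\t{iv.start}\t{iv.end}" for iv in rs.intervals()])


def read_bed(path: str | Path) -> RegionSet:
    pairs = []
    for line in _read_lines(path):
        c, s, e = line.split("\t")[:3]
        pairs.append((c, int(s), int(e)))
    return RegionSet.from_pairs(pairs)


def write_bedpe(pairs: Iterable[BreakpointPair], path: str | Path) -> None:
    """10-column BEDPE: chrom1,start1,end1,chrom2,start2,end2,name,score,strand1,strand2.

    Strand columns are '.' — breakpoint matching is strand-insensitive."""
    lines = []
    for bp in pairs:
        lines.append(
            f"{bp.chrom}\t{bp.left.start}\t{bp.left.end}\t"
            f"{bp.chrom}\t{bp.right.start}\t{bp.right.end}\t"
            f"{bp.source};{bp.svtype}\t0\t.\t."
        )
    _write_text(path, lines)


def read_bedpe(path: str | Path) -> list[BreakpointPair]:
    out = []
    for line in _read_lines(path):
        f = line.split("\t")
        name = f[6]
        source, _, svtype = name.rpartition(";")
        out.append(
            BreakpointPair(
                chrom=f[0],
                left=GenomicInterval(f[0], int(f[1]), int(f[2])),
                right=GenomicInterval(f[3], int(f[4]), int(f[5])),
                svtype=svtype, source=source,
            )
        )
    return out


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]


def read_depth(
    path: str | Path, chrom_lengths: Mapping[str, int] | None = None
) -> DepthTrack:
    """Read a 4-column bedgraph-like depth file; uncovered bases are depth 0.

    Overlapping intervals with conflicting values are fatal."""
    segs: dict[str, list[tuple[int, int, float]]] = {}
    for line in _read_lines(path):
        c, s, e, d = line.split("\t")[:4]
        segs.setdefault(c, []).append((int(s), int(e), float(d)))
    return DepthTrack(segs, chrom_lengths)


def write_depth(track: DepthTrack, path: str | Path) -> None:
    lines = []
    for chrom in sorted(track.segments):
        for s, e, d in track.segments[chrom]:
            dv = f"{d:.6g}" if d != int(d) else str(int(d))
            lines.append(f"{chrom}\t{s}\t{e}\t{dv}")
    _write_text(path, lines)


def read_repeats(path: str | Path) -> list[tuple[GenomicInterval, str, str]]:
    """Read a BED-like repeat annotation: chrom, start, end, class[, family]."""
    out = []
    for line in _read_lines(path):
        f = line.split("\t")
        fam = f[4] if len(f) > 4 else ""
        out.append((GenomicInterval(f[0], int(f[1]), int(f[2])), f[3], fam))
    return out


def write_repeats(repeats: list[tuple[GenomicInterval, str, str]], path: str | Path) -> None:
    lines = [
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cls}\t{fam}"
        for iv, cls, fam in sorted(repeats, key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    ]
    _write_text(path, lines)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """TSV with header sample_id, population, is_dh."""
    lines = _read_lines(path)
    out = []
    for line in lines:
        f = line.split("\t")
        if f[0] == "sample_id":
            continue
        out.append(SampleMeta(f[0], f[1], f[2].lower() in ("1", "true", "yes")))
    ids = [m.sample_id for m in out]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids in metadata")
    return out


def write_sample_meta(meta: list[SampleMeta], path: str | Path) -> None:
    lines = ["sample_id\tpopulation\tis_dh"]
    lines += [
        f"{m.sample_id}\t{m.population}\t{int(m.is_doubled_haploid)}" for m in meta
    ]
    _write_text(path, lines)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Named sequences, uppercase-normalized."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# SAM


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Read a SAM-dialect text file into AlignmentRecords via pysam.

    Unmapped records are dropped. A headerless file is handled by
    synthesizing @SQ lines from the observed reference names before handing
    the text back to pysam. Records with unparsable CIGARs are rejected with
    a logged warning.
    """
    import pysam

    path = str(path)
    with open(path) as fh:
        text = fh.read()
    if "@SQ" not in text:
        chroms: list[str] = []
        for line in text.splitlines():
            if line.startswith("@") or not line.strip():
                continue
            rname = line.split("\t")[2]
            if rname != "*" and rname not in chroms:
                chroms.append(rname)
        header = "".join(f"@SQ\tSN:{c}\tLN:536870911\n" for c in chroms)
        tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
        tmp.write(header + text)
        tmp.close()
        path = tmp.name
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigarstring is None:
                continue
            sa: list[tuple[str, int, str, str]] = []
            if aln.has_tag("SA"):
                for part in str(aln.get_tag("SA")).rstrip(";").split(";"):
                    c, p, st, cg = part.split(",")[:4]
                    sa.append((c, int(p), st, cg))
            try:
                out.append(
                    AlignmentRecord(
                        read_id=aln.query_name,
                        chrom=aln.reference_name,
                        pos=aln.reference_start + 1,
                        strand="-" if aln.is_reverse else "+",
                        cigar=aln.cigarstring,
                        is_supplementary=aln.is_supplementary,
                        supplementary_tags=sa,
                    )
                )
            except ValidationError as exc:
                log.warning("rejected alignment: %s", exc)
    return out


def write_sam(
    alignments: list[AlignmentRecord],
    path: str | Path,
    chrom_lengths: Mapping[str, int],
) -> None:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(chrom_lengths):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}")
    for a in alignments:
        flag = 0
        if a.strand == "-":
            flag |= 16
        if a.is_supplementary:
            flag |= 2048
        cols = [a.read_id, str(flag), a.chrom, str(a.pos), "60", a.cigar, "*", "0", "0", "*", "*"]
        if a.supplementary_tags:
            sa = "".join(f"{c},{p},{st},{cg},60,0;" for c, p, st, cg in a.supplementary_tags)
            cols.append(f"SA:Z:{sa}")
        lines.append("\t".join(cols))
    _write_text(path, lines)


def group_by_read(alignments: list[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    """Resolve supplementary linkage: group records into logical reads by id,
    preserving file order (generator and aligner emit segments in read order)."""
    groups: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        groups.setdefault(a.read_id, []).append(a)
    return groups
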