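#!/usr/bin/env python
"""Profile the retained SV set: counts, spacing, size peaks, repeat/TE
content, TE-library identity and genotype PCA.

Writes the per-sample counts, per-chromosome spacing, deletion size
histogram with flagged peaks, repeat-content table, TE classifications of
peak-range deletions, and the top-10 PC coordinates under results/profile/.
"""

from pathlib import Path

import pandas as pd

from svconfide import io as fmt
from svconfide.config import PipelineConfig
from svconfide.profiles import (
    chromosome_spacing,
    classify_vs_te_library,
    pca_genotypes,
    per_sample_counts,
    repeat_content,
    size_histogram,
    sv_sequence,
)
from svconfide.synth import TEFamily

ROOT = Path(__file__).resolve().parent.parent / "results"


def load_te_library(path: Path) -> list[TEFamily]:
    seqs = fmt.read_fasta(path)
    classes = {"tc1m_analog": "DNA_transposon", "gypsy_analog": "LTR_retrotransposon",
               "unk_analog": "unclassified"}
    lib = []
    for name, seq in seqs.items():
        ltr = seq[:380] if classes.get(name) == "LTR_retrotransposon" else None
        lib.append(TEFamily(name, classes.get(name, "unclassified"), seq, ltr=ltr))
    return lib


def main() -> None:
    cfg = PipelineConfig()
    out = ROOT / "profile"
    out.mkdir(parents=True, exist_ok=True)
    meta = fmt.read_sample_meta(ROOT / "synthetic" / "samples.tsv")
    retained = fmt.read_sv_vcf(ROOT / "retained.vcf", meta)
    genome = fmt.read_fasta(ROOT / "synthetic" / "genome.fasta")
    repeats = fmt.read_repeats(ROOT / "synthetic" / "repeats.tsv")
    te_lib = load_te_library(ROOT / "synthetic" / "te_library.fasta")
    chrom_lengths = {c: len(s) for c, s in genome.items()}

    counts = per_sample_counts(retained, meta)
    pd.Series(counts, name="n_svs").rename_axis("sample_id").to_csv(
        out / "counts.tsv", sep="\t")
    print(f"per-sample SV counts: min {min(counts.values())}, "
          f"max {max(counts.values())}")

    spacing = chromosome_spacing(retained, chrom_lengths)
    pd.Series(spacing, name="kb_per_sv").rename_axis("chrom").to_csv(
        out / "spacing.tsv", sep="\t")
    print("spacing (kb/SV):", {c: round(v, 1) for c, v in spacing.items() if v})

    dels = [sv for sv in retained if sv.svtype == "DEL"]
    hist = size_histogram(dels, cfg.histogram_bin, cfg.peak_factor)
    pd.DataFrame(
        [{"lo": hist.bin_range(i)[0], "hi": hist.bin_range(i)[1],
          "count": c, "peak": i in hist.peak_bins}
         for i, c in enumerate(hist.counts)]
    ).to_csv(out / "histogram.tsv", sep="\t", index=False)
    top = sorted(hist.peak_bins, key=lambda i: -hist.counts[i])[:3]
    print("top deletion size peaks:",
          [(hist.bin_range(i), hist.counts[i]) for i in top])

    rep = repeat_content(retained, repeats)
    rep.to_frame().to_csv(out / "repeat_content.tsv", sep="\t", index=False)
    print(f"masked fraction overall: {rep.overall['fraction']:.3f} "
          f"({ {t: round(v['fraction'], 3) for t, v in rep.by_type.items()} })")

    peak_ranges = [hist.bin_range(i) for i in hist.peak_bins]
    calls = []
    for sv in dels:
        if any(lo <= sv.size < hi for lo, hi in peak_ranges):
            hit = classify_vs_te_library(sv_sequence(genome, sv), te_lib,
                                         cfg.identity_full, cfg.identity_partial)
            calls.append({"id": sv.id, "size": sv.size,
                          "family": hit[0] if hit else ".",
                          "kind": hit[1] if hit else ".",
                          "identity": round(hit[2], 4) if hit else None})
    pd.DataFrame(calls).to_csv(out / "te_calls.tsv", sep="\t", index=False)
    classified = [c for c in calls if c["family"] != "."]
    print(f"TE classification of peak-range deletions: "
          f"{len(classified)}/{len(calls)} assigned "
          f"({pd.Series([c['kind'] for c in classified]).value_counts().to_dict()})")

    coords = pca_genotypes(retained, meta, cfg.n_pcs)
    coords.rename_axis("sample_id").to_csv(out / "pca.tsv", sep="\t")
    pops = pd.Series({m.sample_id: m.population for m in meta})
    print("PC1 mean by population:",
          coords["PC1"].groupby(pops.reindex(coords.index)).mean().round(2).to_dict())


if __name__ == "__main__":
    main()
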