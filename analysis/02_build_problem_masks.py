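#!/usr/bin/env python
"""Build the three problematic-region masks from the simulated artifacts.

Reads the per-sample depth tracks, the repeat annotation and the genome
FASTA written by 01_simulate_cohort.py, derives the high-coverage (>=200x),
low-complexity and assembly-gap masks plus their 1 kb-merged combination,
and writes them as BED under results/masks/.
"""

from pathlib import Path

from svconfide import io as fmt
from svconfide.config import PipelineConfig
from svconfide.regions import (
    assembly_gaps,
    combine_problem_regions,
    high_coverage_multi,
    low_complexity_regions,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig()
    genome = fmt.read_fasta(ROOT / "synthetic" / "genome.fasta")
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    depths = {
        p.stem: fmt.read_depth(p, chrom_lengths)
        for p in sorted((ROOT / "synthetic" / "depth").glob("*.bedgraph"))
    }
    repeats = fmt.read_repeats(ROOT / "synthetic" / "repeats.tsv")

    high_cov = high_coverage_multi(depths, cfg.high_cov_threshold, cfg.high_cov_mode)
    low_cplx = low_complexity_regions(
        repeats, cfg.region_merge_gap, cfg.min_lowcomplexity_len,
        cfg.lowcomplexity_classes)
    gaps = assembly_gaps(genome)
    combined = combine_problem_regions(high_cov, low_cplx, gaps, cfg.region_merge_gap)

    out = ROOT / "masks"
    out.mkdir(parents=True, exist_ok=True)
    for name, rs in (("highcov", high_cov), ("lowcplx", low_cplx),
                     ("gaps", gaps), ("combined", combined)):
        fmt.write_bed(rs, out / f"{name}.bed")
        print(f"{name}: {len(rs)} intervals, {rs.total_length} bp "
              f"-> {out / f'{name}.bed'}")


if __name__ == "__main__":
    main()
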