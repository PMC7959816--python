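"""End-to-end orchestration: simulate -> regions -> filter -> validate ->
profile, with a machine-readable run report.

The run report echoes the configuration, carries the filter audit and the
validation summary, lists every file written, and records per-stage status.
Identical config + seed produce identical outputs; timestamps are excluded
from the diffable report body.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import io as fmt
from .config import PipelineConfig
from .core import Genotype, RegionSet, SVRecord
from .filters import run_cascade
from .profiles import (
    chromosome_spacing,
    classify_vs_te_library,
    pca_genotypes,
    per_sample_counts,
    repeat_content,
    size_histogram,
    sv_sequence,
)
from .regions import (
    assembly_gaps,
    combine_problem_regions,
    high_coverage_multi,
    low_complexity_regions,
)
from .synth import SyntheticBundle, make_bundle, write_bundle
from .validation import summarize, validate

log = logging.getLogger("svconfide")

GENERATOR_KEYS = (
    "n_chrom", "chrom_len", "counts", "pops", "n_dh", "baseline_cov",
    "noise_sd", "divergence", "te_density", "n_gaps", "te_del_fraction",
    "reads_per_sv", "jitter_sd", "n_uncovered", "n_single_read",
)


@dataclass
class RunReport:
    config: dict
    rng_seed: int
    stages: dict[str, str] = field(default_factory=dict)  # name -> ok/failed
    filter_audit: dict | None = None
    validation_summary: list[dict] | None = None
    manifest: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "rng_seed": self.rng_seed,
                "stages": self.stages,
                "filter_audit": self.filter_audit,
                "validation_summary": self.validation_summary,
                "manifest": self.manifest,
            },
            indent=2,
            sort_keys=True,
        )


def load_config(path: str | Path) -> dict:
    """Flat TOML config mirroring PipelineConfig field names plus run keys
    (simulate, outdir, input paths, generator overrides)."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def run_all(config: dict | str | Path, outdir: str | Path | None = None) -> RunReport:
    """Execute the full pipeline per config; returns the run report (also
    written to <outdir>/report.json)."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir or config.get("outdir", "svconfide_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_fields = {
        k: v for k, v in config.items()
        if k in PipelineConfig.__dataclass_fields__
    }
    cfg = PipelineConfig.from_dict(cfg_fields)
    seed = int(config.get("rng_seed", cfg.rng_seed))
    report = RunReport(config=dict(config), rng_seed=seed)

    def stage(name: str):
        def wrap(fn):
            try:
                fn()
                report.stages[name] = "ok"
            except Exception:
                report.stages[name] = "failed"
                (outdir / "report.json").write_text(report.to_json())
                log.exception("stage %s failed", name)
                raise
            return fn

        return wrap

    state: dict[str, Any] = {}

    @stage("simulate")
    def _simulate():
        if config.get("simulate", True):
            gen_kwargs = {k: config[k] for k in GENERATOR_KEYS if k in config}
            bundle = make_bundle(seed=seed, cfg=cfg, **gen_kwargs)
            manifest = write_bundle(bundle, outdir / "synthetic")
            report.manifest.update({f"synthetic_{k}": v for k, v in manifest.items()})
            state["bundle"] = bundle
        else:
            for key in ("vcf", "meta"):
                if key not in config or not Path(config[key]).exists():
                    raise FileNotFoundError(
                        f"simulate=false requires an existing '{key}' path in the config"
                    )
            state["bundle"] = None

    @stage("regions")
    def _regions():
        bundle: SyntheticBundle | None = state["bundle"]
        if bundle is not None:
            genome = bundle.genome
            repeats = bundle.repeats
            depths = bundle.depths
            state["meta"] = bundle.meta
            state["records"] = bundle.records
        else:
            state["meta"] = fmt.read_sample_meta(config["meta"])
            state["records"] = fmt.read_sv_vcf(config["vcf"], state["meta"])
            genome = fmt.read_fasta(config["fasta"]) if "fasta" in config else {}
            repeats = fmt.read_repeats(config["repeats"]) if "repeats" in config else []
            depths = {}
            if "depth_dir" in config:
                for p in sorted(Path(config["depth_dir"]).glob("*.bedgraph")):
                    depths[p.stem] = fmt.read_depth(p)
        high_cov = high_coverage_multi(depths, cfg.high_cov_threshold, cfg.high_cov_mode) \
            if depths else RegionSet()
        if "highcov_bed" in config:
            high_cov = high_cov.union(fmt.read_bed(config["highcov_bed"]))
        low_cplx = low_complexity_regions(
            repeats, cfg.region_merge_gap, cfg.min_lowcomplexity_len,
            cfg.lowcomplexity_classes,
        )
        gaps = assembly_gaps(genome)
        combined = combine_problem_regions(high_cov, low_cplx, gaps, cfg.region_merge_gap)
        for name, rs in (
            ("highcov", high_cov), ("lowcplx", low_cplx),
            ("gaps", gaps), ("combined", combined),
        ):
            path = outdir / f"{name}.bed"
            fmt.write_bed(rs, path)
            report.manifest[f"regions_{name}"] = str(path)
        state.update(high_cov=high_cov, gaps=gaps, genome=genome,
                     repeats=repeats, depths=depths)

    @stage("filter")
    def _filter():
        retained, audit = run_cascade(
            state["records"], state["high_cov"], state["gaps"], state["meta"],
            cfg, depths=state["depths"] or None,
        )
        report.filter_audit = audit.to_dict()
        state["retained"] = retained
        path = outdir / "retained.vcf"
        bundle = state["bundle"]
        fmt.write_sv_vcf(
            retained, path,
            sample_ids=[m.sample_id for m in state["meta"]],
            contigs=bundle.chrom_lengths if bundle else None,
        )
        report.manifest["retained_vcf"] = str(path)
        (outdir / "filter_audit.json").write_text(
            json.dumps(audit.to_dict(), indent=2, sort_keys=True)
        )
        report.manifest["filter_audit"] = str(outdir / "filter_audit.json")

    @stage("validate")
    def _validate():
        bundle = state["bundle"]
        sample = config.get(
            "designated_sample", bundle.designated_dh if bundle else None
        )
        alignments = (
            bundle.alignments if bundle
            else (fmt.read_alignments(config["sam"]) if "sam" in config else [])
        )
        if sample is None or not alignments:
            report.validation_summary = []
            state["candidates"] = []
            return
        candidates = [
            sv for sv in state["retained"]
            if sv.calls.get(sample) and sv.calls[sample].genotype is Genotype.HOM_ALT
        ]
        rep = validate(candidates, alignments, cfg)
        rows = summarize(rep)
        report.validation_summary = rows
        state["candidates"] = candidates
        path = outdir / "validation.tsv"
        import pandas as pd

        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        report.manifest["validation_report"] = str(path)

    @stage("profile")
    def _profile():
        import pandas as pd

        retained: list[SVRecord] = state["retained"]
        meta = state["meta"]
        counts = per_sample_counts(retained, meta)
        pd.Series(counts, name="n_svs").rename_axis("sample_id").to_csv(
            outdir / "counts.tsv", sep="\t"
        )
        chrom_lengths = (
            state["bundle"].chrom_lengths if state["bundle"]
            else {c: len(s) for c, s in state["genome"].items()}
        )
        if chrom_lengths:
            spacing = chromosome_spacing(retained, chrom_lengths)
            pd.Series(spacing, name="kb_per_sv").rename_axis("chrom").to_csv(
                outdir / "spacing.tsv", sep="\t"
            )
        dels = [sv for sv in retained if sv.svtype == "DEL"]
        hist = size_histogram(dels, cfg.histogram_bin, cfg.peak_factor)
        rows = [
            {"lo": hist.bin_range(i)[0], "hi": hist.bin_range(i)[1],
             "count": c, "peak": i in hist.peak_bins}
            for i, c in enumerate(hist.counts)
        ]
        pd.DataFrame(rows).to_csv(outdir / "histogram.tsv", sep="\t", index=False)
        rep = repeat_content(retained, state["repeats"])
        rep.to_frame().to_csv(outdir / "repeat_content.tsv", sep="\t", index=False)
        bundle = state["bundle"]
        if bundle is not None and state["genome"]:
            peak_ranges = [hist.bin_range(i) for i in hist.peak_bins]
            calls = []
            for sv in dels:
                if any(lo <= sv.size < hi for lo, hi in peak_ranges):
                    hit = classify_vs_te_library(
                        sv_sequence(state["genome"], sv), bundle.te_library,
                        cfg.identity_full, cfg.identity_partial,
                    )
                    calls.append(
                        {"id": sv.id, "size": sv.size,
                         "family": hit[0] if hit else ".",
                         "kind": hit[1] if hit else ".",
                         "identity": round(hit[2], 4) if hit else float("nan")}
                    )
            pd.DataFrame(calls).to_csv(outdir / "te_calls.tsv", sep="\t", index=False)
            report.manifest["te_calls"] = str(outdir / "te_calls.tsv")
        try:
            coords = pca_genotypes(retained, meta, cfg.n_pcs)
            coords.rename_axis("sample_id").to_csv(outdir / "pca.tsv", sep="\t")
            report.manifest["pca"] = str(outdir / "pca.tsv")
        except ValueError as exc:
            log.warning("PCA skipped: %s", exc)
        for name in ("counts", "spacing", "histogram", "repeat_content"):
            report.manifest[name] = str(outdir / f"{name}.tsv")

    (outdir / "report.json").write_text(report.to_json())
    report.manifest["report"] = str(outdir / "report.json")
    return report
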