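"""Pipeline configuration: every published threshold as a named, overridable field."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class PipelineConfig:
    """All thresholds used by the masking, filtering, validation and
    profiling stages.

    Defaults are the published values: SVs under 300 bp removed; regions at
    or above 200x coverage masked; problematic regions closer than 1,000 bp
    merged; low-complexity intervals kept only when longer than 200 bp;
    deletion carriers must show DHFFC <= 0.7, duplication carriers >= 1.3,
    inversion carriers within [0.7, 1.3]; sites with AF < 0.05 or > 0.95 or
    call rate < 0.8 dropped; long-read breakpoints matched with 100 bp slop
    or 90% reciprocal overlap and >=2 supporting reads; CIGAR indels count
    only above 50 bp; DHFFC flanks are 1,000 bp; PCA keeps the top 10 PCs.
    """

    min_sv_size: int = 300
    high_cov_threshold: float = 200.0
    region_merge_gap: int = 1000
    min_lowcomplexity_len: int = 200  # strictly greater retained
    dhffc_del_max: float = 0.7
    dhffc_dup_min: float = 1.3
    dhffc_inv_low: float = 0.7
    dhffc_inv_high: float = 1.3
    af_min: float = 0.05
    af_max: float = 0.95
    min_call_rate: float = 0.8
    slop: int = 100
    reciprocal_fraction: float = 0.9
    min_support_reads: int = 2
    min_cigar_indel: int = 50  # strictly greater used
    flank_size: int = 1000
    n_pcs: int = 10
    histogram_bin: int = 20
    identity_full: float = 0.95
    identity_partial: float = 0.80
    rng_seed: int = 0
    # mode switches (see methods note)
    dhffc_mode: str = "literal"  # or "support"
    high_cov_mode: str = "union"  # or "mean"
    lowcomplexity_classes: tuple[str, ...] = ("Low_complexity", "Simple_repeat")
    recompute_dhffc: bool = True
    peak_factor: float = 3.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name != "rng_seed" and isinstance(v, (int, float)) and not isinstance(v, bool):
                if v <= 0:
                    raise ValueError(f"{f.name} must be positive, got {v}")
        if not self.af_min < self.af_max:
            raise ValueError("af_min must be < af_max")
        if not self.dhffc_inv_low < self.dhffc_inv_high:
            raise ValueError("dhffc_inv_low must be < dhffc_inv_high")
        if self.dhffc_mode not in ("literal", "support"):
            raise ValueError(f"unknown dhffc_mode {self.dhffc_mode!r}")
        if self.high_cov_mode not in ("union", "mean"):
            raise ValueError(f"unknown high_cov_mode {self.high_cov_mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "lowcomplexity_classes" in d:
            d["lowcomplexity_classes"] = tuple(d["lowcomplexity_classes"])
        return cls(**d)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out
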