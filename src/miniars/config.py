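"""Pipeline configuration: every knob of the end-to-end synthetic analysis,
serializable to YAML and validated before any stage runs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # cohort composition: preset name -> number of fragments
    loci: dict = field(default_factory=lambda: {
        "ars317_like": 150, "nonpartitioning": 150})
    fragment_length_range: tuple = (100, 200)

    # competition sampling
    acen_timepoints: tuple = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 25.0)
    cen_timepoints: tuple = (0.0, 30.0)
    depth: int = 1_000_000

    # mechanistic simulator
    crowding_penalty: float = 1.0
    noise_sd: float = 0.05
    hours_per_generation: float = 2.0
    n_lineages: int = 8
    init_copies: int = 4
    cen_pf_floor: float = 0.95

    # mutational scanning
    mutscan_rate: float = 0.012
    mutscan_n_oligos: int = 10_000
    mutscan_span: tuple = (-56, 96)

    # analysis thresholds
    pseudocount: float = 0.5
    n_bins: int = 3
    coverage_threshold: float = 0.80
    corner_size: int = 3
    diag_band: int = 1
    delta_threshold: float = 0.4
    min_region_len: int = 8
    window_width: int = 50
    window_step: int = 25
    scan_range: tuple = (-50, 175)
    alpha: float = 0.05
    min_ars: int = 10
    min_fold: float = 2.0
    enrich_p_cutoff: float = 0.01

    seed: int = 0
    outdir: str = "results/pipeline"

    def validate(self) -> None:
        if not self.loci:
            raise ValueError("at least one locus is required")
        lo, hi = self.fragment_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid fragment length range")
        for name, tps in (("acen", self.acen_timepoints), ("cen", self.cen_timepoints)):
            t = [float(x) for x in tps]
            if t != sorted(set(t)) or not t or t[0] != 0.0:
                raise ValueError(f"{name} timepoints must increase from 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.crowding_penalty < 0 or self.noise_sd < 0:
            raise ValueError("crowding penalty and noise must be nonnegative")
        if not (0 <= self.mutscan_rate < 1):
            raise ValueError("mutagenesis rate must lie in [0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if not (0 < self.coverage_threshold <= 1):
            raise ValueError("coverage threshold must lie in (0, 1]")
        if not (1 <= self.corner_size <= 5):
            raise ValueError("corner_size must lie in 1..5")
        if self.diag_band < 0:
            raise ValueError("diag_band must be nonnegative")
        if not (0 < self.delta_threshold <= 1):
            raise ValueError("delta threshold must lie in (0, 1]")
        if self.min_region_len < 1 or self.window_width < 1 or self.window_step < 1:
            raise ValueError("region/window sizes must be >= 1")
        if not (0 <= self.alpha <= 1 and 0 < self.enrich_p_cutoff <= 1):
            raise ValueError("p-value cutoffs must lie in [0, 1]")
        if self.min_ars < 1 or self.min_fold < 0:
            raise ValueError("invalid enrichment thresholds")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        # YAML round-trips lists, not tuples
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cfg = cls(**d)
        for name in ("fragment_length_range", "acen_timepoints", "cen_timepoints",
                     "mutscan_span", "scan_range"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.validate()
        return cfg
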