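"""Run configuration.

Every pipeline constant is a named, documented default here; no analysis code
hard-codes a threshold. The defaults encode the published protocol this
toolkit re-implements: 50 kb / 10 kb diversity windows, a 100 bp sweep-scan
grid with a top-1% composite-likelihood cut, merged regions larger than
300 bp associated to genes within a 5 kb flank (top 3% of genes), a 10-read
coverage floor for methylation sites, the 50%-of-potential-sites rule for
region means, 40 gene-body bins with 250 bp overlap, 250/125 bp flank bins
over 10 kb flanks, a -300/+50 bp TSS window, 50 random gene sets for the
enrichment null and a BH false-discovery rate of 0.2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # diversity windows
    window_size_bp: int = 50_000
    step_bp: int = 10_000
    # sweep scan
    grid_bp: int = 100
    clr_top_fraction: float = 0.01
    min_region_bp: int = 300
    gene_flank_bp: int = 5_000
    gene_top_fraction: float = 0.03
    scan_radius_bp: int = 25_000
    alpha_min: float = 1e-7
    alpha_max: float = 1e-1
    alpha_grid_per_decade: int = 3
    n_distance_bins: int = 64
    max_gap_grid_units: int = 1
    per_chromosome_threshold: bool = False
    sfs_pseudocount: float = 0.5
    # methylome
    min_site_reads: int = 10
    min_region_site_fraction: float = 0.5
    min_tss_sites: int = 10
    body_bins: int = 40
    body_bin_overlap_bp: int = 250
    flank_bin_bp: int = 250
    flank_bin_overlap_bp: int = 125
    flank_span_bp: int = 10_000
    tss_upstream_bp: int = 300
    tss_downstream_bp: int = 50
    # enrichment
    n_random_sets: int = 50
    enrich_alpha: float = 0.05
    # multiple testing
    fdr: float = 0.2
    # randomness
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lengths = (
            self.window_size_bp, self.step_bp, self.grid_bp, self.min_region_bp,
            self.gene_flank_bp, self.scan_radius_bp, self.body_bins,
            self.body_bin_overlap_bp, self.flank_bin_bp, self.flank_bin_overlap_bp,
            self.flank_span_bp, self.tss_upstream_bp, self.tss_downstream_bp,
            self.min_site_reads, self.min_tss_sites, self.n_random_sets,
            self.n_distance_bins,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths and counts must be positive")
        for frac in (self.clr_top_fraction, self.gene_top_fraction,
                     self.min_region_site_fraction, self.fdr, self.enrich_alpha):
            if not (0.0 < frac < 1.0):
                raise ValueError(f"fractions must lie in (0,1), got {frac}")
        if self.window_size_bp < self.step_bp:
            raise ValueError("window_size_bp must be >= step_bp")
        if not (0.0 < self.alpha_min < self.alpha_max):
            raise ValueError("alpha range must satisfy 0 < alpha_min < alpha_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


DEFAULT_CONFIG = RunConfig()
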