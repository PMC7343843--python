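"""Pipeline configuration: every threshold of every stage in one audited
place, with the published defaults, YAML round-tripping and strict key
validation."""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All stage toggles, thresholds and paths.

    Defaults are the published analysis values; thresholds are never
    hard-coded at call sites — stages read them from here.
    """

    # stage toggles
    run_simulate: bool = True
    run_dupexon: bool = True
    run_sexassign: bool = True
    run_pooldiv: bool = True
    run_segment: bool = True
    run_ancestry: bool = True

    # duplicate-exon scan
    max_gap: int = 5000
    min_coverage: float = 0.5
    max_evalue: float = 1e-10
    score_threshold: float = 4.8

    # sex assignment
    subsample_step: int = 100
    percentile_cut: float = 0.999
    min_male_depth: float = 5.0
    min_female_depth: float = 2.0
    min_positions: int = 100
    alpha_level: float = 0.01

    # pool diversity
    window: int = 10_000
    min_analyzed: int = 9000
    min_cov: int = 4
    max_cov: int = 250
    pool_size: int = 50
    min_minor: int = 2

    # segmentation
    open_thresh: float = 0.005
    close_thresh: float = 0.001
    run_length: int = 5

    # ancestry
    min_depth: int = 20
    max_depth: int = 250
    min_diff: float = 0.2

    # simulation scenario
    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 100_000
    n_exons: int = 16
    n_planted: int = 3
    dup_length: int = 300
    n_cov_contigs: int = 60
    n_cov_x: int = 3
    cov_contig_length: int = 50_000
    mean_depth_f: float = 18.0
    mean_depth_m: float = 21.0
    dispersion: float = 5.0
    theta_true: float = 0.005
    pool_mean_depth: float = 50.0
    n_sites: int = 200_000
    n_aims: int = 5000
    switch_prob: float = 1e-3
    alpha_target: float = 0.78
    freq_divergence: float = 0.5
    aim_depth: float = 50.0

    # paths
    out_dir: str = "asmqc_out"
    fasta: str | None = None
    gff3: str | None = None
    female_depth: str | None = None
    male_depth: str | None = None
    pool_counts: str | None = None
    aims: str | None = None
    rate_track: str | None = None
    contig_classes: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected by name, missing keys
    take the published defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    valid = {f.name: f.type for f in fields(PipelineConfig)}
    unknown = set(data) - set(valid)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    defaults = PipelineConfig()
    for key, value in data.items():
        ref = getattr(defaults, key)
        if ref is not None and value is not None:
            if isinstance(ref, bool) != isinstance(value, bool):
                raise ConfigError(f"config key {key!r}: expected bool, got {type(value).__name__}")
            if isinstance(ref, (int, float)) and not isinstance(value, (int, float)):
                raise ConfigError(
                    f"config key {key!r}: expected number, got {type(value).__name__}"
                )
            if isinstance(ref, str) and not isinstance(value, str):
                raise ConfigError(f"config key {key!r}: expected string, got {type(value).__name__}")
    return PipelineConfig(**data)
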