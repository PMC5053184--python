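"""Configuration objects and their plain-text (YAML) serialisation.

All numeric defaults that mirror the study design live here: minimum
coverage 8x, 0.2 stable-site standard deviation, 150-400 bp MspI size
selection, 49 bp reads, 25 % methylation-difference / q < 0.01 differential
cutoffs, >= 5 detected CGs per island, 1500 bp promoters, +/- 10 kb profile
flanks and q < 0.05 for expression correlation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class LandscapeParams:
    """Beta-mixture parameters of the per-context methylation landscape.

    CG sites draw from a low/high bimodal Beta mixture whose high-mode weight
    depends on the genomic compartment; non-CG sites draw from a single
    low-mean Beta.  ``block_bp`` introduces regional correlation: sites in the
    same block share one mixture-mode draw, emulating the focal character of
    CG methylation.
    """

    cg_low_mean: float = 0.08
    cg_high_mean: float = 0.85
    cg_concentration: float = 30.0  # Beta a+b within each mode
    # probability that a CG block is in the high-methylation mode, per compartment
    p_high_background: float = 0.75
    p_high_cgi: float = 0.15
    p_high_shore: float = 0.45
    p_high_repeat: float = 0.92
    noncg_mean: float = 0.015
    noncg_concentration: float = 60.0
    block_bp: int = 300
    shore_bp: int = 2000
    dyad_symmetric: bool = True
    # oocyte-like coupling of non-CG means to local CG methylation
    oocyte_mode: bool = False
    oocyte_coupling: float = 0.25
    # elevated methylation of CG islands near chromosome ends
    telomere_bp: int = 0
    telomere_p_high: float = 0.85
    # tissue effects: regions whose CG dyads are shifted in one sample each
    # (differential methylation is regional in real tissues, e.g. a promoter
    # island hypomethylated in a single tissue)
    n_tissue_regions: int = 40
    tissue_region_bp: int = 600
    tissue_shift: float = 0.6
    tissue_promoter_fraction: float = 0.5

    def validate(self) -> None:
        for name in ("cg_low_mean", "cg_high_mean", "noncg_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("p_high_background", "p_high_cgi", "p_high_shore",
                     "p_high_repeat", "telomere_p_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class ExpressionParams:
    """Promoter methylation -> expression coupling on the log2 scale."""

    baseline_log2: float = 5.0
    coupling: float = 6.0  # log2 units per unit promoter methylation
    noise_sd: float = 0.5


@dataclass
class GenomeParams:
    n_chromosomes: int = 2
    chromosome_bp: int = 1_000_000
    gc_content: float = 0.42
    cgi_per_mb: int = 30
    cgi_length: tuple = (500, 2000)
    cgi_cg_fraction: float = 0.22  # fraction of CGI positions seeded as CG dinucleotides
    genes_per_mb: int = 30
    gene_length: tuple = (2000, 10000)
    promoter_cgi_fraction: float = 0.7
    repeats_per_mb: int = 20
    repeat_length: tuple = (300, 1500)
    repeat_divergence: float = 0.10
    spike_in_bp: int = 4000
    spike_in_name: str = "spike"


@dataclass
class SimulationConfig:
    """Everything the simulator needs; deterministic given ``seed``."""

    seed: int = 1
    genome: GenomeParams = field(default_factory=GenomeParams)
    size_range: tuple = (150, 400)
    read_length: int = 49
    depth: float = 30.0  # mean read pairs per retained fragment
    conversion_rate: float = 0.993
    paired_end: bool = True
    landscape: LandscapeParams = field(default_factory=LandscapeParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    samples: tuple = tuple(f"S{i:02d}" for i in range(1, 11))

    def validate(self) -> None:
        if not 0.0 <= self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate outside [0, 1]")
        lo, hi = self.size_range
        if not lo < hi:
            raise ValueError("size_range.min must be < size_range.max")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        self.landscape.validate()


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters; defaults mirror the study thresholds."""

    outdir: str = "rrbs_out"
    seed: int = 1
    min_cov: int = 8
    sd_threshold: float = 0.2
    scan_thresholds: tuple = tuple(range(3, 11))
    diff_cutoff: float = 0.25
    q_cutoff: float = 0.01
    min_cg: int = 5
    promoter_bp: int = 1500
    flank_bp: int = 10000
    flank_bins: int = 50
    body_bins: int = 40
    integration_q: float = 0.05
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # real-data inputs (unused when simulating)
    genome_fasta: str = ""
    reads_fastq: dict = field(default_factory=dict)
    expression_tsv: str = ""


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "genome", "landscape", "expression", "simulation",
        ):
            sub = {
                "genome": GenomeParams,
                "landscape": LandscapeParams,
                "expression": ExpressionParams,
                "simulation": SimulationConfig,
            }[f.name]
            kwargs[f.name] = _from_plain(sub, v)
        elif isinstance(v, list):
            kwargs[f.name] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


def save_config(config, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(_to_plain(config), sort_keys=True, default_flow_style=None)
    )


def load_simulation_config(path) -> SimulationConfig:
    cfg = _from_plain(SimulationConfig, yaml.safe_load(Path(path).read_text()) or {})
    cfg.validate()
    return cfg


def load_pipeline_config(path) -> PipelineConfig:
    return _from_plain(PipelineConfig, yaml.safe_load(Path(path).read_text()) or {})
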