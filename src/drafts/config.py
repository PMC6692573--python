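"""Layered run configuration with validated defaults.

Defaults are the pipeline's operating points: 15-read DNA cutoff,
16-cluster TSS seed with 10 bp merge and 1% prune rules, 70%/200-read
primary and 10% secondary TSS thresholds, 45 bp promoter scan window,
17 +/- 2 bp spacer, 8 bp TSS region, 50 nt folding window, top-10%
motif-discovery subset, and 10/90 cross-validation split repeated 10
times.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    library: str = ""
    # samples: {sample: {replicate: {"dna": path | [r1, r2], "rna": ...}}}
    samples: Dict[str, Dict[str, Dict[str, Any]]] = field(default_factory=dict)
    outdir: str = "drafts_out"
    seed: int = 0

    adaptor_seq: str = "AGATCGGAAGAGCACACGTCT"
    n_random_bases: int = 2
    adaptor_max_mismatches: int = 1
    min_overlap: int = 10
    max_mismatch_frac: float = 0.1
    counts_from: str = "barcode"

    dna_min_reads: int = 15
    pseudocount: float = 0.0

    k_seed: int = 16
    merge_dist_bp: int = 10
    min_frac: float = 0.01
    primary_frac: float = 0.70
    primary_min_count: int = 200
    secondary_frac: float = 0.10

    motif_width: int = 6
    upstream_window: int = 45
    optimal_spacer: int = 17
    spacer_max_dev: int = 2
    tss_region_bp: int = 8
    fold_window_nt: int = 50
    top_active_frac: float = 0.10
    fold_backend: str = "nussinov"

    train_frac: float = 0.10
    cv_repeats: int = 10
    model_sample: Optional[str] = None

    selective_fold: float = 10.0
    depletion_fc: float = 0.5
    depletion_alpha: float = 0.05

    def __post_init__(self) -> None:
        checks = [
            (self.dna_min_reads >= 0, "dna_min_reads must be >= 0"),
            (self.k_seed >= 1, "k_seed must be >= 1"),
            (self.merge_dist_bp >= 0, "merge_dist_bp must be >= 0"),
            (0 <= self.min_frac < 1, "min_frac must be in [0, 1)"),
            (0 < self.primary_frac <= 1, "primary_frac must be in (0, 1]"),
            (0 <= self.secondary_frac < 1, "secondary_frac must be in [0, 1)"),
            (0 < self.train_frac < 1, "train_frac must be in (0, 1)"),
            (self.cv_repeats >= 1, "cv_repeats must be >= 1"),
            (self.motif_width >= 2, "motif_width must be >= 2"),
            (self.spacer_max_dev >= 0, "spacer_max_dev must be >= 0"),
            (self.fold_backend in ("nussinov", "external"), "unknown fold_backend"),
            (self.counts_from in ("barcode", "match"), "unknown counts_from"),
            (self.n_random_bases >= 0, "n_random_bases must be >= 0"),
            (self.selective_fold > 0, "selective_fold must be > 0"),
            (0 < self.depletion_alpha < 1, "depletion_alpha must be in (0, 1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_dict(cls, d: Dict[str, Any], **overrides: Any) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        merged = {**d, **{k: v for k, v in overrides.items() if v is not None}}
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(d, **overrides)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)
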