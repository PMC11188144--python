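"""Pipeline configuration: every numeric knob in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .sketch import DEFAULT_HASH_SEED


@dataclass
class PipelineConfig:
    # k-mer / sketching
    k_intersection: int = 28  # exact cluster-vs-reads intersections
    k_sketch: int = 21  # containment + ANI sketches
    sketch_size: int = 1000
    hash_seed: int = DEFAULT_HASH_SEED
    # marker index + reference selection
    marker_identity: float = 0.99
    marker_breadth: float = 0.90  # strict: breadth must exceed this
    min_marker_fraction: float = 0.75  # inclusive
    marker_family_count: int = 40
    # culling
    ani_threshold: float = 95.0
    # assembly
    min_contig: int = 500
    min_longest_contig: int = 2000
    min_cumulative_fraction: float = 0.05
    # aligner
    min_identity: float = 0.85
    seed_length: int = 21
    # polishing
    polish_min_depth: int = 2
    polish_majority: float = 0.6
    polish_max_indel: int = 10
    # execution
    threads: int = 1

    def __post_init__(self) -> None:
        for name in ("marker_identity", "marker_breadth", "min_marker_fraction",
                     "min_cumulative_fraction", "min_identity", "polish_majority"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("k_intersection", "k_sketch", "sketch_size", "min_contig",
                     "min_longest_contig", "seed_length", "polish_min_depth",
                     "marker_family_count", "threads"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.ani_threshold <= 100.0:
            raise ValueError("ani_threshold is a percentage in [0, 100]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
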