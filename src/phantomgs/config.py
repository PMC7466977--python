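"""Experiment configuration: a validated, defaulted view of a YAML file.

A single master seed drives named substreams (simulation, traits, CV plan,
bootstrap, clustering), so re-running any stage with the same resolved
configuration reproduces its outputs bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .mixed_model import FIXED_EFFECT_LABELS

__all__ = ["ExperimentConfig", "load_config"]

_SIMULATOR_KEYS = {
    "n_lines", "n_founders", "p_sites", "chrom_length_bp",
    "switch_rate", "founder_allele_corr", "n_subpops",
}
_SIMULATOR_DEFAULTS = dict(
    n_lines=500, n_founders=30, p_sites=30_000, chrom_length_bp=10_000_000,
    switch_rate=3e-6, founder_allele_corr=0.99, n_subpops=3,
)


@dataclass
class ExperimentConfig:
    """Resolved settings of a full phantom-epistasis experiment."""

    simulator: dict = field(default_factory=lambda: dict(_SIMULATOR_DEFAULTS))
    genotypes_path: str | None = None
    densities: list = field(default_factory=lambda: [100, 1000, 10000])
    kinds: list = field(default_factory=lambda: ["G", "H", "K"])
    fixed_effects: list = field(default_factory=lambda: ["mu"])
    maf_threshold: float = 0.01
    h2: float = 0.6
    n_traits: int = 10
    causal_anchor_density: int = 1000
    cv_folds: int = 10
    cv_replicates: int = 10
    n_boot: int = 10_000
    decomposition_samples: int = 10_000
    max_order: int = 6
    master_seed: int = 0

    def __post_init__(self):
        unknown = set(self.simulator) - _SIMULATOR_KEYS
        if unknown:
            raise ValueError(f"unknown simulator key(s): {sorted(unknown)}")
        self.simulator = {**_SIMULATOR_DEFAULTS, **self.simulator}
        if not self.densities:
            raise ValueError("densities must be non-empty")
        if any(d <= 0 for d in self.densities):
            raise ValueError("densities must be positive")
        if any(b <= a for a, b in zip(self.densities, self.densities[1:])):
            raise ValueError("densities must be strictly increasing")
        bad = set(self.kinds) - {"G", "H", "K"}
        if bad:
            raise ValueError(f"kinds must be a subset of G/H/K, got {sorted(bad)}")
        bad = set(self.fixed_effects) - set(FIXED_EFFECT_LABELS)
        if bad:
            raise ValueError(
                f"fixed_effects must be a subset of {FIXED_EFFECT_LABELS}, got {sorted(bad)}"
            )
        if not 0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5)")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        for key in ("n_traits", "causal_anchor_density", "cv_folds", "cv_replicates",
                    "n_boot", "decomposition_samples", "max_order"):
            if getattr(self, key) < 1:
                raise ValueError(f"{key} must be a positive count")

    def resolved_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    flat: dict = {}
    for key, value in raw.items():
        if key == "cv":
            extra = set(value) - {"folds", "replicates"}
            if extra:
                raise ValueError(f"unknown cv key(s): {sorted(extra)}")
            if "folds" in value:
                flat["cv_folds"] = value["folds"]
            if "replicates" in value:
                flat["cv_replicates"] = value["replicates"]
        elif key == "decomposition":
            extra = set(value) - {"n_samples", "max_order"}
            if extra:
                raise ValueError(f"unknown decomposition key(s): {sorted(extra)}")
            if "n_samples" in value:
                flat["decomposition_samples"] = value["n_samples"]
            if "max_order" in value:
                flat["max_order"] = value["max_order"]
        elif key in ExperimentConfig.__dataclass_fields__:
            flat[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    return ExperimentConfig(**flat)
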