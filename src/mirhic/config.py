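"""Run configuration: every tunable of the pipeline in one object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import yaml


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables with their default values.

    Defaults: K=5 score levels with spacing b=3; R=10,000 stratified
    permutations; DE at BH-adjusted p < 1e-4 after keeping genes in the
    per-sample top 10,000 in >= 30% of samples; hierarchy stopped at the
    correlation with Fisher z-score 0.52 (one-sided tail ~0.3);
    signatures of 30 genes up to 80% of the DE set, Jaccard-deduplicated
    at 0.9; miRNAs reported at q < 0.1.
    """

    K: int = 5
    b: int = 3
    R: int = 10_000
    n_swaps_per_edge: float = 10.0
    z_cutoff: float = 0.52
    de_alpha: float = 1e-4
    top_n: int = 10_000
    sample_fraction: float = 0.3
    q_threshold: float = 0.1
    min_size: int = 30
    max_size_fraction: float = 0.8
    dedup_jaccard: float = 0.9
    seed: int = 0
    paired: bool = False
    correlation_method: str = "pearson"
    absolute_correlation: bool = False
    flat_signature: bool = False  # force the single flat DE signature (miRDeG)
    fallback_to_flat: bool = True  # degrade to the flat DE signature if none extracted

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)
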