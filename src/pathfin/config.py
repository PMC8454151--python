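"""Run configuration with paper-anchored defaults and lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration for the end-to-end pipeline.

    Defaults: combined-score threshold 0.4 (strict), complete linkage,
    DE-gene regulation-ratio denominator, neutral band [0.4, 0.6],
    FDR <= 0.1 and fold change >= 1.5 for DE calls.
    """

    cs_threshold: float = 0.4
    linkage: str = "complete"
    ratio_policy: str = "de"
    neutral_band: tuple[float, float] = (0.4, 0.6)
    fdr_cutoff: float = 0.1
    fc_cutoff: float = 1.5
    seed: int = 0
    n_clusters: int = 2
    query: str = ""
    reference: str = ""  # empty: pick the top-ranked drug by pathsim
    evidence: str = ""
    compositions: str = ""
    gmt: list[str] = field(default_factory=list)
    de_table: str = ""
    outdir: str = "pathfin_out"

    def __post_init__(self) -> None:
        if isinstance(self.neutral_band, list):
            self.neutral_band = tuple(self.neutral_band)  # type: ignore[assignment]
        if not 0.0 <= self.cs_threshold <= 1.0:
            raise ValueError("cs_threshold must lie in [0, 1]")
        if self.linkage not in ("complete", "average", "single"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.ratio_policy not in ("de", "measured"):
            raise ValueError(f"unknown ratio policy {self.ratio_policy!r}")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["neutral_band"] = list(self.neutral_band)
        Path(path).write_text(
            yaml.safe_dump(data, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
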