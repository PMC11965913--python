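"""Run configuration: one plain-text (YAML) file drives a whole run."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .preprocess import OutlierConfig, ProportionSpec
from .timecluster import ClusterConfig


@dataclass(frozen=True)
class RunConfig:
    """Everything a prepare/analyze run needs besides the data itself."""

    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    outlier: OutlierConfig = field(default_factory=OutlierConfig)
    proportions: ProportionSpec = field(default_factory=ProportionSpec)
    #: auto-detect percentage bin columns when none are declared
    auto_detect_proportions: bool = True
    alpha: float = 0.05
    #: factor -> allowed-level whitelist applied before analysis
    subset: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {
            "cluster": dataclasses.asdict(self.cluster),
            "outlier": dataclasses.asdict(self.outlier),
            "proportions": dataclasses.asdict(self.proportions),
            "auto_detect_proportions": self.auto_detect_proportions,
            "alpha": self.alpha,
            "subset": self.subset,
        }
        data["outlier"]["group_by"] = list(self.outlier.group_by)
        data["proportions"]["columns"] = list(self.proportions.columns)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        try:
            cluster = ClusterConfig(**data.get("cluster", {}))
            outlier_kw = dict(data.get("outlier", {}))
            outlier_kw["group_by"] = tuple(outlier_kw.get("group_by", ()))
            outlier = OutlierConfig(**outlier_kw)
            prop_kw = dict(data.get("proportions", {}))
            prop_kw["columns"] = tuple(prop_kw.get("columns", ()))
            proportions = ProportionSpec(**prop_kw)
        except TypeError as exc:
            raise ValidationError(f"bad config {path}: {exc}") from exc
        return cls(
            cluster=cluster,
            outlier=outlier,
            proportions=proportions,
            auto_detect_proportions=bool(data.get("auto_detect_proportions", True)),
            alpha=float(data.get("alpha", 0.05)),
            subset=dict(data.get("subset", {})),
        )
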