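"""Pipeline configuration with defaults matching the published thresholds."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import SyntheticConfig


@dataclass
class PipelineConfig:
    # inputs (empty → stage is driven by the synthetic generator or skipped)
    expression: str = ""
    design: str = ""
    annotation: str = ""
    annotation_format: str = "bed"
    obo: str = ""
    gaf: str = ""
    outdir: str = "out"
    seed: int = 0
    # preprocess
    min_intensity: float = 40.0
    min_frac: float = 0.25
    iqr_percentile: float = 10.0
    # differential
    fc_cut: float = 1.3
    alpha: float = 0.05
    use_adjusted: bool = True
    # templates
    r2_threshold: float = 0.95
    flat_eps: float = 0.5
    template_alpha: float = 0.05
    # positional clustering
    min_de: int = 3
    window_genes: int = 10
    n_rand_clusters: int = 100
    n_rand_chromosome: int = 1000
    cluster_fc: float = 2.0
    # GO enrichment
    go_level: int = 3
    go_alpha: float = 0.05
    go_namespace: str = "molecular_function"
    # synthetic generation
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", {})
        if isinstance(syn, dict):
            if "fc_range" in syn:
                syn["fc_range"] = tuple(syn["fc_range"])
            if "conditions" in syn:
                syn["conditions"] = tuple(syn["conditions"])
            syn = SyntheticConfig(**syn)
        return cls(synthetic=syn, **raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["synthetic"]["fc_range"] = list(data["synthetic"]["fc_range"])
        data["synthetic"]["conditions"] = list(data["synthetic"]["conditions"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True))
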