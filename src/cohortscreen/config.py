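"""Single configuration object holding all pipeline thresholds.

Defaults are the screen's published values: CoV filter 0.50, Spearman
redundancy filter 0.98, induction cutoff 2σ, stratified fold-change gate
0.263 (fold change ~1.2), p gate 0.05, valid-value fraction 1/3.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml

from .normalize import MAD_TO_SD


@dataclass
class PipelineConfig:
    cov_max: float = 0.50
    spearman_max: float = 0.98
    induction_sigma: float = 2.0
    log2fc_min: float = 0.263
    p_max: float = 0.05
    valid_frac: float = 1 / 3
    mad_scale: float = MAD_TO_SD
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    n_permutations: int = 1000
    min_dmso_wells: int = 4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = sorted(set(raw) - set(known))
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
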