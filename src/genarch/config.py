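"""Pipeline configuration and seed management.

Every stochastic stage receives an explicit seed derived from one master
seed via ``numpy.random.SeedSequence`` spawning, so identical configuration
implies bit-identical pipeline output. The config round-trips losslessly
through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

STAGES = ("simulate", "meta_qtl", "finemap", "annot", "ldsc", "twas", "burden")


def spawn_seeds(master_seed: int, stages=STAGES) -> dict[str, int]:
    """Derive one 31-bit seed per stage from a master seed, deterministically."""
    children = np.random.SeedSequence(master_seed).spawn(len(stages))
    return {s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(stages, children)}


@dataclass
class PipelineConfig:
    """All tunable stage parameters plus per-stage seeds and paths."""

    seeds: dict = field(default_factory=lambda: spawn_seeds(0))
    paths: dict = field(default_factory=dict)
    maf_threshold: float = 0.01
    credible_level: float = 0.95
    max_causal: int = 3
    ncp_scale: float = 5.2
    jackknife_blocks: int = 200
    bonferroni_tests: int = 1
    cis_h2_pvalue: float = 0.01
    flank: int = 100

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, TypeError):
                data = yaml.safe_load(source)
        return cls(**data)
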