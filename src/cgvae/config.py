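"""Run configuration: one object binding cohort, model, protocol and
evaluation settings, serializable to/from YAML."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .cohort import CohortParams
from .nn.model import ModelConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    cohort: CohortParams = field(default_factory=CohortParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    condition: str = "sex"  # conditioning variable: "sex", "fi" or "none"
    tau: float = 0.1
    test_frac: float = 0.1
    val_frac: float = 0.1
    n_splits: int = 1
    epochs: int = 30
    batch_size: int = 16
    lr: float = 1e-4
    weight_decay: float = 1e-5
    q_edge: float = 0.01
    q_latent: float = 0.05
    top_dims: int = 2
    top_edges: int = 20
    seed: int = 0
    outdir: str = "results"

    # Named sub-seeds: every random stage traces to one of these.
    @property
    def seeds(self) -> dict[str, int]:
        base = int(self.seed)
        return {
            "cohort": base,
            "splits": base + 1,
            "training": base + 2,
            "latent_sampling": base + 3,
            "prediction": base + 4,
        }

    def condition_or_none(self) -> str | None:
        return None if self.condition in ("none", None) else self.condition

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort = CohortParams(**{
        **raw.get("cohort", {}),
        **({"subdomain_sizes": tuple(raw["cohort"]["subdomain_sizes"])}
           if "subdomain_sizes" in raw.get("cohort", {}) else {}),
    })
    model = ModelConfig(**raw.get("model", {}))
    rest = {k: v for k, v in raw.items() if k not in ("cohort", "model")}
    return RunConfig(cohort=cohort, model=model, **rest)


def save_config(config: RunConfig, path: str | Path) -> None:
    payload = asdict(config)
    payload["cohort"]["subdomain_sizes"] = list(payload["cohort"]["subdomain_sizes"])
    for key in ("sex_mask_blocks", "fi_mask_blocks"):
        payload["cohort"][key] = list(payload["cohort"][key])
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def with_overrides(config: RunConfig, **kwargs) -> RunConfig:
    """CLI-over-file precedence: replace top-level fields if not None."""
    updates = {k: v for k, v in kwargs.items() if v is not None}
    return replace(config, **updates)
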