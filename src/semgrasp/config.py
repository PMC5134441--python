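"""YAML run configuration: one nesting level per pipeline stage.

Unknown keys are rejected by name so a typo never silently falls back to
a default; command-line flags override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .errors import ValidationError
from .features import FeatureConfig
from .preprocess import EpochSpec
from .simulate import SynthConfig

__all__ = ["ClassifierConfig", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class ClassifierConfig:
    kind: str = "hmm"  # gmm | hmm
    ngram: str = "unigram"
    n_components: int = 5
    reg: float = 0.05
    alpha: float = 1.0
    voting_n: int = 0
    release_len_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.kind not in ("gmm", "hmm"):
            raise ValidationError(f"classifier.kind must be gmm|hmm, got {self.kind!r}")
        if self.ngram not in ("unigram", "bigram"):
            raise ValidationError(f"classifier.ngram must be unigram|bigram, got {self.ngram!r}")


@dataclass(frozen=True)
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    epoch: EpochSpec = field(default_factory=EpochSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cv_k: int = 10
    n_trials: int = 20
    seed: int = 0


_TUPLE_FIELDS = {
    "steady_start_range",
    "transport_range",
    "gap_range",
    "tail_range",
    "flexor_band",
    "extensor_band",
    "floor_band",
    "included_features",
}


def _build(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def _as_dict(cfg: RunConfig) -> dict:
    doc = {}
    for sec in ("synth", "epoch", "features", "classifier"):
        doc[sec] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(getattr(cfg, sec)).items()
        }
    doc["cv_k"] = cfg.cv_k
    doc["n_trials"] = cfg.n_trials
    doc["seed"] = cfg.seed
    return doc


def config_from_dict(doc: dict) -> RunConfig:
    sections = {"synth": SynthConfig, "epoch": EpochSpec, "features": FeatureConfig, "classifier": ClassifierConfig}
    scalars = {"cv_k", "n_trials", "seed"}
    unknown = set(doc) - set(sections) - scalars
    if unknown:
        raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
    kw = {}
    for sec, cls in sections.items():
        kw[sec] = _build(cls, doc.get(sec, {}) or {}, sec)
    for s in scalars:
        if s in doc:
            kw[s] = doc[s]
    return RunConfig(**kw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_as_dict(cfg), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    try:
        return config_from_dict(doc)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
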