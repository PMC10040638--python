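"""Run configuration: defaults, validation and hashing.

A run is described by one YAML (or dict) document with per-module sections.
Unknown keys are rejected and all validation problems are reported at once.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError
from .simulate import SimulationConfig


@dataclass
class PrepConfig:
    rarefy_depth: int = 14221
    min_samples: int = 3


@dataclass
class EcologyConfig:
    n_perm: int = 999
    top_n: int = 500        # SPEC-OCCU per-group pool size


@dataclass
class NetworkConfig:
    control_group: str = "BP"
    case_group: str = "T1"
    min_prevalence: float = 0.3
    rho_threshold: float = 0.6
    alpha: float = 0.05
    score_quantile: float = 0.90


@dataclass
class ClassifierConfig:
    top_k: int = 15
    n_estimators: int = 500
    train_fraction: float = 67 / 95
    ranks: tuple = ("phylum", "class", "order", "family", "genus", "asv")


@dataclass
class RunConfig:
    seed: int = 0
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    ecology: EcologyConfig = field(default_factory=EcologyConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SECTIONS = {
    "simulate": SimulationConfig,
    "prep": PrepConfig,
    "ecology": EcologyConfig,
    "network": NetworkConfig,
    "classifier": ClassifierConfig,
}

_RANGES = {
    ("prep", "rarefy_depth"): (1, None),
    ("prep", "min_samples"): (1, None),
    ("ecology", "n_perm"): (1, None),
    ("ecology", "top_n"): (1, None),
    ("network", "min_prevalence"): (0.0, 1.0),
    ("network", "rho_threshold"): (0.0, 1.0),
    ("network", "alpha"): (0.0, 1.0),
    ("network", "score_quantile"): (0.0, 1.0),
    ("classifier", "top_k"): (1, None),
    ("classifier", "n_estimators"): (1, None),
    ("classifier", "train_fraction"): (0.0, 1.0),
}


def validate_config(raw) -> RunConfig:
    """Build a :class:`RunConfig` from YAML text, a path, or a mapping.

    An empty document yields all defaults.  Unknown keys, type errors and
    out-of-range values are aggregated into one
    :class:`~crcmicro.errors.ConfigurationError`.
    """
    if raw is None:
        data = {}
    elif isinstance(raw, dict):
        data = raw
    else:
        data = yaml.safe_load(str(raw)) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(["config root must be a mapping"])

    errors: list[str] = []
    cfg = RunConfig()
    for key, value in data.items():
        if key == "seed":
            try:
                cfg.seed = int(value)
            except (TypeError, ValueError):
                errors.append(f"seed must be an integer, got {value!r}")
            continue
        if key not in _SECTIONS:
            errors.append(f"unknown config key {key!r}")
            continue
        section = getattr(cfg, key)
        if not isinstance(value, dict):
            errors.append(f"section {key!r} must be a mapping")
            continue
        valid_fields = {f.name for f in dataclasses.fields(section)}
        for fkey, fval in value.items():
            if fkey not in valid_fields:
                errors.append(f"unknown key {fkey!r} in section {key!r}")
                continue
            current = getattr(section, fkey)
            try:
                if isinstance(current, bool):
                    coerced = bool(fval)
                elif isinstance(current, int) and not isinstance(current, bool):
                    coerced = int(fval)
                elif isinstance(current, float):
                    coerced = float(fval)
                elif isinstance(current, tuple):
                    coerced = tuple(fval)
                elif isinstance(current, dict):
                    coerced = dict(fval)
                else:
                    coerced = fval
            except (TypeError, ValueError):
                errors.append(f"{key}.{fkey} has invalid type: {fval!r}")
                continue
            lo_hi = _RANGES.get((key, fkey))
            if lo_hi is not None:
                lo, hi = lo_hi
                if (lo is not None and coerced < lo) or (
                    hi is not None and coerced > hi
                ):
                    errors.append(
                        f"{key}.{fkey} out of range "
                        f"[{lo}, {'inf' if hi is None else hi}]: {coerced!r}"
                    )
                    continue
            setattr(section, fkey, coerced)

    try:
        cfg.simulate.validate()
    except ConfigurationError as e:
        errors.extend(f"simulate: {m}" for m in e.errors)
    if errors:
        raise ConfigurationError(errors)
    return cfg
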