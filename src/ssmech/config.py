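"""Run configuration: YAML round-trip, hashing, seed derivation."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .dynamics import SMDProtocol
from .potentials import (DynamicSSParams, GoParams, RedoxModel,
                         RestraintParams, TripletRepulsionParams)
from .topology import ToyFoldSpec


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Full pipeline configuration: fold source, potentials, and the
    protocol grid (modes × speeds × seeds)."""

    toy_fold: ToyFoldSpec
    go: GoParams = field(default_factory=GoParams)
    redox_base: RedoxModel = field(default_factory=RedoxModel)
    protocol: SMDProtocol = field(default_factory=SMDProtocol)
    modes: tuple = ("none", "dynamic", "static")
    depths: dict = field(default_factory=lambda: {"weak": 5.5, "high": 11.0})
    speeds: tuple = (0.02,)
    n_seeds: int = 2
    master_seed: int = 0
    bin_width: float = 1.0
    ss_cutoff: float = 5.5

    def conditions(self):
        """Yield (label, mode, D_bond or None, speed) for the full grid;
        dynamic mode expands over the configured redox depths."""
        for mode in self.modes:
            if mode == "dynamic":
                for name, depth in self.depths.items():
                    for speed in self.speeds:
                        yield f"dynamic-{name}-v{speed:g}", mode, depth, speed
            else:
                for speed in self.speeds:
                    yield f"{mode}-v{speed:g}", mode, None, speed

    def trajectory_seed(self, condition_label: str, replica: int) -> int:
        h = hashlib.sha256(
            f"{self.master_seed}|{condition_label}|{replica}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_yaml(cfg: RunConfig) -> str:
    return yaml.safe_dump(_to_plain(cfg), sort_keys=True)


def _build(cls, data: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        kwargs[f.name] = v
    return cls(**kwargs)


def config_from_yaml(text: str) -> RunConfig:
    try:
        data = yaml.safe_load(text)
        tf = data["toy_fold"]
        tf["blocks"] = tuple(tuple(b) for b in tf["blocks"])
        tf["crosslinks"] = tuple(tuple(p) for p in tf.get("crosslinks", ()))
        if tf.get("anchors") is not None:
            tf["anchors"] = tuple(tf["anchors"])
        toy = _build(ToyFoldSpec, tf)
        rb = data.get("redox_base", {})
        redox = RedoxModel(
            mode=rb.get("mode", "none"),
            dyn=_build(DynamicSSParams, rb.get("dyn", {})),
            triplet=_build(TripletRepulsionParams, rb.get("triplet", {})),
            restraint=_build(RestraintParams, rb.get("restraint", {})),
            k_static=rb.get("k_static", 100.0))
        proto = data.get("protocol", {})
        if proto.get("anchors") is not None:
            proto["anchors"] = tuple(proto["anchors"])
        cfg = RunConfig(
            toy_fold=toy,
            go=_build(GoParams, data.get("go", {})),
            redox_base=redox,
            protocol=_build(SMDProtocol, proto),
            modes=tuple(data.get("modes", ("none", "dynamic", "static"))),
            depths=dict(data.get("depths", {"weak": 5.5, "high": 11.0})),
            speeds=tuple(data.get("speeds", (0.02,))),
            n_seeds=int(data.get("n_seeds", 2)),
            master_seed=int(data.get("master_seed", 0)),
            bin_width=float(data.get("bin_width", 1.0)),
            ss_cutoff=float(data.get("ss_cutoff", 5.5)))
    except (KeyError, TypeError, ValueError, yaml.YAMLError) as err:
        raise ConfigError(f"invalid configuration: {err}") from err
    return cfg


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(config_to_yaml(cfg).encode()).hexdigest()[:12]
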