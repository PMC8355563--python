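"""Versioned JSON serialization of trained models and run artifacts.

Model bundles store every synaptic matrix, mask, template, neuron
configuration, class map, and (if present) scaler parameters, plus a
schema version and the SHA-256 hash of the run configuration that
produced them, so a run can be audited and reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .architectures import DomainDescriptor, GTLinearClassifier, MultiLayerGTClassifier, _SupervisedLayer
from .core import DifferentialNetwork, NeuronConfig
from .learning import TrainConfig

MODEL_SCHEMA_VERSION = 1

__all__ = ["save_model", "load_model", "save_network", "load_network", "config_hash"]


def config_hash(obj) -> str:
    """Stable SHA-256 of any JSON-serializable configuration."""
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _net_to_dict(net: DifferentialNetwork) -> dict:
    return {
        "Q": net.Q.tolist(),
        "mask": net.mask.tolist(),
        "b": net.b.tolist(),
        "t": None if net.t is None else net.t.tolist(),
        "config": asdict(net.config),
    }


def _net_from_dict(d: dict) -> DifferentialNetwork:
    cfg = NeuronConfig(**d["config"])
    return DifferentialNetwork(
        np.array(d["Q"]), config=cfg, mask=np.array(d["mask"], dtype=bool),
        b=np.array(d["b"]), t=None if d["t"] is None else np.array(d["t"]),
    )


def save_network(net: DifferentialNetwork, path, extra: dict | None = None) -> None:
    """Checkpoint a differential network (Q, mask, template, config)."""
    d = {"schema_version": MODEL_SCHEMA_VERSION, "type": "network",
         "net": _net_to_dict(net)}
    if extra:
        d["extra"] = extra
    d["config_hash"] = config_hash({k: v for k, v in d.items() if k != "config_hash"})
    Path(path).write_text(json.dumps(d))


def load_network(path) -> DifferentialNetwork:
    d = json.loads(Path(path).read_text())
    if d.get("type") != "network":
        raise ValueError(f"{path} is not a network checkpoint")
    return _net_from_dict(d["net"])


def save_model(model, path, extra: dict | None = None) -> None:
    d: dict = {"schema_version": MODEL_SCHEMA_VERSION}
    if isinstance(model, DomainDescriptor):
        d["type"] = "domain"
        d["D"] = model.D
        d["t"] = model.t.tolist()
        d["seed"] = model.seed
        d["net"] = _net_to_dict(model.net)
        d["train_rates"] = model.train_rates.tolist()
        d["threshold"] = model.threshold
        d["neuron_config"] = asdict(model.neuron_config)
        d["train_config"] = asdict(model.train_config)
    elif isinstance(model, GTLinearClassifier):
        d["type"] = "linear"
        d["variant"] = model.variant
        d["D"] = model.D
        d["classes"] = [getattr(c, "item", lambda c=c: c)() for c in model.codec.classes]
        d["net"] = _net_to_dict(model.layer.net)
        d["neuron_config"] = asdict(model.neuron_config)
    elif isinstance(model, MultiLayerGTClassifier):
        d["type"] = "multilayer"
        d["kind"] = model.kind
        d["D"] = model.D
        d["S"] = model.S
        d["seed"] = model.seed
        d["classes"] = [getattr(c, "item", lambda c=c: c)() for c in model.codec.classes]
        d["connection_prob"] = model.connection_prob
        d["random_scale"] = model.random_scale
        d["feature_scale"] = model.feature_scale
        d["neuron_config"] = asdict(model.neuron_config)
        d["subnets"] = [_net_to_dict(n) for n in model.subnets]
        d["top"] = _net_to_dict(model.top.net)
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    if extra:
        d["extra"] = extra
    d["config_hash"] = config_hash({k: v for k, v in d.items() if k != "config_hash"})
    Path(path).write_text(json.dumps(d))


def load_model(path):
    d = json.loads(Path(path).read_text())
    kind = d.get("type")
    if kind == "domain":
        m = DomainDescriptor(
            d["D"],
            neuron_config=NeuronConfig(**d["neuron_config"]),
            train_config=TrainConfig(**d["train_config"]),
            seed=d["seed"],
        )
        m.t = np.array(d["t"])
        m.net = _net_from_dict(d["net"])
        m.train_rates = np.array(d["train_rates"])
        m.threshold = d["threshold"]
        return m
    if kind == "linear":
        from .architectures import LabelCodec

        m = GTLinearClassifier(d["D"], d["variant"], NeuronConfig(**d["neuron_config"]))
        m.codec = LabelCodec(d["classes"])
        m.layer = _SupervisedLayer(d["D"], m.codec.P, d["variant"], m.neuron_config)
        net = _net_from_dict(d["net"])
        m.layer.net = net
        return m
    if kind == "multilayer":
        m = MultiLayerGTClassifier(
            d["kind"], d["D"], d["classes"], S=d["S"], seed=d["seed"],
            neuron_config=NeuronConfig(**d["neuron_config"]),
            connection_prob=d["connection_prob"], random_scale=d["random_scale"],
            feature_scale=d["feature_scale"],
        )
        m.subnets = [_net_from_dict(nd) for nd in d["subnets"]]
        m.top.net = _net_from_dict(d["top"])
        return m
    raise ValueError(f"unknown model bundle type {kind!r} in {path}")
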