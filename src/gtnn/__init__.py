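"""Spiking growth-transform neural networks.

Spike generation as constraint violation in an energy-minimizing
dynamical system; a backpropagation-free local learning rule that
minimizes total network spiking; unsupervised (domain description,
anomaly detection) and supervised (linear and multi-layer) spiking
architectures with minimum-spiking inference.
"""

from .core import (
    DifferentialNetwork,
    NetworkState,
    NeuronConfig,
    SteadyState,
    Trace,
    gt_step,
    local_gradient,
    relu_curve,
    simulate,
    simulate_batch,
    spike_fn,
)
from .learning import (
    TrainConfig,
    TrainHistory,
    template_weight_update,
    train_fixed_input,
    train_template,
    weight_update,
)
from .architectures import (
    DomainDescriptor,
    GTLinearClassifier,
    MultiLayerGTClassifier,
    Prediction,
)
from .metrics import BinnedCounts, SparsityReport, population_trajectory, psth, rho
from . import datasets

__version__ = "0.1.0"

__all__ = [
    "NeuronConfig",
    "DifferentialNetwork",
    "NetworkState",
    "SteadyState",
    "Trace",
    "spike_fn",
    "gt_step",
    "local_gradient",
    "simulate",
    "simulate_batch",
    "relu_curve",
    "TrainConfig",
    "TrainHistory",
    "weight_update",
    "template_weight_update",
    "train_fixed_input",
    "train_template",
    "DomainDescriptor",
    "GTLinearClassifier",
    "MultiLayerGTClassifier",
    "Prediction",
    "rho",
    "psth",
    "population_trajectory",
    "BinnedCounts",
    "SparsityReport",
    "datasets",
]


def derive_seed(seed: int, *names) -> int:
    """Fan a global seed out to per-component seeds, deterministically.

    Hashes ``(seed, *names)`` with SHA-256 and returns an integer below
    2**31, so the same run configuration reproduces every stream on any
    platform.
    """
    import hashlib

    h = hashlib.sha256(("|".join([str(seed), *map(str, names)])).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
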