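"""Task-level spiking architectures built from differential GT networks.

All models share one inference principle: present each candidate label
to the network and pick the one that makes the network spike least,
measured by the sparsity metric

    rho = 1/(2M) * sum_i (s+_i + s-_i),        s = psi_bar / I_psi,

averaged over every neuron pair the model simulates.  Training never
propagates gradients between layers: each layer adapts its own lateral
weights with the local sparsity-descent rule while inter-layer
connections stay fixed.

Models
------
``DomainDescriptor``
    Unsupervised domain description / anomaly detection via template
    projection; the firing-rate threshold is a quantile of the training
    rates.
``GTLinearClassifier``
    Binary linear classification; ``feed_forward`` trains only the
    synapses into the output pair, ``fully_connected`` trains every
    lateral connection and achieves the same separation with fewer
    spikes.
``MultiLayerGTClassifier``
    Three two-layer spiking networks: fixed random projections
    (kind 1), layer-wise trained lateral connections (kind 2), and
    layer-wise training with label information injected into layer 1
    (kind 3, the sparsest).  Kind 3 also supports slowly varying
    time-series inputs with a constant label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DifferentialNetwork, NeuronConfig, simulate, simulate_batch
from .learning import (
    TrainConfig,
    TrainHistory,
    apply_update,
    init_weights,
    template_weight_update,
    train_template,
    weight_update,
)

__all__ = [
    "Prediction",
    "DomainDescriptor",
    "GTLinearClassifier",
    "MultiLayerGTClassifier",
]


@dataclass
class Prediction:
    """Outcome of minimum-spiking inference for one sample."""

    label: object
    rho_per_candidate: np.ndarray
    margin: float


def _argmin_prediction(classes, rhos: np.ndarray) -> Prediction:
    """Deterministic argmin with ties broken toward the smallest class."""
    order = np.argsort(rhos, kind="stable")
    best = int(order[0])
    margin = float(rhos[order[1]] - rhos[order[0]]) if len(rhos) > 1 else 0.0
    return Prediction(classes[best], rhos.copy(), margin)


class LabelCodec:
    """Maps class labels to the clamped stimulus of the label pairs.

    Binary problems use a single pair driven at -1/+1; ``C > 2``
    problems use ``C`` pairs driven at ``{-1,+1}^C`` with +1 at the
    encoded class.
    """

    def __init__(self, classes, force_onehot: bool = False) -> None:
        self.classes = sorted(set(classes))
        self.C = len(self.classes)
        if self.C < 2:
            raise ValueError("need at least two classes")
        self.P = self.C if (force_onehot or self.C > 2) else 1
        self._index = {c: i for i, c in enumerate(self.classes)}

    def encode(self, label) -> np.ndarray:
        i = self._index[label]
        if self.P == 1:
            return np.array([-1.0 if i == 0 else 1.0])
        vec = -np.ones(self.C)
        vec[i] = 1.0
        return vec

    def candidates(self) -> np.ndarray:
        return np.stack([self.encode(c) for c in self.classes])


# ---------------------------------------------------------------------
# domain description / anomaly detection
# ---------------------------------------------------------------------

class DomainDescriptor:
    """One-class model: spikes little for members, more for anomalies.

    A dense differential network with a fixed random template ``t`` is
    trained by template projection so that ``Q t`` tracks the training
    cloud; the mean firing rate rho of each training point is computed
    afterwards, and the decision threshold is the ``1 - reject_frac``
    empirical quantile of those rates (the maximum when
    ``reject_frac = 0``).  A point is a *member* iff its rate is at or
    below the threshold.
    """

    def __init__(
        self,
        D: int,
        neuron_config: NeuronConfig | None = None,
        train_config: TrainConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.D = D
        self.neuron_config = neuron_config or NeuronConfig(alpha=0.1, T_settle=800, T_avg=500)
        self.train_config = train_config or TrainConfig(eta=0.05, epochs=20, seed=seed)
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.t = rng.uniform(0.2, 1.0, D)
        self.net: DifferentialNetwork | None = None
        self.train_rates: np.ndarray | None = None
        self.threshold: float | None = None
        self.history: TrainHistory | None = None

    def fit(self, X: np.ndarray, reject_frac: float = 0.0) -> "DomainDescriptor":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size == 0:
            raise ValueError("training set is empty")
        if not 0 <= reject_frac < 1:
            raise ValueError("reject_frac must be in [0, 1)")
        net = DifferentialNetwork.uncoupled(self.D, config=self.neuron_config)
        net, self.history = train_template(net, X, self.t, self.train_config)
        self.net = net
        self.train_rates = self.rho(X)
        self.threshold = float(np.quantile(self.train_rates, 1.0 - reject_frac))
        return self

    def rho(self, X: np.ndarray) -> np.ndarray:
        """Sparsity metric of each row of ``X`` under the trained net."""
        if self.net is None:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ss = simulate_batch(self.net, X)
        return (ss.s_plus + ss.s_minus).sum(axis=1) / (2 * self.D)

    def centroid(self) -> np.ndarray:
        """Current template projection ``Q t``."""
        if self.net is None:
            raise RuntimeError("model is not fitted")
        return self.net.Q @ self.net.t

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels (``"member"`` / ``"anomaly"``) and rates for ``X``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.any(X < -0.5) or np.any(X > 1.5):
            warnings.warn(
                "input outside [-0.5, 1.5]^D; did you forget to scale features?",
                stacklevel=2,
            )
        r = self.rho(X)
        labels = np.where(r <= self.threshold, "member", "anomaly")
        return labels, r


# ---------------------------------------------------------------------
# supervised layer (shared by the linear and multi-layer models)
# ---------------------------------------------------------------------

class _SupervisedLayer:
    """Differential network over ``[label pairs, feature pairs, bias]``.

    The stimulus for a presentation is the augmented vector
    ``[y_enc, x, 1]``.  ``feed_forward`` masks training to the rows
    into the label pairs (classic linear regression weights); the
    ``fully_connected`` variant trains every off-diagonal entry.
    """

    def __init__(
        self,
        D: int,
        P: int,
        variant: str,
        neuron_config: NeuronConfig,
    ) -> None:
        if variant not in ("feed_forward", "fully_connected"):
            raise ValueError("variant must be 'feed_forward' or 'fully_connected'")
        self.D, self.P, self.variant = D, P, variant
        M = P + D + 1
        self.M = M
        if variant == "feed_forward":
            mask = np.zeros((M, M), dtype=bool)
            mask[:P, P:] = True
        else:
            mask = ~np.eye(M, dtype=bool)
        self.net = DifferentialNetwork(
            np.zeros((M, M)), config=neuron_config, mask=mask
        )

    def stimulus(self, y_enc: np.ndarray, x: np.ndarray) -> np.ndarray:
        return np.concatenate([y_enc, x, [1.0]])

    def stimuli(self, Y_enc: np.ndarray, X: np.ndarray) -> np.ndarray:
        ones = np.ones((len(X), 1))
        return np.concatenate([Y_enc, X, ones], axis=1)

    def scope_counts(self, ss) -> tuple[np.ndarray, int]:
        """Summed normalized counts and pair count of the rho scope."""
        s = ss.s_plus + ss.s_minus
        if self.variant == "feed_forward":
            return s[..., : self.P].sum(axis=-1), self.P
        return s.sum(axis=-1), self.M

    def present(self, x: np.ndarray, y_enc: np.ndarray, cfg: TrainConfig):
        from .learning import _presentation_update

        b = self.stimulus(y_enc, x)
        return _presentation_update(self.net, b, cfg, weight_update)


# ---------------------------------------------------------------------
# linear supervised classifier
# ---------------------------------------------------------------------

class GTLinearClassifier:
    """Binary linear classification by minimum-spiking inference.

    Training presents ``[y, x, 1]`` with the true label clamped and
    descends the network spiking; inference clamps each candidate label
    and picks the quieter one.  For the feed-forward variant the
    sparsity scope is the output pair alone; the fully-connected
    variant scores (and trains) the whole network, ending markedly
    sparser at equal accuracy.
    """

    def __init__(
        self,
        D: int,
        variant: str = "fully_connected",
        neuron_config: NeuronConfig | None = None,
    ) -> None:
        self.D = D
        self.variant = variant
        self.neuron_config = neuron_config or NeuronConfig(alpha=0.1, T_settle=400, T_avg=400)
        self.codec: LabelCodec | None = None
        self.layer: _SupervisedLayer | None = None
        self.history: dict[str, list[float]] | None = None

    def fit(
        self,
        X: np.ndarray,
        y,
        cfg: TrainConfig | None = None,
        track: bool = True,
        select_best: bool = False,
        X_val: np.ndarray | None = None,
        y_val=None,
        acc_tol: float = 0.0,
    ) -> "GTLinearClassifier":
        """Online training with the true label clamped per presentation.

        ``select_best`` keeps the weights of the epoch with the highest
        accuracy (on the validation set if given, else on the training
        set); ties go to the earliest epoch.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cfg = cfg or TrainConfig(eta=0.05, epochs=10)
        self.codec = LabelCodec(y)
        if self.codec.C != 2:
            raise ValueError("GTLinearClassifier handles binary problems")
        self.layer = _SupervisedLayer(self.D, self.codec.P, self.variant, self.neuron_config)
        init_weights(self.layer.net, cfg)
        Y_enc = np.stack([self.codec.encode(lbl) for lbl in y])
        rng = np.random.default_rng(cfg.seed)
        self.history = {"accuracy": [], "rho_train": []}
        best = None
        for _ in range(cfg.epochs):
            order = rng.permutation(len(X)) if cfg.shuffle else np.arange(len(X))
            for k in order:
                self.layer.present(X[k], Y_enc[k], cfg)
            if track:
                acc = self.score(X_val, y_val) if X_val is not None else self.score(X, y)
                rho_now = self.rho_train(X, y)
                self.history["accuracy"].append(acc)
                self.history["rho_train"].append(rho_now)
                if select_best and (
                    best is None
                    or acc > best[0] + acc_tol
                    or (acc >= best[0] - acc_tol and rho_now < best[1])
                ):
                    best = (max(acc, best[0] if best else acc), rho_now, self.layer.net.Q.copy())
        if select_best and best is not None:
            self.layer.net.Q = best[2]
        return self

    def _rho_batch(self, X: np.ndarray, Y_enc: np.ndarray, scope: str = "variant") -> np.ndarray:
        """Per-sample sparsity with the given labels clamped.

        ``scope="variant"`` is the inference scope (output pair only for
        feed-forward); ``scope="network"`` measures every simulated pair,
        the network-level sparsity used for reporting.
        """
        B = self.layer.stimuli(Y_enc, X)
        ss = simulate_batch(self.layer.net, B)
        if scope == "network":
            s = ss.s_plus + ss.s_minus
            return s.sum(axis=-1) / (2 * self.layer.M)
        counts, pairs = self.layer.scope_counts(ss)
        return counts / (2 * pairs)

    def predict(self, X: np.ndarray) -> list[Prediction]:
        if self.layer is None:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(X)
        cands = self.codec.candidates()  # (C, P)
        rhos = np.empty((n, self.codec.C))
        for ci in range(self.codec.C):
            Y = np.repeat(cands[ci][None, :], n, axis=0)
            rhos[:, ci] = self._rho_batch(X, Y)
        return [_argmin_prediction(self.codec.classes, r) for r in rhos]

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return np.array([p.label for p in self.predict(X)])

    def score(self, X, y) -> float:
        return float(np.mean(self.predict_labels(X) == np.asarray(y)))

    def rho_train(self, X, y) -> float:
        """Mean network-level sparsity with the correct label clamped.

        Measured over every simulated pair for both variants, so the
        untrained feature/bias pairs of the feed-forward network count
        against it — that is the comparison under which the
        fully-connected variant ends markedly sparser.
        """
        Y_enc = np.stack([self.codec.encode(lbl) for lbl in y])
        return float(self._rho_batch(np.atleast_2d(X), Y_enc, scope="network").mean())


# ---------------------------------------------------------------------
# multi-layer networks
# ---------------------------------------------------------------------

class MultiLayerGTClassifier:
    """Two-layer spiking classifiers with layer-local training.

    kind 1
        Layer 1 is ``S`` frozen random sub-networks of ``D`` pairs; the
        summed mean membrane potentials of sub-network ``s`` encode the
        (negative) L1 distance ``-||Q_s t_s - x||_1`` to its centroid
        ``c_s = Q_s t_s``.  These ``S`` distances feed a fully-connected
        supervised layer — only that layer trains.
    kind 2
        Layer 1 is ``S`` sub-networks (``D`` pairs each, sparse random
        lateral connectivity) trained by sparsity descent on the raw
        input; the ON-half mean potentials (``D*S`` values, a rectified
        nonlinear encoding) feed the supervised layer.  The schedule
        trains both layers jointly first, then only the top.
    kind 3
        As kind 2, but each layer-1 sub-network also receives the label
        pairs during training and inference, letting both layers exploit
        feature-label correlations for extra sparsity.
    """

    def __init__(
        self,
        kind: int,
        D: int,
        classes,
        S: int = 10,
        seed: int = 0,
        neuron_config: NeuronConfig | None = None,
        connection_prob: float = 0.5,
        random_scale: float = 0.05,
        feature_scale: float | None = None,
    ) -> None:
        if kind not in (1, 2, 3):
            raise ValueError("kind must be 1, 2 or 3")
        self.kind = kind
        self.D = D
        self.S = S
        self.seed = seed
        self.codec = LabelCodec(classes)
        self.neuron_config = neuron_config or NeuronConfig(alpha=0.1, T_settle=400, T_avg=400)
        self.connection_prob = connection_prob
        self.random_scale = random_scale
        if feature_scale is None:
            # kind 1 features are L1 distances (up to D in magnitude);
            # kind 3's fixed inter-layer gain compensates the amplitude
            # shrinkage of its sparsified hidden activity
            feature_scale = {1: 1.0 / D, 2: 1.0, 3: 4.0}[kind]
        self.feature_scale = feature_scale
        self.history: dict[str, list[float]] = {"accuracy": [], "rho_train": []}
        self._build()

    # -- construction -------------------------------------------------
    def _build(self) -> None:
        rng = np.random.default_rng(self.seed)
        P = self.codec.P
        self.subnets: list[DifferentialNetwork] = []
        self.templates: list[np.ndarray] | None = [] if self.kind == 1 else None
        self.layer1: DifferentialNetwork | None = None
        if self.kind == 1:
            # S frozen, independent random-projection sub-networks
            for s in range(self.S):
                net = DifferentialNetwork.random_coupled(
                    self.D, scale=self.random_scale,
                    seed=int(rng.integers(2**31)), config=self.neuron_config,
                )
                t_s = rng.uniform(0.0, 1.0, self.D)
                net.t = t_s
                net.mask[:] = False
                self.templates.append(t_s)
                self.subnets.append(net)
            self.M_layer1 = self.D * self.S
            n_features = self.S
        else:
            # one coupled differential network spanning all sub-networks,
            # sparse random lateral connectivity across the whole layer
            block = self.D if self.kind == 2 else self.D + P
            M1 = block * self.S
            self.layer1 = DifferentialNetwork.random_coupled(
                M1, scale=self.random_scale, seed=int(rng.integers(2**31)),
                config=self.neuron_config, connection_prob=self.connection_prob,
            )
            self._block = block
            # indices of the feature (input) pairs inside each block
            self._xpair_idx = np.concatenate(
                [np.arange(self.D) + s * block for s in range(self.S)]
            )
            self.M_layer1 = M1
            n_features = self.D * self.S
        self.n_features = n_features
        self.top = _SupervisedLayer(n_features, P, "fully_connected", self.neuron_config)
        self.M_total = self.M_layer1 + self.top.M

    # -- layer 1 ------------------------------------------------------
    def _layer1_stimuli(self, X: np.ndarray, Y_enc: np.ndarray | None) -> np.ndarray:
        """Tile ``[x]`` (kinds 1-2) or ``[x, y]`` (kind 3) over sub-networks."""
        if self.kind == 1:
            return X
        if self.kind == 3:
            if Y_enc is None:
                raise ValueError("kind-3 layer 1 requires label vectors")
            unit = np.concatenate([X, Y_enc], axis=1)
        else:
            unit = X
        return np.tile(unit, (1, self.S))

    def layer1_features(
        self, X: np.ndarray, Y_enc: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Stage-wise layer-1 pass for a batch of samples.

        Returns ``(features, spike_fractions)``: for kind 1, (n, S)
        summed mean potentials, approximately ``-||c_s - x||_1`` per
        sub-network; for kinds 2-3, the (n, D*S) ON-half mean potentials
        of the input pairs.  ``spike_fractions`` sums the normalized
        spike counts of all layer-1 neurons per sample (the layer's
        contribution to the sparsity scope).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == 1:
            feats, counts = [], np.zeros(len(X))
            for net in self.subnets:
                ss = simulate_batch(net, X)
                feats.append((ss.v_bar_plus + ss.v_bar_minus).sum(axis=1))
                counts += (ss.s_plus + ss.s_minus).sum(axis=1)
            return np.stack(feats, axis=1), counts
        B1 = self._layer1_stimuli(X, Y_enc)
        ss = simulate_batch(self.layer1, B1)
        F = ss.v_bar_plus[:, self._xpair_idx]
        counts = (ss.s_plus + ss.s_minus).sum(axis=1)
        return F, counts

    def _train_layer1_step(self, x: np.ndarray, y_enc: np.ndarray, cfg: TrainConfig) -> np.ndarray:
        """One layer-1 presentation with a local update; returns features."""
        from dataclasses import replace

        from .learning import _presentation_update

        if cfg.eta_layer1 is not None and cfg.eta_layer1 != cfg.eta:
            cfg = replace(cfg, eta=cfg.eta_layer1)
        b = self._layer1_stimuli(x[None, :], y_enc[None, :] if y_enc is not None else None)[0]
        ss = _presentation_update(self.layer1, b, cfg, weight_update)
        return ss.v_bar_plus[self._xpair_idx]

    # -- fitting ------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y,
        cfg: TrainConfig | None = None,
        schedule: tuple[int, int] | None = None,
        track: bool = True,
        select_best: bool = False,
        X_val: np.ndarray | None = None,
        y_val=None,
        acc_tol: float = 0.0,
    ) -> "MultiLayerGTClassifier":
        """Layer-wise training with the correct label clamped.

        ``schedule = (epochs_joint, epochs_top)`` applies to kinds 2-3:
        both layers adapt during the joint phase, then only the top
        layer.  Kind 1 has no trainable layer 1, so all epochs train the
        top layer.  ``cfg.epochs`` is used when no schedule is given
        (kinds 2-3 then adapt jointly throughout).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        cfg = cfg or TrainConfig(eta=0.05, epochs=6)
        if schedule is None:
            schedule = (cfg.epochs, 0) if self.kind != 1 else (0, cfg.epochs)
        epochs_joint, epochs_top = schedule
        if epochs_joint < 0 or epochs_top < 0:
            raise ValueError("schedule epochs must be >= 0")
        if self.kind == 1:
            epochs_top += epochs_joint
            epochs_joint = 0
        Y_enc = np.stack([self.codec.encode(lbl) for lbl in y])
        init_weights(self.top.net, cfg)
        rng = np.random.default_rng(cfg.seed)

        F = None
        best = None
        for epoch in range(epochs_joint + epochs_top):
            joint = epoch < epochs_joint
            order = rng.permutation(len(X)) if cfg.shuffle else np.arange(len(X))
            if not joint and F is None:
                F, _ = self.layer1_features(X, Y_enc if self.kind == 3 else None)
                F = F * self.feature_scale
            for k in order:
                if joint:
                    f = self._train_layer1_step(X[k], Y_enc[k] if self.kind == 3 else None, cfg)
                    f = f * self.feature_scale
                else:
                    f = F[k]
                self.top.present(f, Y_enc[k], cfg)
            if track:
                rhos = self._rhos_by_candidate(X)
                labels = np.array(
                    [_argmin_prediction(self.codec.classes, r).label for r in rhos]
                )
                self.history["accuracy"].append(float(np.mean(labels == y)))
                idx = np.array([self.codec.classes.index(lbl) for lbl in y])
                self.history["rho_train"].append(float(rhos[np.arange(len(y)), idx].mean()))
                if select_best:
                    acc = (
                        self.score(X_val, y_val)
                        if X_val is not None
                        else self.history["accuracy"][-1]
                    )
                    rho_now = self.history["rho_train"][-1]
                    # best accuracy (within acc_tol counts as a tie);
                    # ties -> sparsest model, then earliest epoch
                    if (
                        best is None
                        or acc > best[0] + acc_tol
                        or (acc >= best[0] - acc_tol and rho_now < best[1])
                    ):
                        best = (
                            max(acc, best[0] if best else acc),
                            rho_now,
                            None if self.layer1 is None else self.layer1.Q.copy(),
                            self.top.net.Q.copy(),
                        )
        if select_best and best is not None:
            if best[2] is not None:
                self.layer1.Q = best[2]
            self.top.net.Q = best[3]
        return self

    # -- inference ----------------------------------------------------
    def _rho_all_layers(self, X: np.ndarray, Y_enc: np.ndarray) -> np.ndarray:
        """rho over every simulated pair with the given labels clamped."""
        F, counts1 = self.layer1_features(X, Y_enc if self.kind == 3 else None)
        B_top = self.top.stimuli(Y_enc, F * self.feature_scale)
        ss = simulate_batch(self.top.net, B_top)
        counts2 = (ss.s_plus + ss.s_minus).sum(axis=1)
        return (counts1 + counts2) / (2 * self.M_total)

    def _rhos_by_candidate(self, X: np.ndarray) -> np.ndarray:
        """(n, C) sparsity metrics, one column per candidate label.

        For kinds 1-2 layer 1 is label-independent and is simulated
        once; kind 3 re-runs it per candidate since the label pairs
        shape layer-1 activity.
        """
        n = len(X)
        rhos = np.empty((n, self.codec.C))
        if self.kind == 3:
            for ci, c in enumerate(self.codec.classes):
                Y = np.repeat(self.codec.encode(c)[None, :], n, axis=0)
                rhos[:, ci] = self._rho_all_layers(X, Y)
            return rhos
        F, counts1 = self.layer1_features(X, None)
        F = F * self.feature_scale
        for ci, c in enumerate(self.codec.classes):
            Y = np.repeat(self.codec.encode(c)[None, :], n, axis=0)
            ss = simulate_batch(self.top.net, self.top.stimuli(Y, F))
            counts2 = (ss.s_plus + ss.s_minus).sum(axis=1)
            rhos[:, ci] = (counts1 + counts2) / (2 * self.M_total)
        return rhos

    def predict(self, X: np.ndarray) -> list[Prediction]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        rhos = self._rhos_by_candidate(X)
        return [_argmin_prediction(self.codec.classes, r) for r in rhos]

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return np.array([p.label for p in self.predict(X)])

    def score(self, X, y) -> float:
        return float(np.mean(self.predict_labels(X) == np.asarray(y)))

    def rho_train(self, X, y) -> float:
        Y_enc = np.stack([self.codec.encode(lbl) for lbl in y])
        return float(self._rho_all_layers(np.atleast_2d(X), Y_enc).mean())

    # -- time series (kind 3) -----------------------------------------
    def _sequence_frames(self, seq: np.ndarray, y_enc: np.ndarray | None):
        if self.kind == 3 and y_enc is not None:
            lab = np.repeat(y_enc[None, :], len(seq), axis=0)
            return np.concatenate([seq, lab], axis=1)
        return seq

    def _layer1_sequence_pass(
        self, seq: np.ndarray, y_enc: np.ndarray | None,
        cfg: TrainConfig, update: bool,
    ) -> tuple[np.ndarray, float]:
        """Present a slowly varying input to layer 1.

        The stimulus advances one sequence step every ``frame_len``
        simulation steps while any clamped label stays fixed; updates
        (if requested) use the trailing-window means.
        """
        settle, avg = cfg.windows_for(self.layer1)
        T = settle + avg
        frames = self._sequence_frames(seq, y_enc)
        frames = np.tile(frames, (1, self.S))
        frame_len = max(1, T // len(frames))
        net = self.layer1
        _, _, ss = simulate(net, T=T, b=frames[-1], b_frames=frames, frame_len=frame_len)
        if update:
            dQ = weight_update(ss, net, cfg.eta)
            apply_update(net, dQ, cfg.clip)
        counts = float((ss.s_plus + ss.s_minus).sum())
        return ss.v_bar_plus[self._xpair_idx], counts

    def fit_sequences(
        self,
        seqs: np.ndarray,
        y,
        cfg: TrainConfig | None = None,
        schedule: tuple[int, int] | None = None,
        track: bool = False,
    ) -> "MultiLayerGTClassifier":
        """Recurrent mode: train on (K, L, D) sequences, constant labels."""
        if self.kind != 3:
            raise ValueError("sequence training is defined for kind 3")
        seqs = np.asarray(seqs, dtype=float)
        if seqs.ndim != 3 or seqs.shape[2] != self.D:
            raise ValueError("seqs must be (K, L, D)")
        y = np.asarray(y)
        cfg = cfg or TrainConfig(eta=0.05, epochs=4)
        if schedule is None:
            schedule = (cfg.epochs, 0)
        epochs_joint, epochs_top = schedule
        Y_enc = np.stack([self.codec.encode(lbl) for lbl in y])
        init_weights(self.top.net, cfg)
        rng = np.random.default_rng(cfg.seed)
        for epoch in range(epochs_joint + epochs_top):
            joint = epoch < epochs_joint
            order = rng.permutation(len(seqs)) if cfg.shuffle else np.arange(len(seqs))
            for k in order:
                f, _ = self._layer1_sequence_pass(seqs[k], Y_enc[k], cfg, update=joint)
                self.top.present(f * self.feature_scale, Y_enc[k], cfg)
            if track:
                self.history["accuracy"].append(self.score_sequences(seqs, y))
        return self

    def _rho_sequence(self, seq: np.ndarray, y_enc: np.ndarray, cfg: TrainConfig | None = None) -> float:
        cfg = cfg or TrainConfig(eta=0.0, epochs=1)
        f, counts1 = self._layer1_sequence_pass(seq, y_enc, cfg, update=False)
        b = self.top.stimulus(y_enc, f * self.feature_scale)
        _, _, ss = simulate(self.top.net, b=b)
        counts2 = float((ss.s_plus + ss.s_minus).sum())
        return (counts1 + counts2) / (2 * self.M_total)

    def predict_sequences(self, seqs: np.ndarray) -> list[Prediction]:
        seqs = np.asarray(seqs, dtype=float)
        preds = []
        for seq in seqs:
            rhos = np.array(
                [self._rho_sequence(seq, self.codec.encode(c)) for c in self.codec.classes]
            )
            preds.append(_argmin_prediction(self.codec.classes, rhos))
        return preds

    def score_sequences(self, seqs, y) -> float:
        labels = np.array([p.label for p in self.predict_sequences(seqs)])
        return float(np.mean(labels == np.asarray(y)))
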