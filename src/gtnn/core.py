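"""Growth-transform (GT) spiking neuron dynamics.

A GT neuron minimizes a power-dissipation energy
``H(v) = 1/2 Q v^2 - b v + Psi v`` over a bounded membrane potential
``|v| <= v_c`` by repeatedly applying the multiplicative growth-transform
map.  The barrier term ``Psi`` equals ``I_psi`` whenever ``v > 0`` and 0
otherwise; its temporal average plays the role of the KKT multiplier of
the threshold constraint ``v <= 0`` and encodes the firing rate.

The building block for learning is the ON-OFF *differential* network:
``M`` pairs of neurons, where pair *i* receives the stimulus ``+b_i``
(ON) and ``-b_i`` (OFF), and pairs are coupled through a generally
asymmetric synaptic matrix ``Q``.  At steady state the mean differential
potentials satisfy the linear constraint ``Q v_bar = b``.

All simulation here is fully synchronous (Jacobi updates), deterministic,
and optionally batched over independent stimulus vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "NeuronConfig",
    "DifferentialNetwork",
    "NetworkState",
    "Trace",
    "SteadyState",
    "spike_fn",
    "local_gradient",
    "gt_step",
    "simulate",
    "simulate_batch",
    "relu_curve",
]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class NeuronConfig:
    """Global dynamical constants shared by all neurons in a network.

    Parameters
    ----------
    v_c
        Magnitude of the membrane-potential bound; potentials live in
        ``[-v_c, v_c]`` with the spiking threshold at 0.
    I_psi
        Hyperpolarization parameter (barrier height).  Sets the reset
        strength after a threshold crossing and hence the maximum
        attainable firing rate.
    lambda_floor, lambda_margin
        The growth-transform normalization ``lambda`` must exceed
        ``|g|`` for every neuron.  Each step uses the adaptive value
        ``max(lambda_floor, lambda_margin * max|g|)``.
    Q_self
        Self-leakage ``Q_ii`` (fixed during learning; default 1).
    T_settle
        Steps discarded before temporal averaging begins.
    T_avg
        Length of the averaging window; spike rates are quantized on a
        grid of spacing ``1 / T_avg``.
    alpha
        Fractional-step mixing ``v <- (1-alpha) v + alpha * map(v)``.
        ``alpha = 1`` is the plain map.
    """

    v_c: float = 1.0
    I_psi: float = 1.0
    lambda_floor: float = 2.0
    lambda_margin: float = 1.1
    Q_self: float = 1.0
    T_settle: int = 200
    T_avg: int = 1000
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.v_c <= 0:
            raise ValueError("v_c must be > 0")
        if self.I_psi <= 0:
            raise ValueError("I_psi must be > 0")
        if self.lambda_floor <= 0:
            raise ValueError("lambda_floor must be > 0")
        if self.lambda_margin <= 1:
            raise ValueError("lambda_margin must be > 1")
        if self.Q_self <= 0:
            raise ValueError("Q_self must be > 0")
        if self.T_avg < 1:
            raise ValueError("T_avg must be >= 1")
        if self.T_settle < 0:
            raise ValueError("T_settle must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    @classmethod
    def fine(cls, **overrides) -> "NeuronConfig":
        """High-accuracy integration preset.

        Small fractional steps (``alpha = 0.01``) with a long settling
        transient; the steady-state temporal expectations then satisfy
        the ON-OFF encoding identities to within ~2e-3, at the cost of
        a ~10x longer simulation.  Use when the *values* of the means
        matter, not just the fixed point.
        """
        kw = dict(alpha=0.01, T_settle=10_000, T_avg=1000)
        kw.update(overrides)
        return cls(**kw)

    def to_json(self) -> str:
        d = asdict(self)
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "NeuronConfig":
        d = json.loads(s)
        d.pop("schema_version", None)
        return cls(**d)


class DifferentialNetwork:
    """``M`` ON-OFF neuron pairs coupled by a synaptic matrix ``Q``.

    ``Q`` need not be symmetric.  The diagonal is pinned to
    ``config.Q_self`` and is never trainable; ``mask`` marks the
    off-diagonal entries that learning may modify.  ``b`` is the external
    stimulus vector and ``t`` an optional template vector: when set, the
    effective stimulus becomes ``b - Q t`` (template projection),
    recomputed from the current ``Q``.
    """

    def __init__(
        self,
        Q: np.ndarray,
        config: NeuronConfig | None = None,
        mask: np.ndarray | None = None,
        b: np.ndarray | None = None,
        t: np.ndarray | None = None,
    ) -> None:
        Q = np.array(Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be a square matrix")
        self.config = config or NeuronConfig()
        self.M = Q.shape[0]
        np.fill_diagonal(Q, self.config.Q_self)
        self.Q = Q
        if mask is None:
            mask = ~np.eye(self.M, dtype=bool)
        else:
            mask = np.array(mask, dtype=bool)
            if mask.shape != Q.shape:
                raise ValueError("mask shape must match Q")
            mask = mask & ~np.eye(self.M, dtype=bool)
        self.mask = mask
        self.b = np.zeros(self.M) if b is None else np.asarray(b, dtype=float).copy()
        self.t = None if t is None else np.asarray(t, dtype=float).copy()
        if self.b.shape != (self.M,):
            raise ValueError("b must have length M")
        if self.t is not None and self.t.shape != (self.M,):
            raise ValueError("t must have length M")

    # -- constructors -------------------------------------------------
    @classmethod
    def uncoupled(cls, M: int, config: NeuronConfig | None = None, **kw) -> "DifferentialNetwork":
        """Isolated pairs: zero off-diagonal weights, all trainable."""
        return cls(np.zeros((M, M)), config=config, **kw)

    @classmethod
    def random_coupled(
        cls,
        M: int,
        scale: float = 0.1,
        seed: int | np.random.Generator = 0,
        config: NeuronConfig | None = None,
        connection_prob: float = 1.0,
        **kw,
    ) -> "DifferentialNetwork":
        """Off-diagonal weights i.i.d. uniform in ``[-scale, scale]``.

        ``connection_prob < 1`` zeros a random subset of off-diagonal
        entries and freezes them (mask false), as used by the layer-1
        networks of the multi-layer architectures.
        """
        rng = np.random.default_rng(seed)
        Q = rng.uniform(-scale, scale, size=(M, M))
        mask = ~np.eye(M, dtype=bool)
        if connection_prob < 1.0:
            keep = rng.random((M, M)) < connection_prob
            mask &= keep
            Q = np.where(mask, Q, 0.0)
        net = cls(Q, config=config, mask=mask, **kw)
        return net

    # -- helpers ------------------------------------------------------
    def effective_input(self, b: np.ndarray | None = None) -> np.ndarray:
        """Stimulus actually seen by the pairs: ``b`` or ``b - Q t``."""
        b = self.b if b is None else np.asarray(b, dtype=float)
        if self.t is not None:
            return b - self.Q @ self.t
        return b

    def copy(self) -> "DifferentialNetwork":
        return DifferentialNetwork(
            self.Q.copy(), config=self.config, mask=self.mask.copy(),
            b=self.b.copy(), t=None if self.t is None else self.t.copy(),
        )


@dataclass
class NetworkState:
    """Instantaneous state of a differential network."""

    v_plus: np.ndarray
    v_minus: np.ndarray
    psi_plus: np.ndarray
    psi_minus: np.ndarray
    step: int = 0

    @classmethod
    def zeros(cls, M: int) -> "NetworkState":
        return cls(np.zeros(M), np.zeros(M), np.zeros(M), np.zeros(M), 0)


@dataclass
class Trace:
    """Recorded membrane history and spike events.

    ``spike_events`` rows are ``(step, pair_index, polarity)`` with
    polarity +1 for the ON neuron and -1 for the OFF neuron.  A spike
    event at step ``n`` exists iff the corresponding membrane potential
    is above threshold (> 0) at that step.
    """

    v_plus_hist: np.ndarray
    v_minus_hist: np.ndarray
    spike_events: np.ndarray  # (n_events, 3) int array
    T: int

    def to_events_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.spike_events, columns=["step", "pair_index", "polarity"]
        )

    def to_membrane_frame(self):
        import pandas as pd

        M = self.v_plus_hist.shape[1]
        cols = {f"v_plus_{i}": self.v_plus_hist[:, i] for i in range(M)}
        cols.update({f"v_minus_{i}": self.v_minus_hist[:, i] for i in range(M)})
        df = pd.DataFrame(cols)
        df.insert(0, "step", np.arange(self.T))
        return df


@dataclass
class SteadyState:
    """Temporal expectations over the trailing averaging window.

    ``s_plus`` / ``s_minus`` are normalized spike counts
    ``s = psi_bar / I_psi`` in ``[0, 1]`` on a grid of spacing
    ``1 / window``; ``psi_bar = I_psi * s`` exactly by construction.
    ``residual_l1`` is ``||Q v_bar - b_eff||_1`` with
    ``v_bar = v_bar_plus - v_bar_minus``.
    """

    v_bar_plus: np.ndarray
    v_bar_minus: np.ndarray
    psi_bar_plus: np.ndarray
    psi_bar_minus: np.ndarray
    s_plus: np.ndarray
    s_minus: np.ndarray
    residual_l1: float
    window: int

    @property
    def v_bar(self) -> np.ndarray:
        return self.v_bar_plus - self.v_bar_minus

    @property
    def total_spike_fraction(self) -> float:
        """Sum of normalized spike counts over all 2M neurons."""
        return float(np.sum(self.s_plus) + np.sum(self.s_minus))

    @property
    def loss(self) -> float:
        """Total mean spiking activity ``sum_i (psi_bar+ + psi_bar-)``."""
        return float(np.sum(self.psi_bar_plus) + np.sum(self.psi_bar_minus))

    def to_json(self) -> str:
        d = {
            "v_bar_plus": self.v_bar_plus.tolist(),
            "v_bar_minus": self.v_bar_minus.tolist(),
            "psi_bar_plus": self.psi_bar_plus.tolist(),
            "psi_bar_minus": self.psi_bar_minus.tolist(),
            "s_plus": self.s_plus.tolist(),
            "s_minus": self.s_minus.tolist(),
            "residual_l1": self.residual_l1,
            "window": self.window,
        }
        return json.dumps(d)


# ---------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------

def spike_fn(v, I_psi: float):
    """Barrier spike function: ``I_psi`` if ``v > 0`` else 0.

    Total on scalars and arrays; the boundary ``v = 0`` belongs to the
    sub-threshold branch.
    """
    if I_psi <= 0:
        raise ValueError("I_psi must be > 0")
    return np.where(np.asarray(v) > 0, I_psi, 0.0)[()]


def gt_step(v, g, lam: float, v_c: float):
    """One application of the growth-transform fixed-point map.

    ``v' = v_c (-g v_c + lam v) / (-g v + lam v_c)``.  Requires
    ``lam > |g|``; under that condition ``|v'| <= v_c`` and the map
    descends the energy ``H`` (``sign(v' - v) = sign(-g)`` in the
    interior).
    """
    v = np.asarray(v, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(lam <= np.abs(g)):
        raise ValueError("growth-transform requires lam > |g|")
    return (v_c * (-g * v_c + lam * v) / (-g * v + lam * v_c))[()]


def local_gradient(
    net: DifferentialNetwork,
    state: NetworkState,
    i: int,
    polarity: int,
) -> float:
    """Energy gradient seen by one neuron of pair ``i``.

    For the ON neuron (polarity +1)::

        g = Q_self * v+_i - beta_i + Psi+_i,
        beta_i = b_eff_i - sum_{j != i} Q_ij (v+_j - v-_j)

    and for the OFF neuron the effective input is negated with
    ``v-, Psi-`` substituted.  ``b_eff`` honours the template shift
    ``b - Q t`` when a template is set.
    """
    if not 0 <= i < net.M:
        raise IndexError(f"pair index {i} out of range for M={net.M}")
    if polarity not in (+1, -1):
        raise ValueError("polarity must be +1 or -1")
    v_diff = state.v_plus - state.v_minus
    b_eff = net.effective_input()
    coupling = net.Q[i] @ v_diff - net.config.Q_self * v_diff[i]
    beta = b_eff[i] - coupling
    if polarity == +1:
        return float(net.config.Q_self * state.v_plus[i] - beta + state.psi_plus[i])
    return float(net.config.Q_self * state.v_minus[i] + beta + state.psi_minus[i])


# ---------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------

class SimulationError(RuntimeError):
    """Raised when the dynamics become non-finite."""


try:  # optional compiled kernel; the numpy path below is the reference
    import numba as _numba

    @_numba.njit(cache=False, fastmath=False)
    def _kernel(offT, b_sched, step_frame, vp, vm, Ipsi, Qs, vc,
                lfloor, lmargin, alpha, T, start,
                sum_vp, sum_vm, cnt_p, cnt_m, hist_p, hist_m, record):
        # b_sched: (F, B, M); step_frame: (T,) frame index per step
        B, M = vp.shape
        gp = np.empty((B, M))
        gm = np.empty((B, M))
        ok = True
        for n in range(T):
            b_now = b_sched[step_frame[n]]
            coup = np.dot(vp - vm, offT)
            for bi in range(B):
                gmax = 0.0
                for j in range(M):
                    beta = b_now[bi, j] - coup[bi, j]
                    psi_p = Ipsi if vp[bi, j] > 0 else 0.0
                    psi_m = Ipsi if vm[bi, j] > 0 else 0.0
                    a = Qs * vp[bi, j] - beta + psi_p
                    c = Qs * vm[bi, j] + beta + psi_m
                    gp[bi, j] = a
                    gm[bi, j] = c
                    if abs(a) > gmax:
                        gmax = abs(a)
                    if abs(c) > gmax:
                        gmax = abs(c)
                lam = lmargin * gmax
                if lam < lfloor:
                    lam = lfloor
                for j in range(M):
                    nvp = vc * (-gp[bi, j] * vc + lam * vp[bi, j]) / (
                        -gp[bi, j] * vp[bi, j] + lam * vc)
                    nvm = vc * (-gm[bi, j] * vc + lam * vm[bi, j]) / (
                        -gm[bi, j] * vm[bi, j] + lam * vc)
                    if alpha < 1.0:
                        nvp = (1.0 - alpha) * vp[bi, j] + alpha * nvp
                        nvm = (1.0 - alpha) * vm[bi, j] + alpha * nvm
                    vp[bi, j] = nvp
                    vm[bi, j] = nvm
                    if not (np.isfinite(nvp) and np.isfinite(nvm)):
                        ok = False
                    if n >= start:
                        sum_vp[bi, j] += nvp
                        sum_vm[bi, j] += nvm
                        if nvp > 0:
                            cnt_p[bi, j] += 1
                        if nvm > 0:
                            cnt_m[bi, j] += 1
            if record:
                for j in range(M):
                    hist_p[n, j] = vp[0, j]
                    hist_m[n, j] = vm[0, j]
            if not ok:
                return n
        return -1

except Exception:  # pragma: no cover - numba genuinely absent
    _numba = None


def _run_batch(
    Q: np.ndarray,
    b_eff: np.ndarray,
    cfg: NeuronConfig,
    T: int,
    v_plus0: np.ndarray,
    v_minus0: np.ndarray,
    record: bool = False,
    b_frames: np.ndarray | None = None,
    frame_len: int = 1,
):
    """Synchronous simulation of a differential network.

    ``b_eff``: (B, M) effective stimuli, one independent simulation per
    row.  Returns per-row window sums and counts over the trailing
    ``min(T_avg, T)`` steps, plus optional dense history (B = 1 only).

    ``b_frames``: optional (F, M) piecewise-constant stimulus schedule
    (overrides ``b_eff``; frame ``k`` drives steps
    ``[k*frame_len, (k+1)*frame_len)``, last frame held to the end).
    """
    B, M = b_eff.shape
    vc, Ipsi, Qs = cfg.v_c, cfg.I_psi, cfg.Q_self
    off = Q - np.diag(np.diag(Q))
    offT = np.ascontiguousarray(off.T)  # v_diff @ offT == off @ v_diff row-wise
    window = min(cfg.T_avg, T)
    start = T - window

    vp = np.array(v_plus0, dtype=float).reshape(B, M).copy()
    vm = np.array(v_minus0, dtype=float).reshape(B, M).copy()

    sum_vp = np.zeros((B, M))
    sum_vm = np.zeros((B, M))
    cnt_p = np.zeros((B, M), dtype=np.int64)
    cnt_m = np.zeros((B, M), dtype=np.int64)

    hist_p = np.empty((T, M)) if record and B == 1 else None
    hist_m = np.empty((T, M)) if record and B == 1 else None

    alpha = cfg.alpha

    if _numba is not None:
        if b_frames is not None:
            b_sched = np.ascontiguousarray(b_frames[:, None, :])
            step_frame = np.minimum(np.arange(T) // frame_len, len(b_frames) - 1)
        else:
            b_sched = np.ascontiguousarray(b_eff[None, :, :])
            step_frame = np.zeros(T, dtype=np.int64)
        hp = hist_p if hist_p is not None else np.empty((0, M))
        hm = hist_m if hist_m is not None else np.empty((0, M))
        bad = _kernel(
            offT, b_sched, step_frame.astype(np.int64), vp, vm, Ipsi, Qs, vc,
            cfg.lambda_floor, cfg.lambda_margin, alpha, T, start,
            sum_vp, sum_vm, cnt_p, cnt_m, hp, hm, hist_p is not None,
        )
        if bad >= 0:
            raise SimulationError(f"non-finite membrane potential at step {bad}")
        return vp, vm, sum_vp, sum_vm, cnt_p, cnt_m, window, hist_p, hist_m

    for n in range(T):
        psi_p = np.where(vp > 0, Ipsi, 0.0)
        psi_m = np.where(vm > 0, Ipsi, 0.0)
        if b_frames is not None:
            b_now = b_frames[min(n // frame_len, len(b_frames) - 1)]
        else:
            b_now = b_eff
        beta = b_now - (vp - vm) @ offT
        gp = Qs * vp - beta + psi_p
        gm = Qs * vm + beta + psi_m
        gmax = np.maximum(np.abs(gp).max(axis=1), np.abs(gm).max(axis=1))
        lam = np.maximum(cfg.lambda_floor, cfg.lambda_margin * gmax)[:, None]
        new_vp = vc * (-gp * vc + lam * vp) / (-gp * vp + lam * vc)
        new_vm = vc * (-gm * vc + lam * vm) / (-gm * vm + lam * vc)
        if alpha < 1.0:
            new_vp = (1 - alpha) * vp + alpha * new_vp
            new_vm = (1 - alpha) * vm + alpha * new_vm
        vp, vm = new_vp, new_vm
        if not (np.all(np.isfinite(vp)) and np.all(np.isfinite(vm))):
            bad = np.argwhere(~np.isfinite(vp) | ~np.isfinite(vm))
            raise SimulationError(
                f"non-finite membrane potential at step {n}, (batch, pair)={bad[0].tolist()}"
            )
        if hist_p is not None:
            hist_p[n] = vp[0]
            hist_m[n] = vm[0]
        if n >= start:
            sum_vp += vp
            sum_vm += vm
            cnt_p += vp > 0
            cnt_m += vm > 0

    return vp, vm, sum_vp, sum_vm, cnt_p, cnt_m, window, hist_p, hist_m


def _steady_from_sums(Q, b_eff, cfg, sum_vp, sum_vm, cnt_p, cnt_m, window):
    v_bar_p = sum_vp / window
    v_bar_m = sum_vm / window
    s_p = cnt_p / window
    s_m = cnt_m / window
    psi_p = cfg.I_psi * s_p
    psi_m = cfg.I_psi * s_m
    v_bar = v_bar_p - v_bar_m
    residual = np.abs(v_bar @ Q.T - b_eff).sum(axis=-1)
    return v_bar_p, v_bar_m, psi_p, psi_m, s_p, s_m, residual


def simulate(
    net: DifferentialNetwork,
    T: int | None = None,
    init: NetworkState | None = None,
    record: bool = False,
    b: np.ndarray | None = None,
    b_frames: np.ndarray | None = None,
    frame_len: int = 1,
) -> tuple[NetworkState, Trace | None, SteadyState]:
    """Simulate a differential network for ``T`` synchronous steps.

    Per step, all spike functions are computed from the current
    potentials, then all gradients, then every neuron applies one
    growth-transform map (Jacobi update).  The returned
    :class:`SteadyState` averages the trailing ``min(T_avg, T)`` steps.

    ``b`` overrides ``net.b`` for this run; ``b_frames`` supplies a
    piecewise-constant stimulus schedule for slowly varying inputs.
    """
    cfg = net.config
    if T is None:
        T = cfg.T_settle + cfg.T_avg
    if T < 1:
        raise ValueError("T must be >= 1")
    b_run = net.b if b is None else np.asarray(b, dtype=float)
    b_eff = net.effective_input(b_run)[None, :]
    frames = None
    if b_frames is not None:
        frames = np.asarray(b_frames, dtype=float)
        if net.t is not None:
            frames = frames - net.Q @ net.t
    if init is None:
        v_p0 = np.zeros((1, net.M))
        v_m0 = np.zeros((1, net.M))
    else:
        v_p0 = init.v_plus[None, :]
        v_m0 = init.v_minus[None, :]
    vp, vm, s_vp, s_vm, c_p, c_m, window, hp, hm = _run_batch(
        net.Q, b_eff, cfg, T, v_p0, v_m0, record=record,
        b_frames=frames, frame_len=frame_len,
    )
    psi_p_now = spike_fn(vp[0], cfg.I_psi)
    psi_m_now = spike_fn(vm[0], cfg.I_psi)
    state = NetworkState(vp[0], vm[0], psi_p_now, psi_m_now, step=T)
    vbp, vbm, pbp, pbm, sp, sm, res = _steady_from_sums(
        net.Q, b_eff, cfg, s_vp, s_vm, c_p, c_m, window
    )
    ss = SteadyState(vbp[0], vbm[0], pbp[0], pbm[0], sp[0], sm[0], float(res[0]), window)
    trace = None
    if record:
        if hp is None:
            raise ValueError("record=True requires an unbatched run")
        ev_p = np.argwhere(hp > 0)
        ev_m = np.argwhere(hm > 0)
        events = np.concatenate(
            [
                np.column_stack([ev_p, np.full(len(ev_p), 1, dtype=int)]),
                np.column_stack([ev_m, np.full(len(ev_m), -1, dtype=int)]),
            ]
        )
        events = events[np.lexsort((events[:, 2], events[:, 1], events[:, 0]))]
        trace = Trace(hp, hm, events.astype(int), T)
    return state, trace, ss


def simulate_batch(
    net: DifferentialNetwork,
    B: np.ndarray,
    T: int | None = None,
) -> SteadyState:
    """Simulate many independent stimuli at once.

    ``B`` is (n, M): one row per stimulus; all runs share ``net.Q`` and
    start from zero state.  Returns a :class:`SteadyState` whose fields
    are (n, M) arrays (``residual_l1`` is an (n,) array).
    """
    cfg = net.config
    if T is None:
        T = cfg.T_settle + cfg.T_avg
    Bm = np.asarray(B, dtype=float)
    if Bm.ndim != 2 or Bm.shape[1] != net.M:
        raise ValueError("B must be (n, M)")
    if net.t is not None:
        b_eff = Bm - net.Q @ net.t
    else:
        b_eff = Bm
    n = Bm.shape[0]
    z = np.zeros((n, net.M))
    _, _, s_vp, s_vm, c_p, c_m, window, _, _ = _run_batch(
        net.Q, b_eff, cfg, T, z, z.copy()
    )
    vbp, vbm, pbp, pbm, sp, sm, res = _steady_from_sums(
        net.Q, b_eff, cfg, s_vp, s_vm, c_p, c_m, window
    )
    return SteadyState(vbp, vbm, pbp, pbm, sp, sm, res, window)


def relu_curve(
    b_values: Sequence[float],
    Q_self: float,
    cfg: NeuronConfig | None = None,
    T: int | None = None,
) -> np.ndarray:
    """Mean spike function of a single (non-differential) GT neuron.

    Simulates one neuron with leakage ``Q_self`` for each input in
    ``b_values`` and returns ``psi_bar``.  As ``Q_self -> 0`` the curve
    approaches ``ReLU(b)`` up to the rate-quantization of the finite
    averaging window and saturation at ``I_psi``.
    """
    if Q_self <= 0:
        raise ValueError("Q_self must be > 0")
    cfg = cfg or NeuronConfig()
    if T is None:
        T = cfg.T_settle + cfg.T_avg
    b = np.asarray(b_values, dtype=float)[:, None]  # (B, 1)
    v = np.zeros_like(b)
    window = min(cfg.T_avg, T)
    start = T - window
    cnt = np.zeros_like(b)
    for n in range(T):
        psi = np.where(v > 0, cfg.I_psi, 0.0)
        g = Q_self * v - b + psi
        lam = np.maximum(cfg.lambda_floor, cfg.lambda_margin * np.abs(g).max(axis=1))[:, None]
        v = cfg.v_c * (-g * cfg.v_c + lam * v) / (-g * v + lam * cfg.v_c)
        if n >= start:
            cnt += v > 0
    return (cfg.I_psi * cnt / window)[:, 0]
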