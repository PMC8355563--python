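"""Spike statistics: sparsity metrics, PSTHs, and population trajectories.

The central quantity is the sparsity metric

    rho = 1/(2M) * sum_i (s+_i + s-_i),

the normalized mean spike count averaged over all 2M neurons in scope;
rho = 0 is a silent network, rho = 1 a fully saturated one.  The
remaining helpers bin spike events over time (PSTH) and project binned
population activity onto principal components, the standard way to
visualize how a spiking population unfolds in response to a stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SteadyState, Trace

__all__ = [
    "SparsityReport",
    "BinnedCounts",
    "rho",
    "rho_report",
    "psth",
    "population_trajectory",
]


@dataclass
class SparsityReport:
    """Sparsity metrics of a model on a dataset."""

    rho_train: float | None = None
    rho_test: float | None = None
    per_pair: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "rho_train": self.rho_train,
            "rho_test": self.rho_test,
            "per_pair": None if self.per_pair is None else list(map(float, self.per_pair)),
        }


@dataclass
class BinnedCounts:
    """Spike counts per (time bin, neuron).

    Columns 0..M-1 are the ON neurons, M..2M-1 the OFF neurons.
    """

    counts: np.ndarray
    bin_width: int
    normalized: bool = False

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def to_frame(self):
        import pandas as pd

        M = self.counts.shape[1] // 2
        cols = [f"on_{i}" for i in range(M)] + [f"off_{i}" for i in range(M)]
        df = pd.DataFrame(self.counts, columns=cols)
        df.insert(0, "bin", np.arange(self.n_bins))
        return df


def rho(ss: SteadyState, M: int | None = None) -> float:
    """Sparsity metric from a steady state (or batch of them)."""
    s = ss.s_plus + ss.s_minus
    m = s.shape[-1]
    if M is not None and M != m:
        raise ValueError(f"M={M} does not match steady state with {m} pairs")
    val = s.sum(axis=-1) / (2 * m)
    return float(val) if np.ndim(val) == 0 else val


def rho_report(model, X_train=None, y_train=None, X_test=None, y_test=None) -> SparsityReport:
    """Sparsity of a supervised model with the correct labels clamped."""
    rep = SparsityReport()
    if X_train is not None:
        rep.rho_train = model.rho_train(X_train, y_train)
    if X_test is not None:
        rep.rho_test = model.rho_train(X_test, y_test)
    return rep


def psth(trace: Trace, bin_width: int) -> BinnedCounts:
    """Bin a trace's spike events over time.

    Spike conservation is exact: the matrix sums to the number of
    events in the trace.  The last bin may cover fewer than
    ``bin_width`` steps when ``bin_width`` does not divide ``T``.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if trace.T == 0:
        raise ValueError("empty trace")
    M = trace.v_plus_hist.shape[1]
    n_bins = -(-trace.T // bin_width)
    counts = np.zeros((n_bins, 2 * M), dtype=np.int64)
    if len(trace.spike_events):
        steps = trace.spike_events[:, 0] // bin_width
        pairs = trace.spike_events[:, 1]
        pol = trace.spike_events[:, 2]
        cols = np.where(pol > 0, pairs, pairs + M)
        np.add.at(counts, (steps, cols), 1)
    return BinnedCounts(counts, bin_width)


def population_trajectory(
    counts: BinnedCounts, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal-component trajectory of binned population activity.

    Each neuron's count column is max-normalized, then decomposed with
    PCA.  Returns ``(trajectory, explained_variance_ratio,
    eigenspectrum)``: the (bins, k) component scores, the
    non-increasing variance ratios of those k components, and the full
    spectrum of length ``min(bins, neurons)``.

    An all-zero count matrix yields a zero trajectory and an all-zero
    spectrum (flagged by ``explained_variance_ratio`` summing to 0).
    """
    from sklearn.decomposition import PCA

    X = counts.counts.astype(float)
    if np.all(X == 0):
        k = min(n_components, min(X.shape))
        spec = np.zeros(min(X.shape))
        return np.zeros((X.shape[0], k)), np.zeros(k), spec
    colmax = X.max(axis=0)
    colmax[colmax == 0] = 1.0
    Xn = X / colmax
    k_full = min(X.shape)
    pca = PCA(n_components=k_full)
    scores = pca.fit_transform(Xn)
    k = min(n_components, k_full)
    return scores[:, :k], pca.explained_variance_ratio_[:k], pca.explained_variance_
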