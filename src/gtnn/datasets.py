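"""Seeded synthetic datasets, preprocessing, and the few-shot protocol.

Every generator is a pure function of its parameters and seed, returns a
:class:`LabeledDataset` (or a sequence dataset), and writes/reads plain
CSV.  The fixtures mirror the study conditions the architectures are
exercised under:

* 2-D linearly separable blobs (linear classification),
* 2-D XOR quadrant clusters (non-linear classification),
* isotropic point clusters (domain description / anomaly detection),
* multi-batch 16-dimensional "drift" data whose class means random-walk
  across batches with per-sample concentration scaling (emulating a
  metal-oxide gas-sensor array drifting over time),
* slowly varying multi-channel time series with a constant label per
  sequence.

The few-shot reset protocol selects a fixed number of shots per class
for training, a validation fraction, and leaves the rest as test; the
[0, 1] feature scaler is always fitted on the training rows only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "SequenceDataset",
    "FewShotProtocol",
    "MinMaxScaler01",
    "gen_blobs2d",
    "gen_xor",
    "gen_cluster",
    "gen_drift_batches",
    "gen_timeseries",
    "few_shot_split",
    "scale01",
    "load_gas_drift",
    "linear_oracle_accuracy",
]


@dataclass
class MinMaxScaler01:
    """Per-feature affine map of the training data onto [0, 1]."""

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler01":
        X = np.atleast_2d(X)
        return cls(X.min(axis=0), X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        return (np.atleast_2d(X) - self.mins) / span

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        return np.atleast_2d(X) * span + self.mins


@dataclass
class LabeledDataset:
    """Feature matrix with optional labels, split tags, and scaler."""

    X: np.ndarray
    y: np.ndarray | None = None
    split: np.ndarray | None = None  # per-row tag in {train, val, test}
    scaler: MinMaxScaler01 | None = None
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.X)

    def rows(self, tag: str) -> tuple[np.ndarray, np.ndarray | None]:
        if self.split is None:
            raise ValueError("dataset has no split tags")
        m = self.split == tag
        return self.X[m], None if self.y is None else self.y[m]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=[f"f{i}" for i in range(self.X.shape[1])])
        if self.y is not None:
            df["label"] = self.y
        if self.split is not None:
            df["split"] = self.split
        df.to_csv(path, index=False)
        if self.params:
            Path(str(path) + ".json").write_text(json.dumps(self.params, default=str))

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        df = pd.read_csv(path, comment="#")
        feat_cols = [c for c in df.columns if c.startswith("f")]
        y = df["label"].to_numpy() if "label" in df.columns else None
        split = df["split"].to_numpy() if "split" in df.columns else None
        params = {}
        side = Path(str(path) + ".json")
        if side.exists():
            params = json.loads(side.read_text())
        return cls(df[feat_cols].to_numpy(dtype=float), y, split, params=params)


@dataclass
class SequenceDataset:
    """(K, L, D) sequences with one constant label per sequence."""

    X: np.ndarray
    y: np.ndarray
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class FewShotProtocol:
    """Reset-learning bookkeeping: shots per class, validation fraction.

    A class with fewer samples than ``shots`` contributes all of them
    to the training split.  ``reset`` marks that the model is retrained
    from scratch on each incoming batch.
    """

    shots: int = 10
    val_frac: float = 0.1
    seed: int = 0
    reset: bool = True

    def __post_init__(self) -> None:
        if self.shots < 1:
            raise ValueError("shots must be >= 1")
        if not 0 <= self.val_frac < 1:
            raise ValueError("val_frac must be in [0, 1)")


# ---------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------

def _truncated_normal(rng, loc, scale, size):
    """Gaussian noise with its norm clipped at 3 sigma per sample.

    Bounding the displacement (not just each component) guarantees the
    margin properties the 2-D fixtures advertise.
    """
    z = rng.standard_normal(size)
    norms = np.linalg.norm(z, axis=-1, keepdims=True)
    z = z * np.minimum(1.0, 3.0 / np.maximum(norms, 1e-12))
    return loc + scale * z


def gen_blobs2d(
    n_per_class: int = 100,
    separation: float = 2.0,
    noise: float = 0.3,
    seed: int = 0,
) -> LabeledDataset:
    """Two noisy blobs with labels -1 / +1, separable by a line.

    Centers sit ``separation`` apart along the (1, 1) diagonal; the
    noise is a 3-sigma-truncated Gaussian, so the perpendicular
    separating line is guaranteed a margin of at least
    ``separation - 2 * 3 * noise / 2 = separation - 3 * noise``.
    """
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = np.random.default_rng(seed)
    u = np.array([1.0, 1.0]) / np.sqrt(2)
    c_neg = -u * separation / 2
    c_pos = u * separation / 2
    X = np.concatenate(
        [
            _truncated_normal(rng, c_neg, noise, (n_per_class, 2)),
            _truncated_normal(rng, c_pos, noise, (n_per_class, 2)),
        ]
    )
    y = np.concatenate([-np.ones(n_per_class), np.ones(n_per_class)]).astype(int)
    params = dict(kind="blobs2d", n_per_class=n_per_class, separation=separation, noise=noise, seed=seed)
    return LabeledDataset(X, y, params=params)


def gen_xor(
    n_per_quadrant: int = 25,
    noise: float = 0.15,
    seed: int = 0,
    scale: float = 0.5,
) -> LabeledDataset:
    """Four Gaussian quadrant clusters; label = XOR of coordinate signs.

    Quadrants (+,+) and (-,-) belong to class +1, the mixed-sign
    quadrants to class -1.  No line separates the classes (a linear
    rule cannot exceed ~75% accuracy as noise vanishes).  Noise is
    3-sigma truncated, as in :func:`gen_blobs2d`.
    """
    rng = np.random.default_rng(seed)
    centers = scale * np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
    labels = np.array([1, 1, -1, -1])
    Xs, ys = [], []
    for c, lbl in zip(centers, labels):
        Xs.append(_truncated_normal(rng, c, noise, (n_per_quadrant, 2)))
        ys.append(np.full(n_per_quadrant, lbl))
    params = dict(kind="xor", n_per_quadrant=n_per_quadrant, noise=noise, seed=seed, scale=scale)
    return LabeledDataset(np.concatenate(Xs), np.concatenate(ys).astype(int), params=params)


def gen_cluster(
    center,
    spread: float = 0.1,
    n: int = 20,
    seed: int = 0,
) -> LabeledDataset:
    """Isotropic Gaussian point cloud (unlabeled), for domain description."""
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    X = rng.normal(center, spread, size=(n, len(center)))
    params = dict(kind="cluster", center=center.tolist(), spread=spread, n=n, seed=seed)
    return LabeledDataset(X, None, params=params)


def gen_drift_batches(
    n_batches: int = 10,
    D: int = 16,
    C: int = 6,
    n_per_class: int = 30,
    drift_scale: float = 0.15,
    spread: float = 0.05,
    conc_range: tuple[float, float] = (0.5, 1.5),
    seed: int = 0,
) -> list[LabeledDataset]:
    """Multi-batch classification data with sensor-style drift.

    Each class has a base response profile in ``[0.2, 0.8]^D``; from
    batch to batch every class mean takes a Gaussian random-walk step of
    scale ``drift_scale`` (distribution shift over time).  Each sample
    is its class mean times a random concentration factor plus isotropic
    noise, mimicking wide within-class intensity variation.
    """
    rng = np.random.default_rng(seed)
    means = rng.uniform(0.2, 0.8, size=(C, D))
    batches = []
    for b in range(n_batches):
        Xs, ys = [], []
        for c in range(C):
            conc = rng.uniform(*conc_range, size=(n_per_class, 1))
            Xc = conc * means[c] + rng.normal(0, spread, size=(n_per_class, D))
            Xs.append(Xc)
            ys.append(np.full(n_per_class, c))
        params = dict(
            kind="drift", batch=b, n_batches=n_batches, D=D, C=C,
            n_per_class=n_per_class, drift_scale=drift_scale, spread=spread, seed=seed,
        )
        batches.append(
            LabeledDataset(np.concatenate(Xs), np.concatenate(ys).astype(int), params=params)
        )
        means = means + rng.normal(0, drift_scale, size=(C, D))
    return batches


def gen_timeseries(
    classes: int = 2,
    D: int = 6,
    L: int = 480,
    n_per_class: int = 10,
    noise: float = 0.05,
    seed: int = 0,
) -> SequenceDataset:
    """Slowly varying multi-channel sequences with constant labels.

    Each class has a smooth mean trajectory per channel (offset plus a
    low-frequency sinusoid); samples add white noise.  Classes differ in
    their offsets and phases, so a nearest-mean rule distinguishes them
    as noise vanishes.
    """
    rng = np.random.default_rng(seed)
    tgrid = np.arange(L) / L
    Xs, ys = [], []
    for c in range(classes):
        offset = rng.uniform(0.2, 0.8, size=D)
        amp = rng.uniform(0.05, 0.15, size=D)
        phase = rng.uniform(0, 2 * np.pi, size=D)
        freq = rng.integers(1, 3, size=D)
        mean = offset + amp * np.sin(2 * np.pi * freq * tgrid[:, None] + phase)  # (L, D)
        for _ in range(n_per_class):
            Xs.append(mean + rng.normal(0, noise, size=(L, D)))
            ys.append(c)
    params = dict(kind="timeseries", classes=classes, D=D, L=L,
                  n_per_class=n_per_class, noise=noise, seed=seed)
    return SequenceDataset(np.stack(Xs), np.array(ys), params=params)


# ---------------------------------------------------------------------
# protocol helpers
# ---------------------------------------------------------------------

def few_shot_split(ds: LabeledDataset, protocol: FewShotProtocol) -> LabeledDataset:
    """Tag rows as train/val/test per the few-shot protocol.

    ``shots`` samples per class (all of them if the class is smaller)
    go to train; ``val_frac`` of the full batch goes to validation;
    everything else is test.
    """
    if ds.y is None:
        raise ValueError("few-shot split needs labels")
    rng = np.random.default_rng(protocol.seed)
    n = len(ds)
    split = np.full(n, "test", dtype=object)
    for c in np.unique(ds.y):
        idx = np.flatnonzero(ds.y == c)
        take = min(protocol.shots, len(idx))
        chosen = rng.choice(idx, size=take, replace=False)
        split[chosen] = "train"
    rest = np.flatnonzero(split != "train")
    n_val = int(protocol.val_frac * n)
    if n_val > 0 and len(rest) > 0:
        val = rng.choice(rest, size=min(n_val, len(rest)), replace=False)
        split[val] = "val"
    return LabeledDataset(ds.X, ds.y, split.astype(str), params=dict(ds.params))


def scale01(ds: LabeledDataset) -> LabeledDataset:
    """Fit a [0, 1] scaler on the training rows and transform all rows."""
    if ds.split is None:
        scaler = MinMaxScaler01.fit(ds.X)
    else:
        Xtr, _ = ds.rows("train")
        scaler = MinMaxScaler01.fit(Xtr)
    return LabeledDataset(
        scaler.transform(ds.X), ds.y, ds.split, scaler=scaler, params=dict(ds.params)
    )


def load_gas_drift(path) -> list[LabeledDataset]:
    """Read an externally prepared gas-sensor drift table (CSV).

    Expects columns ``batch``, ``label``, and 16 steady-state sensor
    features ``f0..f15`` (one per chemosensor).  Returns one dataset per
    batch, ordered by batch id.  The file is never downloaded: obtain
    and preprocess it separately.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found; the gas-sensor drift table must be downloaded "
            "and converted to CSV (columns batch,label,f0..f15) by the user"
        )
    df = pd.read_csv(path, comment="#")
    feat_cols = [f"f{i}" for i in range(16)]
    missing = [c for c in ["batch", "label", *feat_cols] if c not in df.columns]
    if missing:
        raise ValueError(f"gas-drift table missing columns: {missing}")
    bad = df[feat_cols].isna().any(axis=1) | df["label"].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(f"malformed row at line {line} of {path}")
    out = []
    for b in sorted(df["batch"].unique()):
        sub = df[df["batch"] == b]
        out.append(
            LabeledDataset(
                sub[feat_cols].to_numpy(dtype=float),
                sub["label"].to_numpy(),
                params=dict(kind="gas_drift", batch=int(b), source=str(path)),
            )
        )
    return out


# ---------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------

def linear_oracle_accuracy(X: np.ndarray, y: np.ndarray, n_angles: int = 360) -> float:
    """Best training accuracy of any line, by exhaustive angle search.

    For each direction, project the data and try every midpoint between
    consecutive projected values as a threshold (both orientations).
    Used to certify that the blobs fixture is linearly separable and the
    XOR fixture is not.
    """
    X = np.atleast_2d(X)
    y = np.asarray(y)
    best = 0.0
    for ang in np.linspace(0, np.pi, n_angles, endpoint=False):
        d = np.array([np.cos(ang), np.sin(ang)])
        p = X @ d
        order = np.argsort(p)
        ps = p[order]
        thr = np.concatenate([[ps[0] - 1], (ps[1:] + ps[:-1]) / 2, [ps[-1] + 1]])
        for t in thr:
            pred = np.where(p > t, 1, -1)
            acc = max(np.mean(pred == y), np.mean(-pred == y))
            best = max(best, acc)
        if best == 1.0:
            break
    return float(best)
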