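"""Tests for the synthetic-data generators and the few-shot protocol."""

import numpy as np
import pytest

from gtnn.datasets import (
    FewShotProtocol,
    LabeledDataset,
    MinMaxScaler01,
    few_shot_split,
    gen_blobs2d,
    gen_cluster,
    gen_drift_batches,
    gen_timeseries,
    gen_xor,
    linear_oracle_accuracy,
    load_gas_drift,
    scale01,
)


class TestGenerators:
    @pytest.mark.parametrize("gen,kw", [
        (gen_blobs2d, dict(n_per_class=20)),
        (gen_xor, dict(n_per_quadrant=8)),
        (gen_cluster, dict(center=[0.5, 0.5], n=10)),
    ])
    def test_seed_determinism(self, gen, kw):
        a, b = gen(seed=5, **kw), gen(seed=5, **kw)
        assert np.array_equal(a.X, b.X)
        c = gen(seed=6, **kw)
        assert not np.array_equal(a.X, c.X)

    def test_blobs_linearly_separable(self):
        data = gen_blobs2d(n_per_class=100, separation=2.0, noise=0.3, seed=0)
        assert linear_oracle_accuracy(data.X, data.y) == 1.0

    def test_blobs_zero_noise_margin(self):
        data = gen_blobs2d(n_per_class=5, separation=2.0, noise=0.0, seed=0)
        u = np.array([1, 1]) / np.sqrt(2)
        proj = data.X @ u
        assert proj[data.y == 1].min() - proj[data.y == -1].max() >= 2.0 - 1e-9

    def test_xor_not_linearly_separable(self):
        data = gen_xor(n_per_quadrant=25, noise=0.02, seed=1)
        assert linear_oracle_accuracy(data.X, data.y) <= 0.8

    def test_xor_quadrant_labels(self):
        data = gen_xor(n_per_quadrant=50, noise=0.05, seed=0)
        q_pp = data.y[(data.X[:, 0] > 0) & (data.X[:, 1] > 0)]
        q_pm = data.y[(data.X[:, 0] > 0) & (data.X[:, 1] < 0)]
        assert np.all(q_pp == 1) and np.all(q_pm == -1)

    def test_cluster_median_near_center(self):
        data = gen_cluster([0.5, 0.7], spread=0.1, n=200, seed=2)
        med = np.median(data.X, axis=0)
        assert np.all(np.abs(med - [0.5, 0.7]) < 3 * 0.1 / np.sqrt(200) * 3)

    def test_single_point_cluster(self):
        data = gen_cluster([0.2, 0.9], n=1, seed=0)
        assert data.X.shape == (1, 2)

    def test_drift_batches(self):
        batches = gen_drift_batches(n_batches=10, D=16, C=6, n_per_class=5, seed=3)
        assert len(batches) == 10
        assert all(b.X.shape == (30, 16) for b in batches)
        frozen = gen_drift_batches(n_batches=3, D=4, C=2, n_per_class=50,
                                   drift_scale=0.0, spread=0.0,
                                   conc_range=(1.0, 1.0), seed=3)
        # zero drift, noise and concentration spread: identical batches
        assert np.allclose(frozen[0].X, frozen[2].X)

    def test_drift_batch_classes_separable(self):
        batches = gen_drift_batches(n_batches=2, D=16, C=2, n_per_class=20,
                                    spread=0.01, seed=5)
        from sklearn.linear_model import LogisticRegression

        b = batches[0]
        assert LogisticRegression(max_iter=2000).fit(b.X, b.y).score(b.X, b.y) == 1.0

    def test_timeseries_shape_and_nearest_mean(self):
        seq = gen_timeseries(classes=3, D=6, L=480, n_per_class=2, noise=0.0, seed=0)
        assert seq.X.shape == (6, 480, 6)
        means = {c: seq.X[seq.y == c].mean(axis=(0, 1)) for c in range(3)}
        for i, (x, c) in enumerate(zip(seq.X, seq.y)):
            d = {k: np.abs(x.mean(axis=0) - m).sum() for k, m in means.items()}
            assert min(d, key=d.get) == c


class TestScaling:
    def test_train_rows_in_unit_box(self):
        data = gen_blobs2d(n_per_class=20, seed=1)
        ds = LabeledDataset(data.X, data.y,
                            split=np.array(["train"] * 30 + ["test"] * 10))
        scaled = scale01(ds)
        Xtr, _ = scaled.rows("train")
        assert Xtr.min() >= 0.0 and Xtr.max() <= 1.0

    def test_same_transform_applied_to_test(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        split = np.array(["train"] * 10 + ["test"] * 10)
        scaled = scale01(LabeledDataset(X, None, split))
        manual = MinMaxScaler01.fit(X[:10]).transform(X[10:])
        assert np.allclose(scaled.X[10:], manual)

    def test_roundtrip_exact(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4)) * 10 + 3
        sc = MinMaxScaler01.fit(X)
        back = sc.inverse_transform(sc.transform(X))
        assert np.max(np.abs(back - X) / np.maximum(np.abs(X), 1e-12)) < 1e-12

    def test_constant_feature_guard(self):
        X = np.array([[1.0, 2.0], [1.0, 5.0]])
        sc = MinMaxScaler01.fit(X)
        assert np.all(np.isfinite(sc.transform(X)))


class TestFewShot:
    def test_small_class_keeps_all(self):
        X = np.zeros((27, 2))
        y = np.array([0] * 7 + [1] * 20)
        ds = few_shot_split(LabeledDataset(X, y), FewShotProtocol(shots=10, seed=0))
        tr_mask = ds.split == "train"
        assert int((y[tr_mask] == 0).sum()) == 7  # fewer than shots -> all used
        assert int((y[tr_mask] == 1).sum()) == 10

    def test_one_shot(self):
        X = np.zeros((30, 2))
        y = np.repeat([0, 1, 2], 10)
        ds = few_shot_split(LabeledDataset(X, y), FewShotProtocol(shots=1, seed=1))
        tr_mask = ds.split == "train"
        assert int(tr_mask.sum()) == 3

    def test_val_fraction(self):
        X = np.zeros((100, 2))
        y = np.repeat([0, 1], 50)
        ds = few_shot_split(LabeledDataset(X, y),
                            FewShotProtocol(shots=5, val_frac=0.1, seed=2))
        assert int((ds.split == "val").sum()) == 10

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            FewShotProtocol(shots=0)
        with pytest.raises(ValueError):
            FewShotProtocol(val_frac=1.0)


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        data = gen_blobs2d(n_per_class=10, seed=0)
        p = tmp_path / "blobs.csv"
        data.to_csv(p)
        back = LabeledDataset.from_csv(p)
        assert np.allclose(back.X, data.X)
        assert np.array_equal(back.y, data.y)
        assert back.params["kind"] == "blobs2d"  # sidecar metadata

    def test_gas_drift_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="downloaded"):
            load_gas_drift(tmp_path / "nope.csv")

    def test_gas_drift_parses_and_validates(self, tmp_path):
        import pandas as pd

        rng = np.random.default_rng(0)
        rows = []
        for b in range(2):
            for k in range(3):
                rows.append({"batch": b, "label": k % 2,
                             **{f"f{i}": rng.random() for i in range(16)}})
        p = tmp_path / "gas.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        batches = load_gas_drift(p)
        assert len(batches) == 2 and batches[0].X.shape == (3, 16)

        bad = pd.DataFrame(rows)
        bad.loc[2, "f5"] = np.nan
        bad.to_csv(p, index=False)
        with pytest.raises(ValueError, match="line 4"):
            load_gas_drift(p)

    def test_gas_drift_missing_columns(self, tmp_path):
        import pandas as pd

        p = tmp_path / "gas.csv"
        pd.DataFrame({"batch": [0], "label": [1], "f0": [0.5]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="missing"):
            load_gas_drift(p)
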