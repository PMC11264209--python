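"""Classifier training on synthetic datasets with planted structure."""

import numpy as np
import pandas as pd
import pytest

from tisdesign.classify import (LabeledDataset, TrainingError, build_dataset,
                                normalize_by_reference, reactive_fraction,
                                train_lr, train_nn)
from tisdesign.geometry import FeatureDef, FeatureSchema
from tisdesign.paths import Path, PathEnsemble, WeightedFrames


def make_synthetic_dataset(n_per_class=60, n_features=6, informative=(0,),
                           separation=2.5, seed=0, nonlinear=False,
                           weights=None):
    """Gaussian features; informative columns shift (or XOR-couple) with the
    class.  Groups mimic unique paths (one row per path)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(size=(n, n_features))
    y = np.array([1] * n_per_class + [0] * n_per_class)
    if nonlinear:
        # XOR in the two informative features: linearly inseparable
        i, j = informative[0], informative[1]
        s = rng.choice([-1.0, 1.0], size=n)
        X[:, i] = s * separation / 2 + 0.25 * rng.normal(size=n)
        X[:, j] = np.where(y == 1, s, -s) * separation / 2 \
            + 0.25 * rng.normal(size=n)
    else:
        for i in informative:
            X[:, i] += separation * y
    names = [f"f{i}" for i in range(n_features)]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    return LabeledDataset(X=pd.DataFrame(X, columns=names), y=y, weights=w,
                          groups=np.arange(n), window=(-30.0, 0.0))


class TestTrainLR:
    def test_planted_feature_survives_lasso(self):
        ds = make_synthetic_dataset(informative=(2,), separation=3.0, seed=1)
        model = train_lr(ds, n_features=3, seed=0)
        assert "f2" in model.features
        assert len(model.features) == 3

    def test_shuffled_labels_chance_auroc(self):
        rng = np.random.default_rng(5)
        aurocs = []
        for s in range(6):
            ds = make_synthetic_dataset(informative=(), seed=s)
            model = train_lr(ds, n_features="all", seed=s)
            aurocs.append(model.mean_auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.05

    def test_separable_data_high_auroc(self):
        ds = make_synthetic_dataset(informative=(0, 1), separation=6.0, seed=2)
        model = train_lr(ds, n_features="all", seed=0)
        assert model.mean_auroc >= 0.99
        assert model.mean_accuracy >= 0.95

    def test_single_class_errors(self):
        ds = make_synthetic_dataset(seed=3)
        ds.y[:] = 1
        with pytest.raises(TrainingError):
            train_lr(ds)

    def test_weighted_equals_duplicated(self):
        """Integer weights and row duplication give the same LR fit."""
        ds_w = make_synthetic_dataset(n_per_class=40, seed=4,
                                      weights=np.tile([3.0, 1.0], 40))
        rows = np.repeat(np.arange(80), np.tile([3, 1], 40))
        ds_d = LabeledDataset(X=ds_w.X.iloc[rows].reset_index(drop=True),
                              y=ds_w.y[rows],
                              weights=np.ones(len(rows)),
                              groups=ds_w.groups[rows],
                              window=ds_w.window)
        m_w = train_lr(ds_w, seed=0)
        m_d = train_lr(ds_d, seed=0)
        cw = m_w.pipeline.named_steps["clf"].coef_
        cd = m_d.pipeline.named_steps["clf"].coef_
        assert np.allclose(cw, cd, atol=1e-4)


class TestTrainNN:
    def test_deterministic_given_seed(self):
        ds = make_synthetic_dataset(seed=6)
        a = train_nn(ds, n_features="all", seed=3)
        b = train_nn(ds, n_features="all", seed=3)
        assert np.array_equal(a.cv_auroc, b.cv_auroc)
        assert np.array_equal(a.cv_accuracy, b.cv_accuracy)

    def test_nn_beats_lr_on_xor(self):
        ds = make_synthetic_dataset(n_per_class=100, informative=(0, 1),
                                    nonlinear=True, seed=7)
        lr = train_lr(ds, n_features="all", seed=0)
        nn = train_nn(ds, n_features="all", seed=0)
        assert lr.mean_auroc < 0.65          # XOR defeats the linear model
        assert nn.mean_auroc >= lr.mean_auroc - 0.02
        assert nn.mean_auroc > 0.9

    def test_greedy_selects_planted_feature(self):
        ds = make_synthetic_dataset(informative=(4,), separation=3.0, seed=8)
        model = train_nn(ds, n_features=1, seed=0)
        assert model.features == ["f4"]


def _aligned_ensemble(lam_offsets, mult, label_positions, seed=0):
    ens = PathEnsemble(condition={"kind": "pathway", "type": "R"})
    for i, (off, m) in enumerate(zip(lam_offsets, mult)):
        n = 11
        times = np.arange(-8.0, 3.0)
        positions = np.tile(label_positions, (n, 1))
        positions[:, 3] += off          # shifts the d(0,1) feature by off
        lam = np.linspace(-0.85, 0.85, n)
        ens.entries.append(Path(times=times, lambdas=lam, positions=positions,
                                velocities=None, endpoints=("A", "B"),
                                multiplicity=m, path_id=i))
    return ens


class TestBuildDataset:
    SCHEMA = FeatureSchema([FeatureDef("d01", "distance", (0, 1))])

    def _base_positions(self):
        return np.array([0.0, 0, 0, 1.5, 0, 0])

    def test_one_row_per_path(self, rng):
        r = _aligned_ensemble([0.0, 0.1], [1, 1], self._base_positions())
        nr = _aligned_ensemble([0.2, 0.3, 0.4], [1, 1, 1],
                               self._base_positions())
        ds = build_dataset([r], [nr], self.SCHEMA, (-5.0, 0.0), rng)
        assert len(ds.y) == 5
        assert ds.y.sum() == 2
        assert list(ds.X.columns) == ["d01"]

    def test_multiplicity_becomes_weight(self, rng):
        r = _aligned_ensemble([0.0], [4], self._base_positions())
        nr = _aligned_ensemble([0.1], [2], self._base_positions())
        ds = build_dataset([r], [nr], self.SCHEMA, (-5.0, 0.0), rng)
        assert sorted(ds.weights.tolist()) == [2.0, 4.0]

    def test_empty_window_errors(self, rng):
        r = _aligned_ensemble([0.0], [1], self._base_positions())
        nr = _aligned_ensemble([0.1], [1], self._base_positions())
        with pytest.raises(TrainingError):
            build_dataset([r], [nr], self.SCHEMA, (100.0, 130.0), rng)


class TestReactiveFraction:
    def test_always_reactive_model_gives_one(self):
        ds = make_synthetic_dataset(informative=(0,), separation=8.0, seed=9)
        model = train_lr(ds, seed=0)
        # frames far on the reactive side of the planted feature
        n_atoms = (ds.X.shape[1] + 2) // 3 + 1
        frames = WeightedFrames(
            positions=np.zeros((5, 6)), weights=np.ones(5),
            times=np.zeros(5), path_ids=np.arange(5))
        schema = FeatureSchema([FeatureDef(c, "distance", (0, 1))
                                for c in [ds.X.columns[0]]])
        # build frames whose single feature is extreme
        frames.positions[:, 3] = 50.0  # distance 50 >> reactive mean
        X = pd.DataFrame({c: np.zeros(5) for c in ds.X.columns})
        X[ds.X.columns[0]] = 50.0
        p = model.predict_proba(X)
        frac = float(np.mean(p >= 0.5))
        assert frac == 1.0

    def test_normalization(self):
        assert normalize_by_reference(0.3, 0.15) == pytest.approx(2.0)
        assert normalize_by_reference(0.3, 0.3) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            normalize_by_reference(0.3, 0.0)


def test_scan_window_count():
    """The default scan grid tiles (-200, 0) fs with 30 fs windows every
    5 fs: 35 placements."""
    t0, t1, width, step = -200.0, 0.0, 30.0, 5.0
    n = int(np.floor((t1 - t0 - width) / step + 1e-9)) + 1
    assert n == 35


def test_scan_windows_table_shape(rng):
    """One row per (window, kind, feature count); windows without frames for
    a class are recorded with NaN metrics instead of aborting the scan."""
    from tisdesign.classify import scan_windows

    base = np.array([0.0, 0, 0, 1.5, 0, 0])
    schema = FeatureSchema([FeatureDef("d01", "distance", (0, 1))])
    r = _aligned_ensemble(rng.normal(0.4, 0.05, 12), [1] * 12, base)
    nr = _aligned_ensemble(rng.normal(0.0, 0.05, 12), [1] * 12, base)
    # paths span t in [-8, 2]; scan over (-20, 0) includes empty windows
    table = scan_windows([r], [nr], schema, t_range=(-20.0, 0.0), width=6.0,
                         step=6.0, kinds=("LR",), feature_counts=("all",),
                         seed=0, rng=rng)
    n_windows = int(np.floor((20.0 - 6.0) / 6.0 + 1e-9)) + 1
    assert len(table) == n_windows
    assert set(table.columns) >= {"t_lo", "t_hi", "kind", "n_features",
                                  "auroc", "accuracy"}
    covered = table[table.t_lo >= -9]
    assert covered.auroc.notna().all()
    assert table.auroc.isna().any()          # the early windows are empty
    assert (covered.auroc >= 0.9).all()      # separable planted offset


def test_fold_split_keeps_paths_together():
    """All rows of a unique path land in the same CV fold."""
    from sklearn.model_selection import StratifiedGroupKFold
    rng = np.random.default_rng(0)
    groups = np.repeat(np.arange(40), 3)
    y = np.repeat(rng.integers(0, 2, 40), 3)
    X = rng.normal(size=(120, 4))
    cv = StratifiedGroupKFold(n_splits=5, shuffle=True, random_state=0)
    for tr, te in cv.split(X, y, groups):
        assert not set(groups[tr]) & set(groups[te])
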