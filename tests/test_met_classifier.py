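"""High-confidence selection, grouped folds, met scoring, sweeps, UMAP, KDE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pannetrisk import synthgen
from pannetrisk._nnet import TrainingSchedule
from pannetrisk.met_classifier import (
    MET_TRAINING_SCHEDULE,
    MetScoreMap,
    embed_umap,
    grouped_kfold,
    kde_density,
    score_tiles,
    select_high_confidence_tiles,
    threshold_sweep,
    train_met_classifier,
)
from pannetrisk.tiling import CLASS_ORDER
from pannetrisk.tissue_classifier import ClassProbabilityMap


def make_class_map(p_cancer, p_stroma=None, background=None):
    rows, cols = p_cancer.shape
    grid = np.zeros((rows, cols, 5))
    grid[..., 0] = p_cancer
    if p_stroma is not None:
        grid[..., 2] = p_stroma
    grid[..., 3] = 1.0 - grid[..., :3].sum(axis=2)  # remainder to NORMAL
    bg = background if background is not None else np.zeros((rows, cols), bool)
    grid[bg] = np.nan
    return ClassProbabilityMap(grid=grid, background_mask=bg)


class TestHighConfidenceSelection:
    def test_threshold_inclusive(self):
        p = np.array([[0.96, 0.94], [0.95, 0.10]])
        cmap = make_class_map(p)
        sel = select_high_confidence_tiles(cmap, "CANCER")
        assert sel.tolist() == [[True, False], [True, False]]

    def test_planted_subthreshold_fraction(self):
        rng = np.random.default_rng(0)
        p = np.full((10, 10), 0.97)
        low = rng.choice(100, size=30, replace=False)
        p[np.unravel_index(low, (10, 10))] = 0.5
        sel = select_high_confidence_tiles(make_class_map(p), "CANCER")
        assert sel.sum() == 70

    def test_stroma_requires_cancer_adjacency(self):
        p_stroma = np.full((30, 30), 0.97)
        p_cancer = np.zeros((30, 30))
        p_cancer[0, 0] = 0.98  # lone cancer cell in the corner
        p_stroma[0, 0] = 0.0
        cmap = make_class_map(p_cancer, p_stroma)
        sel = select_high_confidence_tiles(cmap, "STROMA", adjacency_radius=10)
        # only cells within Chebyshev distance 10 of (0, 0), minus the cancer cell
        expect = np.zeros((30, 30), bool)
        expect[:11, :11] = True
        expect[0, 0] = False
        assert np.array_equal(sel, expect)

    def test_empty_selection_warns(self):
        cmap = make_class_map(np.full((4, 4), 0.5))
        with pytest.warns(UserWarning):
            sel = select_high_confidence_tiles(cmap, "CANCER")
        assert not sel.any()


class TestGroupedKFold:
    def _cohort(self, n, slides_per=None):
        pids = [f"P{i}" for i in range(n)]
        slides = {p: [f"{p}_S0"] for p in pids}
        if slides_per:
            for p, k in slides_per.items():
                slides[p] = [f"{p}_S{j}" for j in range(k)]
        return pids, slides

    def test_balanced_fold_sizes_89_patients(self):
        pids, slides = self._cohort(89)
        fa = grouped_kfold(pids, slides, k=5, seed=0)
        sizes = pd.Series(
            {p: f for s, f in fa.fold_of_slide.items() for p in [fa.patient_of_slide[s]]}
        ).value_counts()
        assert sorted(sizes.tolist()) == [17, 18, 18, 18, 18]

    def test_patient_slides_coassigned(self):
        pids, slides = self._cohort(10, {"P3": 3})
        fa = grouped_kfold(pids, slides, k=3, seed=1)
        folds = {fa.fold_of_slide[s] for s in slides["P3"]}
        assert len(folds) == 1

    def test_leave_one_patient_out_limit(self):
        pids, slides = self._cohort(6)
        fa = grouped_kfold(pids, slides, k=6, seed=0)
        assert len({fa.fold_of_slide[s] for s in fa.fold_of_slide}) == 6

    def test_k_exceeding_patients_rejected(self):
        pids, slides = self._cohort(4)
        with pytest.raises(ValueError):
            grouped_kfold(pids, slides, k=5)

    def test_no_leakage_property(self):
        pids, slides = self._cohort(23, {"P1": 2, "P5": 4})
        fa = grouped_kfold(pids, slides, k=5, seed=9)
        for fold in range(5):
            val_patients = {fa.patient_of_slide[s] for s in fa.validation_slides(fold)}
            train_patients = {fa.patient_of_slide[s] for s in fa.training_slides(fold)}
            assert not val_patients & train_patients


@pytest.fixture(scope="module")
def met_fixture(textures):
    """Tiles from shifted (met) vs unshifted (non-met) cancer textures."""
    shifted = synthgen.shifted_textures(textures, metastatic=True)["CANCER"]
    base = textures["CANCER"]
    rng = np.random.default_rng(42)
    tiles, labels = [], []
    for _ in range(350):
        tiles.append(synthgen.make_texture_tile(base, 64, int(rng.integers(2**31 - 1))))
        labels.append(0)
        tiles.append(synthgen.make_texture_tile(shifted, 64, int(rng.integers(2**31 - 1))))
        labels.append(1)
    return tiles, labels


FAST_MET = TrainingSchedule(
    learning_rate=0.05,
    max_epochs=15,
    per_class_accuracy_stop=None,
    lr_decay_factor=0.1,
    lr_decay_after_epochs=5,
    l2_penalty=1e-4,
    seed=3,
)


class TestMetClassifier:
    def test_default_schedule_matches_training_protocol(self):
        s = MET_TRAINING_SCHEDULE
        assert s.max_epochs == 15
        assert s.learning_rate == 1e-4
        assert s.lr_decay_factor == 0.1 and s.lr_decay_after_epochs == 5
        assert s.momentum == 0.9 and s.l2_penalty == 1e-4

    def test_determinism(self, met_fixture):
        tiles, labels = met_fixture
        m1 = train_met_classifier(tiles[:100], labels[:100], FAST_MET, hidden_dims=(8,))
        m2 = train_met_classifier(tiles[:100], labels[:100], FAST_MET, hidden_dims=(8,))
        for w1, w2 in zip(m1.net.weights_, m2.net.weights_):
            assert np.array_equal(w1, w2)

    def test_holdout_auc_on_planted_shift(self, met_fixture):
        from sklearn.metrics import roc_auc_score

        tiles, labels = met_fixture
        model = train_met_classifier(tiles[:500], labels[:500], FAST_MET, hidden_dims=(8,))
        p = model.score(tiles[500:])
        assert roc_auc_score(labels[500:], p) > 0.7

    def test_mean_score_ordering(self, met_fixture):
        tiles, labels = met_fixture
        model = train_met_classifier(tiles[:500], labels[:500], FAST_MET, hidden_dims=(8,))
        p = model.score(tiles[500:])
        y = np.array(labels[500:])
        assert p[y == 1].mean() > p[y == 0].mean()

    def test_zero_epochs_rejected(self, met_fixture):
        tiles, labels = met_fixture
        with pytest.raises(ValueError):
            TrainingSchedule(max_epochs=0)

    def test_single_label_rejected(self, met_fixture):
        tiles, labels = met_fixture
        pos = [t for t, l in zip(tiles, labels) if l == 1][:20]
        with pytest.raises(ValueError):
            train_met_classifier(pos, [1] * 20, FAST_MET)

    def test_score_map_assembly(self, met_fixture):
        tiles, labels = met_fixture
        model = train_met_classifier(tiles[:100], labels[:100], FAST_MET, hidden_dims=(8,))
        placed = tiles[100:104]
        for i, t in enumerate(placed):
            t.grid_row, t.grid_col = divmod(i, 2)
        m = score_tiles(model, placed, (3, 3), "CANCER")
        assert m.valid_mask.sum() == 4
        assert not m.valid_mask[2].any()
        assert (m.scores[m.valid_mask] >= 0).all() and (m.scores[m.valid_mask] <= 1).all()
        # scoring twice gives identical values
        m2 = score_tiles(model, placed, (3, 3), "CANCER")
        assert np.array_equal(m.scores, m2.scores)


class TestThresholdSweep:
    def test_default_grid_retention_monotone(self):
        rng = np.random.default_rng(0)
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        table = threshold_sweep(scores, labels)
        assert table.threshold.tolist() == [0.5, 0.9, 0.99, 0.999, 0.9999, 0.99999]
        retained = table.retained.tolist()
        assert retained == sorted(retained, reverse=True)
        assert retained[0] == 500  # tau=0.5 keeps every scored tile

    def test_zero_retention_row_is_null(self):
        scores = np.array([0.6, 0.4, 0.55])
        labels = np.array([1, 0, 1])
        table = threshold_sweep(scores, labels, thresholds=(0.5, 0.99))
        assert table.loc[1, "retained"] == 0
        assert np.isnan(table.loc[1, "tp"])

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(5)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        table = threshold_sweep(scores, labels, thresholds=(0.5, 0.7, 0.9))
        for _, row in table.iterrows():
            keep = np.maximum(scores, 1 - scores) >= row.threshold
            pred = scores[keep] >= 0.5
            true = labels[keep] == 1
            assert row.tp == int((pred & true).sum())
            assert row.fn == int((~pred & true).sum())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_retention_weakly_decreasing_property(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        table = threshold_sweep(scores, labels, thresholds=(0.5, 0.6, 0.8, 0.95, 0.999))
        retained = table.retained.tolist()
        assert retained == sorted(retained, reverse=True)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep(np.array([0.5]), np.array([1]), thresholds=(0.4,))


class TestEmbedding:
    def test_umap_contract_1024_to_2(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 1024))
        emb = embed_umap(X, seed=1)
        assert emb.shape == (120, 2)

    def test_separated_clusters_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(100, 64))
        b = rng.normal(8, 1, size=(100, 64))
        emb = embed_umap(np.vstack([a, b]), seed=0)
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(emb)
        labels = km.labels_
        truth = np.array([0] * 100 + [1] * 100)
        acc = max((labels == truth).mean(), (labels != truth).mean())
        assert acc >= 0.9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            embed_umap(np.zeros((5, 10)))


class TestKDE:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(200, 2))
        xx, yy, dens = kde_density(pts, grid_resolution=120)
        dx = xx[0, 1] - xx[0, 0]
        dy = yy[1, 0] - yy[0, 0]
        integral = dens.sum() * dx * dy
        assert abs(integral - 1.0) < 0.02
        assert (dens >= 0).all()

    def test_mode_near_sample_mean(self):
        rng = np.random.default_rng(3)
        pts = rng.normal([3.0, -2.0], 0.2, size=(300, 2))
        xx, yy, dens = kde_density(pts)
        i = np.unravel_index(dens.argmax(), dens.shape)
        mode = np.array([xx[i], yy[i]])
        assert np.linalg.norm(mode - [3.0, -2.0]) < 0.4

    def test_degenerate_sample_falls_back(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])  # collinear
        with pytest.warns(UserWarning):
            xx, yy, dens = kde_density(pts)
        assert np.isfinite(dens).all()
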