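"""Feature extractor vs independent brute-force oracles; imputation contract."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pannetrisk.met_classifier import MetScoreMap
from pannetrisk.slide_features import (
    CLUSTER_BINS,
    CLUSTER_THRESHOLDS,
    FEATURE_NAMES,
    PROBABILITY_BANDS,
    ClusterBinSpec,
    block_cluster_histogram,
    extract_slide_features,
    feature_schema,
    impute_missing,
    neighbor_filter,
    reduced_feature_table,
)
from pannetrisk import synthgen

from conftest import random_score_map


# ---------------------------------------------------------------------------
# Brute-force oracles (straight-line reimplementations, kept independent of
# the vectorized production code)
# ---------------------------------------------------------------------------


def oracle_neighbor_filter(score_map: MetScoreMap, k: int) -> np.ndarray:
    rows, cols = score_map.valid_mask.shape
    out = np.zeros((rows, cols), bool)
    for r in range(rows):
        for c in range(cols):
            if not score_map.valid_mask[r, c]:
                continue
            n = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and score_map.valid_mask[rr, cc]:
                        n += 1
            out[r, c] = n >= k
    return out


def oracle_cluster_hist(score_map: MetScoreMap, threshold: float) -> list[int]:
    rows, cols = score_map.scores.shape
    counts = []
    for r0 in range(0, rows - 9, 10):
        for c0 in range(0, cols - 9, 10):
            n = 0
            for r in range(r0, r0 + 10):
                for c in range(c0, c0 + 10):
                    if score_map.valid_mask[r, c] and score_map.scores[r, c] >= threshold:
                        n += 1
            counts.append(n)
    hist = []
    for lo, hi in CLUSTER_BINS:
        hist.append(sum(1 for n in counts if lo <= n <= hi))
    return hist


def oracle_compartment_features(score_map: MetScoreMap) -> dict[str, float]:
    comp = score_map.compartment.lower()
    vals = sorted(score_map.scores[r, c]
                  for r in range(score_map.scores.shape[0])
                  for c in range(score_map.scores.shape[1])
                  if score_map.valid_mask[r, c])
    vals = np.array(vals)
    n = len(vals)
    f: dict[str, float] = {}

    def moments(prefix, x):
        f[f"{prefix}_mean"] = x.mean() if len(x) >= 1 else np.nan
        f[f"{prefix}_sd"] = x.std(ddof=1) if len(x) >= 2 else np.nan
        if len(x) >= 3 and x.std() > 0:
            f[f"{prefix}_skewness"] = sps.skew(x)
        else:
            f[f"{prefix}_skewness"] = np.nan
        if len(x) >= 4 and x.std() > 0:
            f[f"{prefix}_kurtosis"] = sps.kurtosis(x)
        else:
            f[f"{prefix}_kurtosis"] = np.nan

    moments(comp, vals)
    for lo, hi in PROBABILITY_BANDS:
        name = f"[{lo:g},{hi:g})" if hi < 1 else f"[{lo:g},1]"
        cnt = sum(1 for v in vals if (lo <= v < hi) or (hi == 1.0 and lo <= v <= 1.0))
        f[f"{comp}_count_{name}"] = cnt
        f[f"{comp}_prop_{name}"] = cnt / n if n else np.nan
    moments(f"{comp}_high_tail", vals[vals > 0.9])
    moments(f"{comp}_low_tail", vals[vals < 0.1])
    f[f"{comp}_n_valid"] = n
    f[f"{comp}_min"] = vals.min() if n else np.nan
    f[f"{comp}_max"] = vals.max() if n else np.nan
    f[f"{comp}_median"] = np.median(vals) if n else np.nan
    f[f"{comp}_iqr"] = (
        np.percentile(vals, 75) - np.percentile(vals, 25) if n else np.nan
    )
    rows, cols = score_map.scores.shape
    bm = []
    for r0 in range(0, rows - 9, 10):
        for c0 in range(0, cols - 9, 10):
            xs = [score_map.scores[r, c]
                  for r in range(r0, r0 + 10) for c in range(c0, c0 + 10)
                  if score_map.valid_mask[r, c]]
            if xs:
                bm.append(np.mean(xs))
    moments(f"{comp}_blockmean", np.array(bm))
    for thr in CLUSTER_THRESHOLDS:
        for (lo, hi), h in zip(CLUSTER_BINS, oracle_cluster_hist(score_map, thr)):
            f[f"{comp}_clusters_t{thr:g}_bin{lo}_{hi}"] = h
    return f


# ---------------------------------------------------------------------------


class TestNeighborFilter:
    def test_isolated_cell_removed(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        m = MetScoreMap(scores=mask * 0.5, valid_mask=mask, compartment="CANCER")
        with pytest.warns(UserWarning):
            out = neighbor_filter(m, 1)
        assert not out.valid_mask.any()

    def test_3x3_block_center_survives_at_8(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        m = MetScoreMap(scores=mask * 0.5, valid_mask=mask, compartment="CANCER")
        out = neighbor_filter(m, 8)
        assert out.valid_mask.sum() == 1
        assert out.valid_mask[2, 2]

    def test_3x3_block_all_survive_at_3(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        m = MetScoreMap(scores=mask * 0.5, valid_mask=mask, compartment="STROMA")
        out = neighbor_filter(m, 3)
        assert out.valid_mask.sum() == 9

    def test_compartment_defaults(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        cancer = MetScoreMap(scores=mask * 0.5, valid_mask=mask, compartment="CANCER")
        stroma = MetScoreMap(scores=mask * 0.5, valid_mask=mask, compartment="STROMA")
        assert neighbor_filter(cancer).valid_mask.sum() == 1  # default 8
        assert neighbor_filter(stroma).valid_mask.sum() == 9  # default 3

    def test_single_pass_not_iterated(self):
        # a 2-wide bar: under threshold 3, ends lose cells once but the
        # survivors are NOT re-filtered
        mask = np.zeros((4, 6), bool)
        mask[1:3, 1:5] = True
        m = MetScoreMap(scores=mask * 0.5, valid_mask=mask, compartment="STROMA")
        out = neighbor_filter(m, 3)
        assert np.array_equal(out.valid_mask, oracle_neighbor_filter(m, 3))

    @pytest.mark.parametrize("k", [0, 1, 3, 5, 8])
    def test_matches_oracle_on_random_masks(self, k):
        rng = np.random.default_rng(k)
        for _ in range(20):
            m = random_score_map(rng, rows=12, cols=14)
            out = neighbor_filter(m, k)
            assert np.array_equal(out.valid_mask, oracle_neighbor_filter(m, k))
            # anti-extensive
            assert not (out.valid_mask & ~m.valid_mask).any()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(77)
        m = random_score_map(rng, rows=15, cols=15)
        prev = neighbor_filter(m, 0).valid_mask
        for k in range(1, 9):
            cur = neighbor_filter(m, k).valid_mask
            assert not (cur & ~prev).any()
            prev = cur


class TestClusterHistogram:
    def test_all_zero_scores(self):
        m = MetScoreMap(
            scores=np.zeros((20, 20)), valid_mask=np.ones((20, 20), bool), compartment="CANCER"
        )
        hist = block_cluster_histogram(m, ClusterBinSpec(0.5))
        assert hist[0] == 4 and hist[1:].sum() == 0

    def test_planted_nine_positives_in_bin_8_9(self):
        m = synthgen.make_score_map(20, 20, [((0, 0), 9, 0.6)], 0.1, seed=3)
        hist = block_cluster_histogram(m, ClusterBinSpec(0.5))
        assert hist[4] == 1  # bin 8-9
        assert hist.sum() == 4  # conservation over the 4 complete blocks

    def test_high_threshold_moves_block_to_zero_bin(self):
        m = synthgen.make_score_map(20, 20, [((0, 0), 9, 0.6)], 0.1, seed=3)
        hist = block_cluster_histogram(m, ClusterBinSpec(0.99))
        assert hist[0] == 4

    def test_grid_smaller_than_block_warns(self):
        m = MetScoreMap(
            scores=np.zeros((5, 5)), valid_mask=np.ones((5, 5), bool), compartment="CANCER"
        )
        with pytest.warns(UserWarning):
            hist = block_cluster_histogram(m, ClusterBinSpec(0.5))
        assert hist.sum() == 0

    def test_matches_oracle_on_random_maps(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            m = random_score_map(rng, rows=23, cols=31)
            for thr in (0.3, 0.5, 0.9):
                hist = block_cluster_histogram(m, ClusterBinSpec(thr))
                assert hist.tolist() == oracle_cluster_hist(m, thr)

    def test_bins_must_partition(self):
        with pytest.raises(ValueError):
            ClusterBinSpec(0.5, bins=((0, 1), (2, 3)))


class TestFeatureExtraction:
    def test_schema_is_150_with_75_per_compartment(self):
        schema = feature_schema()
        assert len(schema) == 150
        assert sum(1 for s in schema if s["compartment"] == "cancer") == 75
        assert sum(1 for s in schema if s["compartment"] == "stroma") == 75
        assert [s["name"] for s in schema][:4] == [
            "cancer_mean", "cancer_sd", "cancer_skewness", "cancer_kurtosis",
        ]

    def test_constant_map_forced_statistics(self):
        scores = np.full((10, 10), 0.3)
        mask = np.zeros((10, 10), bool)
        mask[:5, :10] = True  # 50 tiles at 0.3
        cmap = MetScoreMap(scores=np.where(mask, scores, 0), valid_mask=mask, compartment="CANCER")
        smap = MetScoreMap(
            scores=np.zeros((10, 10)), valid_mask=np.zeros((10, 10), bool), compartment="STROMA"
        )
        vec = extract_slide_features(cmap, smap)
        assert vec["cancer_mean"] == pytest.approx(0.3)
        assert vec["cancer_sd"] == pytest.approx(0.0)
        assert vec["cancer_prop_[0.5,0.9)"] == 0.0
        assert np.isnan(vec["cancer_high_tail_mean"])  # empty tail
        assert np.isnan(vec["cancer_skewness"])  # zero variance
        assert vec["cancer_n_valid"] == 50

    def test_oracle_equivalence_on_random_maps(self):
        """100 random maps: exact counts, 1e-9 relative moments."""
        rng = np.random.default_rng(2024)
        for i in range(100):
            cmap = random_score_map(rng, rows=30, cols=30, compartment="CANCER")
            smap = random_score_map(rng, rows=30, cols=30, compartment="STROMA")
            vec = extract_slide_features(cmap, smap)
            oracle = {**oracle_compartment_features(cmap), **oracle_compartment_features(smap)}
            assert set(vec.index) == set(oracle)
            for name in vec.index:
                a, b = vec[name], oracle[name]
                if np.isnan(b):
                    assert np.isnan(a), name
                elif "count" in name or "clusters" in name or name.endswith("n_valid"):
                    assert a == b, name
                else:
                    assert a == pytest.approx(b, rel=1e-9, abs=1e-12), name

    def test_band_counts_sum_to_valid_count(self):
        rng = np.random.default_rng(9)
        cmap = random_score_map(rng, compartment="CANCER")
        smap = random_score_map(rng, compartment="STROMA")
        vec = extract_slide_features(cmap, smap)
        for comp in ("cancer", "stroma"):
            count_cols = [n for n in FEATURE_NAMES if n.startswith(f"{comp}_count_[")]
            assert vec[count_cols].sum() == vec[f"{comp}_n_valid"]

    def test_reduced_table_aggregates_bands(self):
        rng = np.random.default_rng(10)
        cmap = random_score_map(rng, compartment="CANCER")
        smap = random_score_map(rng, compartment="STROMA")
        vec = extract_slide_features(cmap, smap)
        red = reduced_feature_table(pd.DataFrame([vec]))
        v = cmap.valid_scores
        assert red.loc[0, "cancer_count_ge_0.5"] == (v >= 0.5).sum()
        assert red.loc[0, "cancer_count_gt_0.9"] == (v >= 0.9).sum()
        assert red.loc[0, "cancer_count_lt_0.1"] == (v < 0.1).sum()


class TestImputation:
    def test_complete_table_unchanged(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        out = impute_missing(df)
        pd.testing.assert_frame_equal(out, df)

    def test_collinear_imputation_accuracy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        df = pd.DataFrame({"a": x, "b": 2.0 * x + 1.0, "c": rng.normal(size=40)})
        truth = df.loc[5, "b"]
        df.loc[5, "b"] = np.nan
        out = impute_missing(df, seed=0)
        assert out.loc[5, "b"] == pytest.approx(truth, rel=0.01)

    def test_observed_entries_unchanged_and_deterministic(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        df.iloc[3, 1] = np.nan
        df.iloc[7, 4] = np.nan
        out1 = impute_missing(df, seed=5)
        out2 = impute_missing(df, seed=5)
        pd.testing.assert_frame_equal(out1, out2)
        obs = ~df.isna()
        assert np.array_equal(out1.values[obs.values], df.values[obs.values])
        assert not out1.isna().any().any()

    def test_fully_missing_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="b"):
            impute_missing(df)

    def test_default_iterations_is_ten(self):
        import inspect

        sig = inspect.signature(impute_missing)
        assert sig.parameters["iterations"].default == 10
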