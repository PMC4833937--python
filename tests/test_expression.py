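import itertools

import numpy as np
import pandas as pd
import pytest

from glyfam.expression import (
    ExpressionMatrix,
    fold_change,
    hierarchical_cluster,
    log_transform,
    pearson_distance_matrix,
    regulation_call,
    specificity_class,
)
from glyfam.synthetic_data import TISSUES, SimConfig, generate_expression


class TestTransforms:
    def test_log2_values(self):
        df = pd.DataFrame({"c": [0.0, 3.0]})
        out = log_transform(df, pseudocount=1.0)
        assert out["c"].tolist() == [0.0, 2.0]

    def test_monotone(self):
        df = pd.DataFrame({"c": [0.5, 1.5, 7.0]})
        out = log_transform(df)["c"].tolist()
        assert out == sorted(out)

    def test_negative_input_errors(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame({"c": [-1.0]}))

    @pytest.mark.parametrize(
        "stress,mock,expected",
        [(4, 2, 2.0), (1, 1, 1.0), (0, 2, 0.05)],
    )
    def test_fold_change(self, stress, mock, expected):
        assert fold_change(stress, mock, floor=0.1) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "fc,expected", [(2.5, "up"), (0.4, "down"), (1.3, "unchanged")]
    )
    def test_regulation_call(self, fc, expected):
        assert regulation_call(fc) == expected

    def test_reciprocal_consistency(self):
        """up on (a,b) mirrors down on (b,a)."""
        for a, b in [(5.0, 1.0), (1.0, 5.0), (2.0, 2.0)]:
            fwd = regulation_call(fold_change(a, b))
            rev = regulation_call(1.0 / fold_change(b, a))
            assert fwd == rev


def brute_force_average_linkage(d: np.ndarray):
    """Exhaustive average-linkage agglomeration; returns merge sequence
    as (frozenset_a, frozenset_b, height) triples."""
    clusters = {i: frozenset([i]) for i in range(len(d))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ca, cb = clusters[a], clusters[b]
            h = np.mean([d[i, j] for i in ca for j in cb])
            if best is None or h < best[0] - 1e-12:
                best = (h, a, b)
        h, a, b = best
        merges.append((clusters[a], clusters[b], h))
        clusters[min(a, b)] = clusters[a] | clusters[b]
        del clusters[max(a, b)]
    return merges


class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]],
                          dtype=float)
        # rows 0 and 1 perfectly correlated -> distance 0
        link, _ = hierarchical_cluster(df)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        df = pd.DataFrame([[1, 2, 3], [3, 2, 1]], dtype=float)
        d = pearson_distance_matrix(df)
        assert d[0, 1] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.uniform(0.1, 10, size=(6, 8)))
        d = pearson_distance_matrix(df)
        oracle = brute_force_average_linkage(d)
        link, _ = hierarchical_cluster(df)
        # same merge heights in the same order
        assert np.allclose(
            [h for _, _, h in oracle], link[:, 2], atol=1e-10
        )
        # same composition of merged clusters at every step
        n = len(df)
        scipy_clusters = {i: frozenset([i]) for i in range(n)}
        for step, row in enumerate(link):
            a, b = int(row[0]), int(row[1])
            merged = scipy_clusters[a] | scipy_clusters[b]
            oa, ob, _ = oracle[step]
            assert merged == oa | ob
            scipy_clusters[n + step] = merged

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(0.1, 10, size=(5, 6)),
                          index=list("abcde"))
        perm = df.iloc[[3, 1, 4, 0, 2]]
        _, ordered1 = hierarchical_cluster(df)
        _, ordered2 = hierarchical_cluster(perm)
        h1 = sorted(hierarchical_cluster(df)[0][:, 2])
        h2 = sorted(hierarchical_cluster(perm)[0][:, 2])
        assert np.allclose(h1, h2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(0.1, 10, size=(4, 6)))
        l1, _ = hierarchical_cluster(df)
        l2, _ = hierarchical_cluster(df * 37.5)
        assert np.allclose(l1[:, 2], l2[:, 2])

    def test_zero_variance_row_flagged(self):
        df = pd.DataFrame([[1, 1, 1], [1, 2, 3], [3, 2, 1]], dtype=float)
        with pytest.warns(UserWarning, match="zero-variance"):
            d = pearson_distance_matrix(df)
        assert d[0, 1] == 1.0 and d[0, 2] == 1.0

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(pd.DataFrame([[1.0, 2.0]]))


SEED_COLS = [c for c, k in TISSUES.items() if k == "seed"]
OTHER_COLS = [c for c in TISSUES if c not in SEED_COLS]


def _row(values: dict) -> pd.Series:
    return pd.Series({c: values.get(c, 0.0) for c in TISSUES})


class TestSpecificity:
    def test_constitutive(self):
        row = _row({c: 5.0 for c in TISSUES})
        assert specificity_class(row, TISSUES) == "constitutive"

    def test_seed_specific(self):
        row = _row({c: 3.0 for c in SEED_COLS})
        assert specificity_class(row, TISSUES) == "seed_specific"

    def test_non_seed(self):
        row = _row({c: 3.0 for c in OTHER_COLS})
        assert specificity_class(row, TISSUES) == "non_seed"

    def test_silent(self):
        assert specificity_class(_row({}), TISSUES) == "silent"

    def test_restricted(self):
        row = _row({SEED_COLS[0]: 3.0, OTHER_COLS[0]: 3.0})
        assert specificity_class(row, TISSUES) == "restricted"


class TestPlantedRecovery:
    def test_noise_free_exact(self):
        cfg = SimConfig(seed=1, expression_sigma=0.0)
        tissue, classes, stress, truth = generate_expression(cfg)
        for gid, planted in truth.expression_classes.items():
            assert specificity_class(tissue.loc[gid], classes) == planted
        for gid, fc in truth.expression_fc.items():
            measured = fold_change(
                stress.loc[gid, "stress"], stress.loc[gid, "mock"]
            )
            expected = (
                "up" if fc >= 2 else "down" if fc <= 0.5 else "unchanged"
            )
            assert regulation_call(measured) == expected

    def test_moderate_noise_recovery(self):
        """>= 95% of planted specificity labels and regulation calls
        recovered at the generator's default noise level."""
        hits = trials = 0
        for seed in range(5):
            cfg = SimConfig(seed=seed, expression_sigma=0.1)
            tissue, classes, stress, truth = generate_expression(cfg)
            for gid, planted in truth.expression_classes.items():
                trials += 1
                got = specificity_class(tissue.loc[gid], classes)
                hits += got == planted
            for gid, fc in truth.expression_fc.items():
                trials += 1
                measured = fold_change(
                    stress.loc[gid, "stress"], stress.loc[gid, "mock"]
                )
                expected = (
                    "up" if fc >= 2 else "down" if fc <= 0.5 else "unchanged"
                )
                hits += regulation_call(measured) == expected
        assert hits / trials >= 0.95


class TestMatrixValidation:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(
                pd.DataFrame({"c": [-1.0]}), {"c": "seed"}
            )

    def test_missing_condition_class_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(pd.DataFrame({"c": [1.0]}), {})


class TestHeatmap:
    def test_writes_png_and_svg(self, tmp_path):
        from glyfam.expression import plot_heatmap

        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            rng.uniform(0.1, 10, size=(4, 5)),
            index=list("abcd"),
            columns=[f"t{i}" for i in range(5)],
        )
        for suffix in ("png", "svg"):
            out = tmp_path / f"heat.{suffix}"
            plot_heatmap(df, out)
            assert out.exists() and out.stat().st_size > 0
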