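import itertools

import numpy as np
import pandas as pd
import pytest

from biocrustdiv.envmodels import (
    PLSPathModel,
    all_subset_regression,
    block_distances,
    default_path_matrix,
    filter_multicollinearity,
    prune_paths,
    residual_normality_check,
)
from biocrustdiv.io import ParameterError


class TestMulticollinearity:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["b"] = X["a"]
        X["c"] = rng.normal(size=30)
        kept = filter_multicollinearity(X)
        assert "c" in kept
        assert len([k for k in kept if k in ("a", "b")]) == 1

    def test_orthogonal_predictors_untouched(self):
        X = pd.DataFrame(np.eye(4), columns=list("wxyz"))
        assert filter_multicollinearity(X) == list("wxyz")

    def test_constructed_collinearity(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=50)
        x2 = rng.normal(size=50)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 + rng.normal(0, 1e-3, 50)})
        kept = filter_multicollinearity(X)
        assert "x2" in kept
        assert len({"x1", "x3"} & set(kept)) == 1


def oracle_best_subset(y, X, max_size):
    """Independent exhaustive search via numpy lstsq on raw data."""
    cols = list(X.columns)
    n = len(y)
    best = None
    tss = ((y - y.mean()) ** 2).sum()
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(cols, size):
            design = np.column_stack([np.ones(n), X[list(combo)].to_numpy()])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            rss = ((y - design @ beta) ** 2).sum()
            r2 = 1 - rss / tss
            sigma2 = rss / n
            llf = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1)
            aic = 2 * (size + 2) - 2 * llf
            cand = (combo, r2, aic)
            if best is None or r2 > best[1] + 1e-9 or (
                abs(r2 - best[1]) <= 1e-9 and aic < best[2]
            ):
                best = cand
    return best


class TestAllSubsetRegression:
    def test_planted_truth_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("wxyz"))
        y = 3.0 * X["x"] - 2.0 * X["z"]
        model = all_subset_regression(y, X)
        assert set(model.predictors) == {"x", "z"}
        assert model.gof == pytest.approx(1.0, abs=1e-12)

    def test_gof_tie_broken_by_aic(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        X = pd.DataFrame({"x": x, "x_copy": x})
        y = 2 * x + rng.normal(0, 1, 50)
        model = all_subset_regression(y, X)
        assert len(model.predictors) == 1  # smaller subset wins the tie

    def test_agrees_with_independent_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            p = rng.integers(2, 7)
            n = 30
            X = pd.DataFrame(rng.normal(size=(n, p)),
                             columns=[f"v{i}" for i in range(p)])
            beta = rng.normal(size=p) * (rng.random(p) < 0.5)
            y = X.to_numpy() @ beta + rng.normal(0, 1, n)
            model = all_subset_regression(pd.Series(y), X)
            combo, r2, aic = oracle_best_subset(y, X, p)
            assert set(model.predictors) == set(combo)
            assert model.gof == pytest.approx(r2, abs=1e-9)
            assert model.aic == pytest.approx(aic, abs=1e-6)

    def test_gof_monotone_in_max_size(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(40, 5)))
        X.columns = [f"v{i}" for i in range(5)]
        y = X.to_numpy() @ rng.normal(size=5) + rng.normal(0, 1, 40)
        gofs = [all_subset_regression(y, X, max_size=k).gof for k in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(gofs, gofs[1:]))

    def test_too_few_observations(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)),
                         columns=list("abc"))
        with pytest.raises(ParameterError):
            all_subset_regression([1.0, 2.0, 3.0, 4.0], X)


def test_residual_normality_check_flags():
    rng = np.random.default_rng(0)
    ok = residual_normality_check(rng.normal(size=500))
    skewed = residual_normality_check(rng.exponential(size=500))
    assert ok["acceptable"]
    assert not skewed["acceptable"]


class TestBlockDistances:
    def _alpha(self, n, rng):
        return pd.DataFrame(
            {"faith_pd": rng.normal(10, 2, n), "richness": rng.integers(5, 50, n),
             "pielou": rng.uniform(0.5, 1, n)},
            index=[f"s{i}" for i in range(n)])

    def test_vector_lengths(self):
        rng = np.random.default_rng(0)
        blocks = block_distances(alpha=self._alpha(7, rng))
        assert len(blocks["alpha"]) == 7 * 6 // 2

    def test_identical_samples_zero(self):
        alpha = pd.DataFrame({"faith_pd": [3.0, 3.0], "richness": [4, 4],
                              "pielou": [0.8, 0.8], "extra": [1.0, 2.0]},
                             index=["a", "b"])
        with pytest.warns(UserWarning):  # constant columns drop
            blocks = block_distances(alpha=alpha[["faith_pd", "richness", "pielou"]]
                                     .assign(pielou=[0.8, 0.9]))
        # only pielou varies; identical in the other two
        assert blocks["alpha"].iloc[0, 0] > 0

    def test_affine_invariance_of_env_block(self, tiny_meta):
        b1 = block_distances(frame=tiny_meta)
        scaled = tiny_meta
        scaled.data["temp"] = 2.0 * scaled.data["temp"] + 5.0
        b2 = block_distances(frame=scaled)
        assert np.allclose(b1["climatic"].to_numpy(), b2["climatic"].to_numpy())


class TestPLSPathModel:
    def _chain_data(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        m = 0.7 * x + rng.normal(0, 0.7, n)
        y = 0.6 * m + rng.normal(0, 0.8, n)
        blocks = {"X": pd.DataFrame({"x1": x}), "M": pd.DataFrame({"m1": m}),
                  "Y": pd.DataFrame({"y1": y})}
        pm = pd.DataFrame([[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                          index=["X", "M", "Y"], columns=["X", "M", "Y"])
        return blocks, pm, x, m, y

    def test_single_indicator_chain_equals_sequential_ols(self):
        blocks, pm, x, m, y = self._chain_data()
        res = PLSPathModel(blocks, pm).fit()
        # single-indicator latents degenerate to standardized variables,
        # so paths equal the standardized OLS coefficients
        assert res.path_coefficients.loc["M", "X"] == pytest.approx(
            np.corrcoef(x, m)[0, 1], abs=1e-6)
        assert res.path_coefficients.loc["Y", "M"] == pytest.approx(
            np.corrcoef(m, y)[0, 1], abs=1e-6)

    def test_planted_path_recovered(self):
        rng = np.random.default_rng(5)
        n = 500
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(0, 0.6, n)
        blocks = {"X": pd.DataFrame({"x": x}), "Y": pd.DataFrame({"y": y})}
        pm = pd.DataFrame([[0, 0], [1, 0]], index=["X", "Y"], columns=["X", "Y"])
        res = PLSPathModel(blocks, pm).fit()
        assert res.path_coefficients.loc["Y", "X"] == pytest.approx(0.8, abs=0.05)

    def test_indicator_order_invariance(self):
        rng = np.random.default_rng(6)
        n = 200
        latent = rng.normal(size=n)
        Xb = pd.DataFrame({f"i{j}": latent + rng.normal(0, 0.4, n) for j in range(3)})
        yv = 0.5 * latent + rng.normal(0, 0.5, n)
        pm = pd.DataFrame([[0, 0], [1, 0]], index=["L", "Y"], columns=["L", "Y"])
        r1 = PLSPathModel({"L": Xb, "Y": pd.DataFrame({"y": yv})}, pm).fit()
        r2 = PLSPathModel({"L": Xb[["i2", "i0", "i1"]], "Y": pd.DataFrame({"y": yv})},
                          pm).fit()
        assert np.allclose(np.abs(r1.scores["L"]), np.abs(r2.scores["L"]), atol=1e-4)
        assert abs(r1.path_coefficients.loc["Y", "L"]) == pytest.approx(
            abs(r2.path_coefficients.loc["Y", "L"]), abs=1e-4)

    def test_cyclic_path_matrix_rejected(self):
        pm = pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ParameterError):
            PLSPathModel({"A": pd.DataFrame({"a": [1.0, 2.0]}),
                          "B": pd.DataFrame({"b": [2.0, 1.0]})}, pm)

    def test_summary_mentions_gof_and_paths(self):
        blocks, pm, *_ = self._chain_data(n=100, seed=2)
        res = PLSPathModel(blocks, pm).fit()
        text = res.summary()
        assert "GoF index" in text
        assert "X" in text and "->" in text


class TestPrunePaths:
    def _model_with_junk(self, seed):
        rng = np.random.default_rng(seed)
        n = 250
        latent = rng.normal(size=n)
        Xb = pd.DataFrame({
            "good1": latent + rng.normal(0, 0.3, n),
            "good2": latent + rng.normal(0, 0.3, n),
            "junk": rng.normal(size=n),
        })
        yv = 0.7 * latent + rng.normal(0, 0.5, n)
        pm = pd.DataFrame([[0, 0], [1, 0]], index=["L", "Y"], columns=["L", "Y"])
        return PLSPathModel({"L": Xb, "Y": pd.DataFrame({"y": yv})}, pm).fit()

    def test_planted_junk_indicator_removed(self):
        for seed in range(10):
            pruned = prune_paths(self._model_with_junk(seed))
            assert [b for b, i in pruned.pruning_log] == ["L"]
            assert [i for b, i in pruned.pruning_log] == ["junk"]
            assert list(pruned.outer_loadings["L"].index) == ["good1", "good2"]

    def test_all_strong_loadings_fixpoint(self):
        pruned = prune_paths(self._model_with_junk(0), loading_threshold=0.0)
        assert pruned.pruning_log == []

    def test_threshold_zero_noop(self):
        res = self._model_with_junk(1)
        assert prune_paths(res, loading_threshold=0.0).pruning_log == []


def test_default_path_matrix_lower_triangular():
    pm = default_path_matrix(("a", "b", "c"))
    assert np.all(np.triu(pm.to_numpy()) == 0)
    assert pm.loc["c", "a"] == 1


def test_vif_filter_drops_constructed_collinearity():
    rng = np.random.default_rng(7)
    x1 = rng.normal(size=80)
    x2 = rng.normal(size=80)
    X = pd.DataFrame({"a": x1, "b": x2, "c": x1 + rng.normal(0, 1e-2, 80)})
    kept = filter_multicollinearity(X, method="vif")
    assert "b" in kept
    assert len({"a", "c"} & set(kept)) == 1
    # orthogonal predictors survive
    assert filter_multicollinearity(X[["a", "b"]], method="vif") == ["a", "b"]
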