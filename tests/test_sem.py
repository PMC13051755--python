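import itertools

import numpy as np
import pandas as pd
import pytest

from phyllokbs.sem import (
    PathModel,
    build_study_model,
    fit_sem,
    saturated_model,
    soil_pc1,
    total_effects,
)
from .conftest import make_metadata


def brute_force_total_effect(edges, coeffs, src, dst, variables):
    """Sum of path-coefficient products over every directed path (oracle)."""
    out = {v: [] for v in variables}
    for (a, b), c in zip(edges, coeffs):
        out[a].append((b, c))
    total = 0.0
    stack = [(src, 1.0)]
    while stack:
        node, prod = stack.pop()
        for nxt, c in out[node]:
            if nxt == dst:
                total += prod * c
            stack.append((nxt, prod * c))
    return total


@pytest.fixture
def chain_data():
    rng = np.random.default_rng(0)
    n = 500
    a = rng.standard_normal(n)
    b = 0.6 * a + np.sqrt(1 - 0.36) * rng.standard_normal(n)
    c = 0.5 * b + np.sqrt(1 - 0.25) * rng.standard_normal(n)
    d = 0.4 * c + np.sqrt(1 - 0.16) * rng.standard_normal(n)
    return pd.DataFrame({"a": a, "b": b, "c": c, "d": d})


class TestFitSEM:
    def test_saturated_model_has_zero_discrepancy(self, chain_data):
        fit = fit_sem(chain_data, saturated_model(list("abcd")), n_restarts=2)
        assert fit.chi_square == pytest.approx(0.0, abs=1e-8)
        assert fit.gfi == pytest.approx(1.0, abs=1e-8)
        assert fit.df == 0 and fit.rmsea == 0.0

    def test_single_regression_standardized_path_equals_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        y = 0.7 * x + rng.standard_normal(300)
        data = pd.DataFrame({"x": x, "y": 3 + 10 * y})  # affine shift on y
        fit = fit_sem(data, PathModel(["x", "y"], [("x", "y")]), n_restarts=2)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.estimates["std_estimate"].iloc[0] == pytest.approx(r, abs=1e-8)

    def test_chain_recovery_within_tolerance(self, chain_data):
        model = PathModel(list("abcd"), [("a", "b"), ("b", "c"), ("c", "d")])
        fit = fit_sem(chain_data, model)
        truth = {"b": 0.6, "c": 0.5, "d": 0.4}
        for _, row in fit.estimates.iterrows():
            assert row["std_estimate"] == pytest.approx(truth[row["effect"]], abs=0.1)
            assert row["p"] < 1e-4
        assert fit.chi_square >= 0 and fit.df == 3

    def test_fit_invariant_to_affine_rescaling(self, chain_data):
        model = PathModel(list("abcd"), [("a", "b"), ("b", "c"), ("c", "d")])
        fit1 = fit_sem(chain_data, model)
        rescaled = chain_data * [10.0, 0.1, 1000.0, 2.0] + [5.0, -2.0, 0.0, 1.0]
        fit2 = fit_sem(rescaled, model)
        np.testing.assert_allclose(
            fit1.estimates["std_estimate"], fit2.estimates["std_estimate"], atol=1e-6
        )
        assert fit1.chi_square == pytest.approx(fit2.chi_square, abs=1e-6)

    def test_fit_invariant_to_variable_ordering(self, chain_data):
        m1 = PathModel(list("abcd"), [("a", "b"), ("b", "c"), ("c", "d")])
        m2 = PathModel(list("dcba"), [("a", "b"), ("b", "c"), ("c", "d")])
        f1 = fit_sem(chain_data, m1)
        f2 = fit_sem(chain_data[list("dcba")], m2)
        e1 = f1.estimates.set_index(["cause", "effect"])["std_estimate"]
        e2 = f2.estimates.set_index(["cause", "effect"])["std_estimate"]
        np.testing.assert_allclose(e1.sort_index(), e2.sort_index(), atol=1e-8)

    def test_cyclic_model_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            PathModel(["x", "y"], [("x", "y"), ("y", "x")])

    def test_underidentified_model_rejected(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.standard_normal((10, 2)), columns=["x", "y"])
        with pytest.raises(ValueError, match="n > p"):
            fit_sem(data.iloc[:2], PathModel(["x", "y"], [("x", "y")]))


class TestTotalEffects:
    def test_chain_total_is_product_of_paths(self, chain_data):
        model = PathModel(list("abcd"), [("a", "b"), ("b", "c"), ("c", "d")])
        fit = fit_sem(chain_data, model)
        te = total_effects(fit)
        prod = fit.estimates["std_estimate"].prod()
        assert te.at["d", "a"] == pytest.approx(prod, abs=1e-10)
        assert te.at["a", "d"] == 0.0

    def test_matches_path_enumeration_oracle_on_random_dags(self):
        rng = np.random.default_rng(3)
        variables = list("abcdef")
        for trial in range(4):
            edges = [
                (variables[i], variables[j])
                for i, j in itertools.combinations(range(6), 2)
                if rng.random() < 0.5
            ]
            if not edges:
                continue
            n = 400
            data = np.zeros((n, 6))
            coeffs = {}
            for j, v in enumerate(variables):
                data[:, j] = rng.standard_normal(n)
                for (a, b) in edges:
                    if b == v:
                        c = rng.uniform(-0.5, 0.5)
                        coeffs[(a, b)] = c
                        data[:, j] += c * data[:, variables.index(a)]
            df = pd.DataFrame(data, columns=variables)
            fit = fit_sem(df, PathModel(variables, edges), n_restarts=1)
            te = total_effects(fit)
            est = fit.estimates.set_index(["cause", "effect"])["std_estimate"]
            oracle = brute_force_total_effect(
                edges, [est[e] for e in edges], "a", "f", variables
            )
            assert te.at["f", "a"] == pytest.approx(oracle, abs=1e-8)


class TestStudyModel:
    def test_assembles_five_variables(self):
        ids = [f"s{i}" for i in range(12)]
        meta = make_metadata(ids, ["resistant"] * 6 + ["susceptible"] * 6)
        rng = np.random.default_rng(4)
        data, model = build_study_model(
            pd.Series(rng.standard_normal(12), index=ids),
            pd.Series(rng.uniform(0, 0.2, 12), index=ids),
            pd.Series(rng.uniform(0, 0.05, 12), index=ids),
            meta,
        )
        assert data.shape == (12, 5)
        assert model.df >= 0
        assert set(model.variables) == set(data.columns)

    def test_soil_pc1_matches_pcoa_of_euclidean_distances(self):
        from phyllokbs.diversity import DistanceMatrix, pcoa

        rng = np.random.default_rng(5)
        soil = rng.normal([6.5, 15, 20, 200, 10, 20], [0.3, 5, 5, 50, 3, 6], (20, 6))
        pc1 = soil_pc1(soil)
        z = (soil - soil.mean(0)) / soil.std(0, ddof=1)
        d = np.sqrt(((z[:, None] - z[None, :]) ** 2).sum(-1))
        axis1 = pcoa(DistanceMatrix([f"s{i}" for i in range(20)], d)).pcoa1
        agree = min(np.abs(axis1 - pc1).max(), np.abs(axis1 + pc1).max())
        assert agree < 1e-8

    def test_per_class_row_counts(self):
        ids = [f"s{i}" for i in range(10)]
        meta = make_metadata(ids, ["resistant"] * 4 + ["susceptible"] * 6)
        rng = np.random.default_rng(6)
        res_ids = meta.samples_in_class("resistant")
        data, _ = build_study_model(
            pd.Series(rng.standard_normal(4), index=res_ids),
            pd.Series(rng.uniform(0, 1, 4), index=res_ids),
            pd.Series(rng.uniform(0, 1, 4), index=res_ids),
            meta,
            sample_ids=res_ids,
        )
        assert len(data) == 4
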