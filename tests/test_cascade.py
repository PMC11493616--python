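import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aphidcascade.cascade import (
    CascadeError,
    Claim,
    Composite,
    PathSpec,
    default_path_spec,
    dsep_basis_set,
    fishers_c,
    fit_composite,
    fit_paths,
    prune_paths,
    standardize,
)
from aphidcascade.simulate import CascadeCoefficients, gen_cascade_dataset, gen_linear_dag


# ---------------------------------------------------------------------------
# standardize


def test_standardize_examples():
    z = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
    assert z["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])


def test_standardize_idempotent_and_invertible():
    rng = np.random.default_rng(0)
    x = rng.normal(3.0, 2.5, 50)
    df = pd.DataFrame({"x": x})
    z = standardize(df)
    z2 = standardize(z)
    assert np.allclose(z["x"], z2["x"], atol=1e-12)
    back = z["x"].to_numpy() * x.std(ddof=1) + x.mean()
    assert np.allclose(back, x, atol=1e-12)


def test_standardize_zero_variance_names_column():
    df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
    with pytest.raises(CascadeError, match="flat"):
        standardize(df)


# ---------------------------------------------------------------------------
# composites


def test_composite_duplicated_indicator_is_identity():
    rng = np.random.default_rng(1)
    x = rng.normal(size=100)
    other = rng.normal(size=100)
    cf = fit_composite(pd.DataFrame({"x": x, "o": other}), pd.Series(x))
    assert cf.loadings["x"] == pytest.approx(1.0, abs=1e-10)
    assert cf.loadings["o"] == pytest.approx(0.0, abs=1e-10)
    zx = (x - x.mean()) / x.std(ddof=1)
    assert np.allclose(cf.scores, zx, atol=1e-8)


def test_composite_exact_least_squares_weights():
    rng = np.random.default_rng(2)
    a = rng.normal(size=200)
    b = rng.normal(size=200)
    b -= a * (a @ b) / (a @ a)  # orthogonalize
    y = 2.0 * a - 1.0 * b
    cf = fit_composite(pd.DataFrame({"a": a, "b": b}), pd.Series(y))
    ratio = cf.loadings["a"] / cf.loadings["b"]
    truth = (2.0 * a.std(ddof=1)) / (-1.0 * b.std(ddof=1))
    assert ratio == pytest.approx(truth, rel=1e-8)


def test_composite_rejects_collinear_indicators():
    x = np.arange(20.0)
    with pytest.raises(CascadeError):
        fit_composite(pd.DataFrame({"a": x, "b": 2 * x}), pd.Series(x))


def test_composite_recovers_reported_growth_path():
    """Composite plant-growth -> r_m recovers the reported 0.820 at n = 1000."""
    df = gen_cascade_dataset(n=1000, seed=77).drop(columns=["plant_growth", "physiochemistry"])
    fit = fit_paths(default_path_spec(), df)
    beta = fit.edges[("plant_growth", "r_m")].beta
    assert beta == pytest.approx(0.820, abs=0.1)


# ---------------------------------------------------------------------------
# path spec and basis set


def test_cyclic_spec_rejected():
    with pytest.raises(CascadeError):
        PathSpec(nodes=("a", "b"), edges=(("a", "b"), ("b", "a")))


def test_indicator_in_two_composites_rejected():
    with pytest.raises(CascadeError):
        PathSpec(
            nodes=("c1", "c2", "y"),
            edges=(("c1", "y"), ("c2", "y")),
            composites=(
                Composite("c1", ("i1", "i2"), "y"),
                Composite("c2", ("i1", "i3"), "y"),
            ),
        )


def test_saturated_dag_empty_basis_set():
    spec = PathSpec(nodes=("a", "b", "c"), edges=(("a", "b"), ("a", "c"), ("b", "c")))
    assert dsep_basis_set(spec) == []


def test_chain_basis_set():
    spec = PathSpec(nodes=("x", "y", "z"), edges=(("x", "y"), ("y", "z")))
    assert dsep_basis_set(spec) == [Claim(u="x", v="z", cond=("y",))]


def _brute_force_basis_count(nodes, edges, correlated=()):
    """Independent enumeration of the basis set size (loops + DFS)."""
    children = {n: [] for n in nodes}
    for u, v in edges:
        children[u].append(v)

    def descendants(n):
        out, stack = set(), [n]
        while stack:
            for c in children[stack.pop()]:
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    adjacent = {frozenset(e) for e in edges} | {frozenset(p) for p in correlated}
    k = 0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if frozenset((u, v)) not in adjacent:
                k += 1  # exactly one claim per non-adjacent pair
    return k


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_basis_set_count_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    nodes = tuple("abcdef"[: rng.integers(3, 7)])
    edges = tuple(
        (nodes[i], nodes[j])
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
        if rng.random() < 0.4
    )
    spec = PathSpec(nodes=nodes, edges=edges)
    assert len(dsep_basis_set(spec)) == _brute_force_basis_count(nodes, edges)


def test_default_spec_basis_set():
    claims = dsep_basis_set(default_path_spec())
    assert claims == [Claim(u="physiochemistry", v="abundance", cond=("plant_growth", "r_m"))]


def test_spec_yaml_round_trip(tmp_path):
    spec = default_path_spec()
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    assert PathSpec.from_yaml(path) == spec


# ---------------------------------------------------------------------------
# Fisher's C


def test_fishers_c_values():
    assert fishers_c([1.0, 1.0]) == (0.0, 4, 1.0)
    C, df, p = fishers_c([0.5, 0.5])
    assert C == pytest.approx(2.7726, abs=1e-4)
    assert df == 4
    assert p == pytest.approx(stats.chi2.sf(C, 4))
    assert fishers_c([]) == (0.0, 0, 1.0)
    with pytest.raises(CascadeError):
        fishers_c([0.0, 0.5])


def test_claim_pvalues_uniform_under_true_model():
    """d-separation test calibration: claim p-values are U(0, 1)."""
    pvals = []
    spec = default_path_spec()
    for rep in range(400):
        df = gen_cascade_dataset(n=120, seed=10_000 + rep)
        fit = fit_paths(spec, df)
        pvals.extend(fit.claim_pvalues)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# path fitting


def test_perfect_single_edge_fit():
    x = np.linspace(-2, 2, 40)
    df = pd.DataFrame({"x": x, "y": 2 * x})
    fit = fit_paths(PathSpec(nodes=("x", "y"), edges=(("x", "y"),)), df)
    assert fit.edges[("x", "y")].beta == pytest.approx(1.0, abs=1e-10)
    assert fit.r2["y"] == pytest.approx(1.0, abs=1e-12)


def test_null_edge_recovery():
    df = gen_linear_dag({("x", "y"): 0.0}, n=10_000, seed=3)
    fit = fit_paths(PathSpec(nodes=("x", "y"), edges=(("x", "y"),)), df)
    assert abs(fit.edges[("x", "y")].beta) < 0.05


def test_single_predictor_beta_equals_pearson_r():
    rng = np.random.default_rng(6)
    x = rng.normal(size=200)
    y = 0.4 * x + rng.normal(size=200)
    df = pd.DataFrame({"x": x, "y": y})
    fit = fit_paths(PathSpec(nodes=("x", "y"), edges=(("x", "y"),)), df)
    r = stats.pearsonr(x, y)[0]
    assert fit.edges[("x", "y")].beta == pytest.approx(r, abs=1e-10)


def test_r2_matches_normal_equations():
    rng = np.random.default_rng(7)
    a, b = rng.normal(size=(2, 60))
    y = 0.5 * a - 0.3 * b + rng.normal(size=60)
    df = pd.DataFrame({"a": a, "b": b, "y": y})
    fit = fit_paths(PathSpec(nodes=("a", "b", "y"), edges=(("a", "y"), ("b", "y"))), df)
    Z = standardize(df)
    X = np.column_stack([np.ones(60), Z["a"], Z["b"]])
    beta = np.linalg.solve(X.T @ X, X.T @ Z["y"].to_numpy())
    resid = Z["y"].to_numpy() - X @ beta
    r2 = 1 - resid @ resid / (Z["y"].to_numpy() @ Z["y"].to_numpy())
    assert fit.r2["y"] == pytest.approx(r2, abs=1e-10)


def test_too_few_rows_rejected():
    df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [1.0, 0.0, 2.0], "z": [2.0, 1.0, 0.0]})
    spec = PathSpec(nodes=("x", "y", "z"), edges=(("x", "z"), ("y", "z")))
    with pytest.raises(CascadeError):
        fit_paths(spec, df.iloc[:3].assign(extra=0))  # 3 rows < 2 parents + 2


# ---------------------------------------------------------------------------
# pruning


def test_zero_edge_is_least_significant_first():
    """A genuinely zero path tops the removal order almost always."""
    coeffs = CascadeCoefficients(phys_to_rm=0.0)
    spec = default_path_spec()
    hits = 0
    for rep in range(200):
        df = gen_cascade_dataset(coeffs, n=500, seed=20_000 + rep)
        fit = fit_paths(spec, df)
        worst = max(fit.edges.items(), key=lambda kv: kv[1].p)[0]
        hits += worst == ("physiochemistry", "r_m")
    assert hits >= 180


def test_strong_edges_survive_pruning():
    edges = {("a", "b"): 0.6, ("a", "c"): 0.5, ("b", "c"): 0.5}
    df = gen_linear_dag(edges, n=1000, seed=17)
    spec = PathSpec(nodes=("a", "b", "c"), edges=tuple(edges))
    result = prune_paths(spec, df)
    assert result.removed == ()
    assert len(result.fitted.edges) == 3


def test_aic_trace_non_increasing():
    coeffs = CascadeCoefficients(phys_to_rm=0.0)
    for rep in range(10):
        df = gen_cascade_dataset(coeffs, n=400, seed=31_000 + rep)
        result = prune_paths(default_path_spec(), df)
        trace = np.array(result.aic_trace)
        assert np.all(np.diff(trace) < 0) or len(trace) == 1
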