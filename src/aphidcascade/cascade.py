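"""Piecewise path analysis: composites, d-separation, Fisher's C, AIC pruning.

The cascade from stress-driven plant change to aphid performance is
modelled as a set of linked ordinary least-squares regressions over a
directed acyclic graph (piecewise structural equation modelling).  Two
composite predictors bundle the plant indicators: *plant growth* (leaf
area, root volume) and *physiochemistry* (leaf water potential, tannin
content).  A composite is a loading-weighted sum of standardized
indicators, re-standardized to unit variance; following the usual
piecewise-SEM construction the loadings are the coefficients of an OLS
regression of the composite's designated response on its indicators,
frozen before the structural fits.

Global fit uses the d-separation basis set: every non-adjacent ordered
pair (u, v) with u not a descendant of v, conditioned on the union of
both nodes' parents.  Each independence claim is tested by regressing v
on u plus the conditioning set; the claim p-values combine into
Fisher's C = -2 sum ln p with df = 2k, tested against the upper
chi-square tail (p > 0.05 indicates adequate fit).  Model selection
removes the least-significant path while AIC = C + 2K drops, with K the
number of fitted coefficients (slopes + intercepts) across the
component regressions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats

__all__ = [
    "CascadeError",
    "Composite",
    "PathSpec",
    "EdgeFit",
    "Claim",
    "FittedPath",
    "PruneResult",
    "standardize",
    "fit_composite",
    "fit_paths",
    "dsep_basis_set",
    "fishers_c",
    "prune_paths",
    "default_path_spec",
]

_CONDITION_LIMIT = 1e8


class CascadeError(ValueError):
    """Raised for invalid path specifications or degenerate data."""


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column (mean 0, SD 1 with the n-1 denominator)."""
    if len(table) < 3:
        raise CascadeError("need at least 3 rows to standardize")
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise CascadeError(f"column {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=table.index)


@dataclass(frozen=True)
class CompositeFit:
    loadings: pd.Series
    scores: np.ndarray


def fit_composite(indicators: pd.DataFrame, response: pd.Series) -> CompositeFit:
    """Build a composite score from indicators.

    Loadings are the OLS coefficients of ``response`` on the standardized
    indicators; the score is the loading-weighted indicator sum,
    re-standardized.  Collinear indicators are rejected by condition
    number.
    """
    if indicators.shape[1] < 2:
        raise CascadeError("a composite needs at least 2 indicators")
    if len(indicators) < indicators.shape[1] + 2:
        raise CascadeError("too few rows for the number of indicators")
    Z = standardize(indicators)
    X = Z.to_numpy()
    if np.linalg.cond(X.T @ X) > _CONDITION_LIMIT:
        raise CascadeError("collinear indicators")
    y = np.asarray(response, dtype=float)
    y = (y - y.mean()) / y.std(ddof=1)
    beta = np.linalg.lstsq(sm.add_constant(X), y, rcond=None)[0][1:]
    raw = X @ beta
    sd = raw.std(ddof=1)
    if sd == 0:
        raise CascadeError("composite score has zero variance")
    return CompositeFit(loadings=pd.Series(beta, index=indicators.columns), scores=raw / sd)


@dataclass(frozen=True)
class Composite:
    """Named indicator bundle with the response its loadings are fit against."""

    name: str
    indicators: tuple[str, ...]
    response: str


@dataclass(frozen=True)
class PathSpec:
    """DAG over structural nodes, with composites and correlated-error pairs."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    composites: tuple[Composite, ...] = ()
    correlated: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise CascadeError("path specification is cyclic")
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise CascadeError(f"edge ({u}, {v}) references unknown node")
        for u, v in self.correlated:
            if u not in self.nodes or v not in self.nodes:
                raise CascadeError(f"correlated pair ({u}, {v}) references unknown node")
        seen: dict[str, str] = {}
        for comp in self.composites:
            if comp.name not in self.nodes:
                raise CascadeError(f"composite {comp.name!r} is not a node")
            for ind in comp.indicators:
                if ind in seen:
                    raise CascadeError(f"indicator {ind!r} in more than one composite")
                seen[ind] = comp.name

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == node))

    def endogenous(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.parents(n))

    def drop_edge(self, edge: tuple[str, str]) -> "PathSpec":
        if edge not in self.edges:
            raise CascadeError(f"edge {edge} not in specification")
        return replace(self, edges=tuple(e for e in self.edges if e != edge))

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = {
            "nodes": list(self.nodes),
            "edges": [list(e) for e in self.edges],
            "composites": [
                {"name": c.name, "indicators": list(c.indicators), "response": c.response}
                for c in self.composites
            ],
            "correlated": [list(p) for p in self.correlated],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PathSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            nodes=tuple(payload["nodes"]),
            edges=tuple(tuple(e) for e in payload["edges"]),
            composites=tuple(
                Composite(name=c["name"], indicators=tuple(c["indicators"]), response=c["response"])
                for c in payload.get("composites", [])
            ),
            correlated=tuple(tuple(p) for p in payload.get("correlated", [])),
        )


@dataclass(frozen=True)
class EdgeFit:
    beta: float
    se: float
    p: float


@dataclass(frozen=True)
class Claim:
    """Independence claim u _||_ v | cond, tested via the partial slope of u."""

    u: str
    v: str
    cond: tuple[str, ...]


@dataclass(frozen=True)
class FittedPath:
    spec: PathSpec
    edges: dict[tuple[str, str], EdgeFit]
    r2: dict[str, float]
    loadings: dict[str, pd.Series]
    correlations: dict[tuple[str, str], tuple[float, float]]
    claims: tuple[Claim, ...]
    claim_pvalues: tuple[float, ...]
    C: float
    df: int
    p_C: float
    K: int
    aic: float


def dsep_basis_set(spec: PathSpec) -> list[Claim]:
    """The d-separation basis set of the spec's DAG.

    One claim per non-adjacent unordered node pair, ordered so the first
    element is not a descendant of the second (lexicographic when neither
    descends from the other), conditioned on the union of both nodes'
    parents.  Correlated-error pairs count as adjacent.  The list is
    deterministically sorted.
    """
    g = spec.graph()
    adjacent = {frozenset(e) for e in spec.edges} | {frozenset(p) for p in spec.correlated}
    desc = {n: nx.descendants(g, n) for n in spec.nodes}
    claims = []
    for u, v in itertools.combinations(sorted(spec.nodes), 2):
        if frozenset((u, v)) in adjacent:
            continue
        if u in desc[v]:
            u, v = v, u
        cond = tuple(sorted((set(spec.parents(u)) | set(spec.parents(v))) - {u, v}))
        claims.append(Claim(u=u, v=v, cond=cond))
    return sorted(claims, key=lambda c: (c.u, c.v))


def fishers_c(pvalues) -> tuple[float, int, float]:
    """Fisher's C = -2 sum ln p over k claims; df = 2k; upper chi-square p."""
    pvalues = list(pvalues)
    if not pvalues:
        return 0.0, 0, 1.0
    for p in pvalues:
        if not 0.0 < p <= 1.0:
            raise CascadeError(f"claim p-value {p} outside (0, 1]")
    C = float(-2.0 * np.sum(np.log(pvalues)))
    df = 2 * len(pvalues)
    return C, df, float(stats.chi2.sf(C, df))


def _ols(y: np.ndarray, X: pd.DataFrame):
    model = sm.OLS(y, sm.add_constant(X.to_numpy()))
    return model.fit()


def fit_paths(spec: PathSpec, table: pd.DataFrame) -> FittedPath:
    """Fit every component regression of the path model on standardized data.

    Composite scores are built first (from stored loadings when the score
    column is already present in ``table`` under the composite's name,
    otherwise estimated via :func:`fit_composite` against the designated
    response); each endogenous node is then regressed on its parents.
    All variables are standardized, so slopes are standardized path
    coefficients.
    """
    composite_names = {c.name for c in spec.composites}
    needed = [n for n in spec.nodes if n not in composite_names]
    missing = [n for n in needed if n not in table.columns]
    if missing:
        raise CascadeError(f"nodes missing from table: {missing}")
    use: list[str] = list(needed)
    for comp in spec.composites:
        if comp.name in table.columns:
            use.append(comp.name)
        else:
            absent = [i for i in comp.indicators if i not in table.columns]
            if absent:
                raise CascadeError(f"indicators missing from table: {absent}")
            use.extend(comp.indicators)

    work = standardize(table[use])

    loadings: dict[str, pd.Series] = {}
    frame = pd.DataFrame(index=table.index)
    for n in needed:
        frame[n] = work[n]
    for comp in spec.composites:
        if comp.name in work.columns:
            # score column supplied directly (e.g. by the generator)
            frame[comp.name] = work[comp.name]
            continue
        if comp.response not in work.columns:
            raise CascadeError(f"composite response {comp.response!r} missing from table")
        cf = fit_composite(work[list(comp.indicators)], work[comp.response])
        loadings[comp.name] = cf.loadings
        frame[comp.name] = cf.scores

    largest_parent_set = max((len(spec.parents(n)) for n in spec.endogenous()), default=0)
    if len(frame) < largest_parent_set + 2:
        raise CascadeError("fewer rows than largest parent set + 2")

    edges: dict[tuple[str, str], EdgeFit] = {}
    r2: dict[str, float] = {}
    K = 0
    for node in spec.endogenous():
        parents = spec.parents(node)
        res = _ols(frame[node].to_numpy(), frame[list(parents)])
        for j, parent in enumerate(parents):
            edges[(parent, node)] = EdgeFit(
                beta=float(res.params[j + 1]),
                se=float(res.bse[j + 1]),
                p=float(res.pvalues[j + 1]),
            )
        r2[node] = float(res.rsquared)
        K += len(parents) + 1

    correlations: dict[tuple[str, str], tuple[float, float]] = {}
    for u, v in spec.correlated:
        r, p = stats.pearsonr(frame[u], frame[v])
        correlations[(u, v)] = (float(r), float(p))

    claims = tuple(dsep_basis_set(spec))
    pvals = []
    for claim in claims:
        regressors = [claim.u, *claim.cond]
        res = _ols(frame[claim.v].to_numpy(), frame[regressors])
        pvals.append(float(res.pvalues[1]))
    C, dfree, p_C = fishers_c(pvals)
    return FittedPath(
        spec=spec, edges=edges, r2=r2, loadings=loadings, correlations=correlations,
        claims=claims, claim_pvalues=tuple(pvals), C=C, df=dfree, p_C=p_C,
        K=K, aic=C + 2 * K,
    )


@dataclass(frozen=True)
class PruneResult:
    fitted: FittedPath
    spec: PathSpec
    aic_trace: tuple[float, ...]
    removed: tuple[tuple[str, str], ...]


def prune_paths(spec: PathSpec, table: pd.DataFrame) -> PruneResult:
    """Backward AIC pruning of non-significant paths.

    Repeatedly proposes removing the single least-significant edge
    (largest p; ties broken by smaller |beta|, then lexicographic edge
    label) and accepts the removal only if AIC = C + 2K decreases; stops
    otherwise.  The AIC trace over accepted models is therefore strictly
    decreasing.
    """
    fitted = fit_paths(spec, table)
    trace = [fitted.aic]
    removed: list[tuple[str, str]] = []
    while fitted.edges:
        edge = min(
            fitted.edges.items(),
            key=lambda item: (-item[1].p, abs(item[1].beta), "->".join(item[0])),
        )[0]
        candidate_spec = fitted.spec.drop_edge(edge)
        candidate = fit_paths(candidate_spec, table)
        if candidate.aic < fitted.aic:
            fitted = candidate
            trace.append(candidate.aic)
            removed.append(edge)
        else:
            break
    return PruneResult(fitted=fitted, spec=fitted.spec, aic_trace=tuple(trace), removed=tuple(removed))


def default_path_spec() -> PathSpec:
    """The stress-cascade path model.

    plant_growth (composite of leaf area and root volume) and
    physiochemistry (composite of water potential and tannin) are
    correlated exogenous predictors; the aphid intrinsic rate of
    increase r_m responds to both, and whole-period mean abundance
    responds to plant growth and r_m.
    """
    return PathSpec(
        nodes=("plant_growth", "physiochemistry", "r_m", "abundance"),
        edges=(
            ("plant_growth", "r_m"),
            ("physiochemistry", "r_m"),
            ("plant_growth", "abundance"),
            ("r_m", "abundance"),
        ),
        composites=(
            Composite(name="plant_growth", indicators=("leaf_area", "root_volume"), response="abundance"),
            Composite(name="physiochemistry", indicators=("water_potential", "tannin"), response="r_m"),
        ),
        correlated=(("plant_growth", "physiochemistry"),),
    )
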