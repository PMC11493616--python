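"""Linear-Gaussian cascade generator for the path analysis.

Two entry points:

* :func:`gen_linear_dag` samples an arbitrary DAG of standardized
  variables: exogenous nodes are independent N(0, 1); each endogenous
  node is the coefficient-weighted sum of its parents plus Gaussian
  noise scaled so the marginal variance is exactly 1 (an error if the
  coefficients already imply variance > 1).

* :func:`gen_cascade_dataset` samples the calibrated stress-cascade
  testbed: correlated composite scores *plant growth* g and
  *physiochemistry* p (corr rho), indicator pairs built around each
  score, and the two structural equations

      r_m       = b_g2r * g + b_p2r * p + noise
      abundance = b_g2a * g + b_r2a * r_m + noise.

  The indicator construction is exact rather than noisy-proxy: each
  indicator pair (i1, i2) with loadings (w1, w2) is built as

      i1 = a1 * s + w2 * kappa * d,    i2 = a2 * s - w1 * kappa * d,

  with s the composite score and d an independent N(0, 1) disturbance,
  so the loading-weighted sum w1*i1 + w2*i2 = (w1*a1 + w2*a2) * s
  reproduces the score exactly (the disturbance cancels).  The scale
  (a1, a2, kappa) is solved so the indicators have unit variance and the
  population OLS regression of the composite's designated response on
  the raw indicators returns exactly the calibrated loadings — i.e. the
  fitting side's composite construction recovers the generator's truth.

Default coefficients are the reported standardized effects of the
stress-cascade analysis; under them the population R-squared values are
0.584 for r_m and 0.801 for abundance, matching the reported 0.58/0.80.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from aphidcascade.cascade import CascadeError

__all__ = ["CascadeCoefficients", "DEFAULT_CASCADE", "gen_cascade_dataset", "gen_linear_dag"]


@dataclass(frozen=True)
class CascadeCoefficients:
    """Standardized coefficient set of the calibrated cascade testbed."""

    growth_loadings: tuple[tuple[str, float], ...] = (("leaf_area", 0.407), ("root_volume", 0.535))
    phys_loadings: tuple[tuple[str, float], ...] = (("water_potential", 0.553), ("tannin", -0.336))
    growth_phys_corr: float = 0.838
    growth_to_rm: float = 0.820
    phys_to_rm: float = -0.068
    growth_to_abundance: float = 0.544
    rm_to_abundance: float = 0.408

    def response_slope_growth(self) -> float:
        """Population slope of abundance on the growth score."""
        return self.growth_to_abundance + self.rm_to_abundance * self.rm_slope_on_growth()

    def rm_slope_on_growth(self) -> float:
        """cov(g, r_m) = direct effect plus the correlated-physiochemistry path."""
        return self.growth_to_rm + self.phys_to_rm * self.growth_phys_corr

    def response_slope_phys(self) -> float:
        """Population slope of r_m on the physiochemistry score."""
        return self.growth_to_rm * self.growth_phys_corr + self.phys_to_rm


DEFAULT_CASCADE = CascadeCoefficients()


def _solve_indicator_pair(w1: float, w2: float, target: float) -> tuple[float, float, float]:
    """Solve (a1, a2, kappa) so indicators are unit-variance and the
    response-on-indicators regression returns (w1, w2) exactly.

    Requires w1*a1 + w2*a2 = target with a_i = sign(w_i) sqrt(1 - (w_other kappa)^2);
    the left side decreases from |w1| + |w2| as kappa grows, so a root
    exists iff target <= |w1| + |w2| (and above the kappa-limited floor).
    """
    if target <= 0:
        raise CascadeError("composite response slope must be positive for calibration")

    def nu(kappa: float) -> float:
        t1 = 1.0 - (w2 * kappa) ** 2
        t2 = 1.0 - (w1 * kappa) ** 2
        if t1 < 0 or t2 < 0:
            return np.nan
        return abs(w1) * np.sqrt(t1) + abs(w2) * np.sqrt(t2)

    hi = 1.0 / max(abs(w1), abs(w2))
    if nu(0.0) < target:
        raise CascadeError("loadings too small for the requested response slope")
    if nu(hi) > target:
        raise CascadeError("response slope below the reachable range")
    kappa = brentq(lambda k: nu(k) - target, 0.0, hi, xtol=1e-14)
    a1 = np.copysign(np.sqrt(1.0 - (w2 * kappa) ** 2), w1)
    a2 = np.copysign(np.sqrt(1.0 - (w1 * kappa) ** 2), w2)
    return float(a1), float(a2), float(kappa)


def gen_cascade_dataset(
    coeffs: CascadeCoefficients | Mapping[tuple[str, str], float] | None = None,
    n: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample a standardized trait table for the path analysis.

    With a :class:`CascadeCoefficients` (or None for the defaults) the
    calibrated six-indicator cascade is generated; the composite score
    columns ``plant_growth`` and ``physiochemistry`` are included
    alongside the indicator columns.  With a mapping of
    ``(cause, effect) -> beta`` an arbitrary linear DAG is generated via
    :func:`gen_linear_dag`.
    """
    if isinstance(coeffs, Mapping):
        return gen_linear_dag(coeffs, n=n, seed=seed)
    c = coeffs if coeffs is not None else DEFAULT_CASCADE
    if n < 10:
        raise CascadeError("n must be >= 10")
    rho = c.growth_phys_corr
    if not -1.0 < rho < 1.0:
        raise CascadeError("growth_phys_corr must be in (-1, 1)")

    rng = np.random.default_rng(seed)
    p_score = rng.standard_normal(n)
    g_score = rho * p_score + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)

    (g1, wg1), (g2, wg2) = c.growth_loadings
    a1, a2, kap_g = _solve_indicator_pair(wg1, wg2, c.response_slope_growth())
    d = rng.standard_normal(n)
    cols = {
        g1: a1 * g_score + wg2 * kap_g * d,
        g2: a2 * g_score - wg1 * kap_g * d,
    }
    (p1, wp1), (p2, wp2) = c.phys_loadings
    b1, b2, kap_p = _solve_indicator_pair(wp1, wp2, c.response_slope_phys())
    e = rng.standard_normal(n)
    cols[p1] = b1 * p_score + wp2 * kap_p * e
    cols[p2] = b2 * p_score - wp1 * kap_p * e

    var_rm = c.growth_to_rm**2 + c.phys_to_rm**2 + 2 * c.growth_to_rm * c.phys_to_rm * rho
    if var_rm > 1:
        raise CascadeError("r_m coefficients imply variance > 1")
    r_m = (
        c.growth_to_rm * g_score
        + c.phys_to_rm * p_score
        + np.sqrt(1.0 - var_rm) * rng.standard_normal(n)
    )
    cov_g_rm = c.rm_slope_on_growth()
    var_ab = (
        c.growth_to_abundance**2
        + c.rm_to_abundance**2
        + 2 * c.growth_to_abundance * c.rm_to_abundance * cov_g_rm
    )
    if var_ab > 1:
        raise CascadeError("abundance coefficients imply variance > 1")
    abundance = (
        c.growth_to_abundance * g_score
        + c.rm_to_abundance * r_m
        + np.sqrt(1.0 - var_ab) * rng.standard_normal(n)
    )
    cols["r_m"] = r_m
    cols["abundance"] = abundance
    cols["plant_growth"] = g_score
    cols["physiochemistry"] = p_score
    order = [g1, g2, p1, p2, "r_m", "abundance", "plant_growth", "physiochemistry"]
    return pd.DataFrame({k: cols[k] for k in order})


def gen_linear_dag(
    edges: Mapping[tuple[str, str], float], n: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Sample a standardized linear-Gaussian DAG from an edge->beta mapping.

    Nodes are inferred from the edge list; exogenous nodes are
    independent N(0, 1); endogenous nodes get Gaussian noise scaled so
    their population variance is exactly 1 (zero noise when the
    coefficients already explain everything; an error if they imply
    variance > 1).
    """
    if n < 10:
        raise CascadeError("n must be >= 10")
    g = nx.DiGraph()
    for (u, v), beta in edges.items():
        g.add_edge(u, v, beta=float(beta))
    if not nx.is_directed_acyclic_graph(g):
        raise CascadeError("coefficient graph is cyclic")
    rng = np.random.default_rng(seed)
    order = list(nx.lexicographical_topological_sort(g))
    cov: dict[tuple[str, str], float] = {}
    data: dict[str, np.ndarray] = {}

    def get_cov(a: str, b: str) -> float:
        return cov.get((a, b), cov.get((b, a), 0.0))

    for node in order:
        parents = sorted(g.predecessors(node))
        if not parents:
            data[node] = rng.standard_normal(n)
            cov[(node, node)] = 1.0
            for other in data:
                if other != node:
                    cov[(node, other)] = 0.0
            continue
        betas = np.array([g.edges[p, node]["beta"] for p in parents])
        S = np.array([[get_cov(a, b) for b in parents] for a in parents])
        explained = float(betas @ S @ betas)
        if explained > 1.0 + 1e-9:
            raise CascadeError(
                f"coefficients into {node!r} imply variance {explained:.3f} > 1"
            )
        noise_sd = np.sqrt(max(1.0 - explained, 0.0))
        value = noise_sd * rng.standard_normal(n)
        for beta, p in zip(betas, parents):
            value = value + beta * data[p]
        data[node] = value
        cov[(node, node)] = 1.0
        for other in order:
            if other == node or other not in data:
                continue
            cov[(node, other)] = float(
                sum(beta * get_cov(p, other) for beta, p in zip(betas, parents))
            )
    return pd.DataFrame({k: data[k] for k in sorted(data)})
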