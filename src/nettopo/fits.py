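"""Power-law fitting of degree distributions and degree–clustering profiles.

The fitting procedure is ordinary least squares on base-10 logarithmized
data: for points (x_i, y_i) with x_i, y_i > 0 the model log10 y = gamma *
log10 x + b is fitted, gamma is the reported exponent and 10**b the
amplitude.  Two goodness statistics are reported and they are deliberately
distinct:

* ``r_squared`` — the coefficient of determination of the linear fit on the
  LOGARITHMIZED data (equal to the squared Pearson correlation of the
  log-log points, an OLS identity).
* ``r`` — the Pearson correlation between the OBSERVED values and the FITTED
  power-law values amplitude * x**gamma on the ORIGINAL scale.

This mirrors the convention of the Cytoscape NetworkAnalyzer power-law
panel, where the two statistics are printed side by side and are generally
not related by r**2 = R².

Zero counts and zero clustering classes cannot enter a log fit and are
excluded upstream (with logging); no logarithmic binning of the degree axis
is applied — raw degree classes are fitted as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .metrics import degree_distribution, node_clustering

logger = logging.getLogger(__name__)

__all__ = [
    "PowerLawFit",
    "DegreeClusteringProfile",
    "FitError",
    "fit_power_law",
    "fit_degree_distribution",
    "degree_clustering_profile",
    "fit_degree_vs_clustering",
]


class FitError(ValueError):
    """Raised when a power-law fit is impossible (too few or degenerate points)."""


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a least-squares power-law fit y = amplitude * x**gamma."""

    gamma: float
    amplitude: float
    r: float
    r_squared: float
    n_points: int

    def to_row(self) -> dict[str, object]:
        return {
            "gamma": round(self.gamma, 3),
            "r": round(self.r, 3),
            "R2": round(self.r_squared, 3),
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class DegreeClusteringProfile:
    """Mean clustering coefficient per degree class k >= 2.

    ``n_excluded_zero`` counts degree classes whose mean clustering was 0
    (log-undefined, excluded from fitting).
    """

    points: tuple[tuple[int, float], ...]
    n_excluded_zero: int = 0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    # degenerate (zero-variance) inputs: correlation is undefined; report 1.0
    # for an exact match (fit reproduces the data) and 0.0 otherwise
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_power_law(points) -> PowerLawFit:
    """OLS fit of log10 y on log10 x.

    Parameters
    ----------
    points : sequence of (x, y)
        Strictly positive coordinates; callers exclude zero values upstream.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if any(x <= 0 or y <= 0 for x, y in pts):
        raise FitError("fit_power_law requires strictly positive x and y")
    if len(pts) < 2:
        raise FitError(f"fit_power_law requires >= 2 points, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.all(x == x[0]):
        raise FitError("fit_power_law: all x values identical (degenerate fit)")
    log_x, log_y = np.log10(x), np.log10(y)
    result = stats.linregress(log_x, log_y)
    gamma = float(result.slope)
    amplitude = float(10.0 ** result.intercept)
    fitted = amplitude * x ** gamma
    return PowerLawFit(
        gamma=gamma,
        amplitude=amplitude,
        r=_pearson(y, fitted),
        r_squared=float(result.rvalue) ** 2,
        n_points=len(pts),
    )


def fit_degree_distribution(net: nx.Graph) -> PowerLawFit:
    """Fit the node-degree distribution n(k) ~ k**gamma.

    Requires at least two distinct positive degree classes (a ring or a
    complete graph has one and cannot be fitted).
    """
    dist = degree_distribution(net)
    if len(dist.points) < 2:
        raise FitError(
            f"degree distribution of {net.graph.get('name', '?')} has "
            f"{len(dist.points)} degree class(es); need >= 2"
        )
    return fit_power_law(dist.points)


def degree_clustering_profile(net: nx.Graph) -> DegreeClusteringProfile:
    """Mean node clustering per degree class k >= 2, zero-mean classes excluded."""
    by_degree: dict[int, list[float]] = {}
    for node in net.nodes:
        k = len(net.adj[node])
        if k < 2:
            continue
        c = node_clustering(net, node)
        by_degree.setdefault(k, []).append(c)
    points = []
    n_excluded = 0
    for k in sorted(by_degree):
        mean_cc = sum(by_degree[k]) / len(by_degree[k])
        if mean_cc > 0:
            points.append((k, mean_cc))
        else:
            n_excluded += 1
    if n_excluded:
        logger.info(
            "degree_clustering_profile(%s): excluded %d zero-clustering degree classes",
            net.graph.get("name", "?"), n_excluded,
        )
    return DegreeClusteringProfile(points=tuple(points), n_excluded_zero=n_excluded)


def fit_degree_vs_clustering(net: nx.Graph, per_node: bool = False) -> PowerLawFit:
    """Fit mean clustering vs degree, C(k) ~ k**gamma.

    By default the fit is over per-degree-class mean clustering values;
    ``per_node=True`` fits the raw per-node (k, C) scatter instead (nodes
    with undefined or zero clustering are excluded either way).
    """
    if per_node:
        pts = []
        for node in net.nodes:
            k = len(net.adj[node])
            c = node_clustering(net, node)
            if c is not None and c > 0:
                pts.append((k, c))
        n_dropped = net.number_of_nodes() - len(pts)
        if n_dropped:
            logger.info(
                "fit_degree_vs_clustering(%s): excluded %d nodes with undefined/zero clustering",
                net.graph.get("name", "?"), n_dropped,
            )
        if len(pts) < 2:
            raise FitError("fewer than 2 nodes with positive clustering")
        return fit_power_law(pts)
    profile = degree_clustering_profile(net)
    if len(profile.points) < 2:
        raise FitError(
            f"degree-clustering profile of {net.graph.get('name', '?')} has "
            f"{len(profile.points)} usable class(es); need >= 2"
        )
    return fit_power_law(profile.points)
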