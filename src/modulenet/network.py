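"""Sparse Gaussian graphical model estimation and the derived gene network.

The gene network is the support of an L1-penalized maximum-likelihood
estimate of the inverse covariance (precision) matrix theta: an edge
joins genes i and j exactly when theta_ij is nonzero, i.e. when the two
genes are conditionally dependent given all others. The penalty rho is
chosen by scanning a grid and keeping the densest network that still
admits at least one seed-module set for the partitioning step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .errors import ConvergenceError, DataError, NoSeedSetError
from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_SUPPORT_TOL = 1e-8
DEFAULT_PENALTY_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass
class PrecisionEstimate:
    """An estimated precision matrix with its provenance.

    ``objective`` is the penalized log-likelihood
    log det(theta) - tr(S theta) - rho * ||theta||_1, with the L1 norm
    taken over the off-diagonal only unless ``penalize_diagonal``.
    """

    theta: np.ndarray
    rho: float
    empirical_cov: np.ndarray
    converged: bool
    objective: float
    penalize_diagonal: bool = False
    n_iter: int | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.empirical_cov = np.asarray(self.empirical_cov, dtype=float)
        if self.rho < 0:
            raise DataError(f"penalty rho must be nonnegative, got {self.rho}")


@dataclass
class GeneNetwork:
    """Undirected gene network backed by a networkx graph."""

    graph: nx.Graph
    gene_ids: list[str]
    source: PrecisionEstimate | None = None

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return list(self.gene_ids)

    def degree(self) -> dict[str, int]:
        return {g: self.graph.degree(g) for g in self.gene_ids}

    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges()]

    @classmethod
    def from_graph(cls, graph: nx.Graph, source: PrecisionEstimate | None = None) -> "GeneNetwork":
        return cls(graph=graph, gene_ids=[str(n) for n in graph.nodes()], source=source)

    @classmethod
    def from_edgelist(cls, path: str | Path) -> "GeneNetwork":
        """Read an edge-list TSV (gene_a, gene_b[, weight]); header optional."""
        g = nx.Graph()
        with open(path) as fh:
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise DataError(f"edge-list line {i + 1} has fewer than two columns")
                if i == 0 and parts[0].lower() in {"gene_a", "source", "from"}:
                    continue
                a, b = parts[0], parts[1]
                if a == b:
                    raise DataError(f"self-loop on {a!r} at line {i + 1}")
                w = float(parts[2]) if len(parts) > 2 else 1.0
                g.add_edge(a, b, weight=w)
        return cls.from_graph(g)

    def write_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\ttheta_ij\n")
            for a, b in sorted(self.edges()):
                w = self.graph.edges[a, b].get("weight", 1.0)
                fh.write(f"{a}\t{b}\t{w:.6g}\n")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)

    def write_degree_table(self, path: str | Path) -> None:
        deg = self.degree()
        with open(path, "w") as fh:
            fh.write("gene\tdegree\n")
            for g in sorted(deg, key=lambda x: (-deg[x], x)):
                fh.write(f"{g}\t{deg[g]}\n")


def standardize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene and scale to unit variance (1/N convention).

    Zero-variance genes are left centered but unscaled, with a warning.
    """
    x = mat.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    zero = sd[:, 0] == 0
    if zero.any():
        logger.warning("standardize: %d zero-variance genes left unscaled", int(zero.sum()))
    sd = np.where(sd == 0, 1.0, sd)
    return ExpressionMatrix(list(mat.gene_ids), list(mat.sample_ids), (x - mu) / sd)


def empirical_covariance(mat: ExpressionMatrix, ddof: int = 0) -> np.ndarray:
    """Gene-by-gene empirical covariance across samples.

    Uses the maximum-likelihood 1/N normalization by default (ddof=0),
    consistent with the penalized Gaussian likelihood.
    """
    if mat.n_samples < 2:
        raise DataError("covariance requires at least 2 samples")
    x = mat.values - mat.values.mean(axis=1, keepdims=True)
    s = x @ x.T / (mat.n_samples - ddof)
    return (s + s.T) / 2.0


def _penalized_loglik(theta: np.ndarray, s: np.ndarray, rho: float, penalize_diagonal: bool) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    l1 = np.abs(theta).sum()
    if not penalize_diagonal:
        l1 -= np.abs(np.diag(theta)).sum()
    return float(logdet - np.trace(s @ theta) - rho * l1)


def graphical_lasso(
    s: np.ndarray,
    rho: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    penalize_diagonal: bool = False,
) -> PrecisionEstimate:
    """Maximize log det(theta) - tr(S theta) - rho*||theta||_1.

    With ``penalize_diagonal`` the L1 norm runs over the whole matrix;
    this is solved exactly through the off-diagonal-only problem on
    S + rho*I (the diagonal of theta is positive at any optimum, so its
    penalty is a linear term absorbable into S). rho=0 requires an
    invertible S and returns its inverse.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise DataError(f"S must be square, got shape {s.shape}")
    if not np.allclose(s, s.T, atol=1e-8):
        raise DataError("S must be symmetric")
    if rho < 0:
        raise DataError(f"rho must be nonnegative, got {rho}")

    if rho == 0:
        try:
            theta = np.linalg.inv(s)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("S is singular; rho=0 requires an invertible S") from exc
        cond = np.linalg.cond(s)
        if not np.isfinite(cond) or cond > 1e12:
            raise ConvergenceError(f"S is numerically singular (cond={cond:.3g}); use rho > 0")
        theta = (theta + theta.T) / 2.0
        return PrecisionEstimate(
            theta=theta,
            rho=0.0,
            empirical_cov=s,
            converged=True,
            objective=_penalized_loglik(theta, s, 0.0, penalize_diagonal),
            penalize_diagonal=penalize_diagonal,
        )

    s_eff = s + rho * np.eye(s.shape[0]) if penalize_diagonal else s
    converged = True
    n_iter = None
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            _, theta, n_iter = _sk_graphical_lasso(
                s_eff, alpha=rho, tol=tol, enet_tol=tol, max_iter=max_iter,
                return_n_iter=True,
            )
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, theta, n_iter = _sk_graphical_lasso(
                    s_eff, alpha=rho, tol=tol, enet_tol=tol, max_iter=max_iter,
                    return_n_iter=True,
                )
        except FloatingPointError as exc:
            raise ConvergenceError(f"graphical lasso failed at rho={rho}: {exc}") from exc
    theta = (theta + theta.T) / 2.0
    return PrecisionEstimate(
        theta=theta,
        rho=float(rho),
        empirical_cov=s,
        converged=converged,
        objective=_penalized_loglik(theta, s, rho, penalize_diagonal),
        penalize_diagonal=penalize_diagonal,
        n_iter=n_iter,
    )


def network_from_precision(
    est: PrecisionEstimate,
    gene_ids: Sequence[str],
    support_tol: float = DEFAULT_SUPPORT_TOL,
) -> GeneNetwork:
    """Build the gene network from the off-diagonal support of theta.

    An edge (i, j) exists when either triangle entry exceeds
    ``support_tol`` in absolute value (OR-symmetrization); no self-loops.
    """
    if not est.converged:
        raise ConvergenceError("refusing to build a network from a non-converged estimate")
    theta = est.theta
    p = theta.shape[0]
    if len(gene_ids) != p:
        raise DataError(f"{len(gene_ids)} gene ids for a {p}x{p} precision matrix")
    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    mag = np.maximum(np.abs(theta), np.abs(theta.T))
    ii, jj = np.nonzero(np.triu(mag, k=1) > support_tol)
    for i, j in zip(ii, jj):
        g.add_edge(gene_ids[i], gene_ids[j], weight=float(theta[i, j]))
    return GeneNetwork(graph=g, gene_ids=[str(x) for x in gene_ids], source=est)


@dataclass
class PenaltyScanResult:
    selected_rho: float
    table: pd.DataFrame
    network: GeneNetwork
    estimate: PrecisionEstimate

    def write_table(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def penalty_scan(
    mat: ExpressionMatrix,
    grid: Sequence[float] = DEFAULT_PENALTY_GRID,
    k: int = 20,
    support_tol: float = DEFAULT_SUPPORT_TOL,
    do_standardize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
    penalize_diagonal: bool = False,
) -> PenaltyScanResult:
    """Scan the penalty grid and keep the densest feasible network.

    The selected rho is the smallest grid value whose network admits at
    least one seed-module set (checked with up to ``k`` hubs) — i.e. the
    network that keeps the most edges while remaining partitionable.
    rho=0 is skipped with a warning when P > N (singular covariance).
    """
    from .partition import enumerate_seed_sets, initialize_modules, select_hubs

    grid = [float(r) for r in grid]
    if not grid:
        raise DataError("penalty grid is empty")
    if sorted(grid) != grid:
        raise DataError("penalty grid must be sorted ascending")
    work = standardize(mat) if do_standardize else mat
    s = empirical_covariance(work)

    rows = []
    candidates: list[tuple[float, GeneNetwork, PrecisionEstimate]] = []
    prev_edges: int | None = None
    for rho in grid:
        if rho == 0 and mat.n_genes > mat.n_samples:
            logger.warning("penalty_scan: skipping rho=0 (P=%d > N=%d, S singular)", mat.n_genes, mat.n_samples)
            rows.append({"rho": rho, "n_edges": np.nan, "n_nodes_degree_ge1": np.nan,
                         "has_seed_set": False, "converged": False})
            continue
        try:
            est = graphical_lasso(s, rho, tol=tol, max_iter=max_iter, penalize_diagonal=penalize_diagonal)
        except ConvergenceError as exc:
            logger.warning("penalty_scan: rho=%.3g infeasible (%s)", rho, exc)
            rows.append({"rho": rho, "n_edges": np.nan, "n_nodes_degree_ge1": np.nan,
                         "has_seed_set": False, "converged": False})
            continue
        net = network_from_precision(est, work.gene_ids, support_tol=support_tol) if est.converged else None
        if net is None:
            rows.append({"rho": rho, "n_edges": np.nan, "n_nodes_degree_ge1": np.nan,
                         "has_seed_set": False, "converged": False})
            continue
        deg = net.degree()
        n_pos = sum(1 for d in deg.values() if d >= 1)
        has_seed = False
        if n_pos >= 2:
            k_eff = min(k, n_pos)
            hubs = select_hubs(net, k=k_eff)
            mods = initialize_modules(net, hubs)
            has_seed = len(mods) >= 2 and bool(enumerate_seed_sets(mods))
        if prev_edges is not None and net.n_edges > prev_edges:
            logger.warning(
                "penalty_scan: edge count increased from %d to %d at rho=%.3g "
                "(expected non-increasing in rho)", prev_edges, net.n_edges, rho,
            )
        prev_edges = net.n_edges
        rows.append({"rho": rho, "n_edges": net.n_edges, "n_nodes_degree_ge1": n_pos,
                     "has_seed_set": has_seed, "converged": True})
        if has_seed:
            candidates.append((rho, net, est))
    table = pd.DataFrame(rows)
    if not candidates:
        raise NoSeedSetError(
            "no penalty on the grid yields a network with a seed-module set; "
            "try a finer grid or different support tolerance"
        )
    rho_sel, net_sel, est_sel = candidates[0]
    return PenaltyScanResult(selected_rho=rho_sel, table=table, network=net_sel, estimate=est_sel)


@dataclass
class PowerLawFit:
    """Least-squares log-log fit of the degree distribution (diagnostic)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    scale_free_like: bool
    warning: str | None = None


def degree_distribution_fit(net: GeneNetwork) -> PowerLawFit:
    """Fit log10(frequency) vs log10(degree) over degrees >= 1.

    A scale-free network shows a clearly negative slope with a good
    linear fit. This is a shape diagnostic only, not a formal power-law
    test.
    """
    degrees = [d for d in net.degree().values() if d >= 1]
    if not degrees:
        raise DataError("degree distribution fit requires a non-empty network")
    values, counts = np.unique(degrees, return_counts=True)
    warning = None
    if len(degrees) < 10:
        warning = "fewer than 10 positive-degree nodes; fit is unreliable"
    if len(values) < 3:
        warning = f"only {len(values)} distinct degree values; fit is degenerate"
    if len(values) < 2:
        return PowerLawFit(slope=0.0, intercept=float(np.log10(counts[0] / len(degrees))),
                           r_squared=1.0, n_points=1, scale_free_like=False,
                           warning=warning or "single-valued degree distribution")
    x = np.log10(values.astype(float))
    y = np.log10(counts / len(degrees))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid ** 2).sum()) / ss_tot
    scale_free_like = bool(slope < -0.5 and r2 > 0.5)
    if not scale_free_like and warning is None:
        warning = "degree distribution does not look scale-free"
    return PowerLawFit(slope=float(slope), intercept=float(intercept), r_squared=r2,
                       n_points=len(values), scale_free_like=scale_free_like, warning=warning)
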