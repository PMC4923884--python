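"""Synthetic expression data with known network and outcome structure.

The generator draws multivariate-normal expression from a sparse,
hub-dominated precision matrix: each planted module is a star of one
hub gene and its leaves, optionally plus random background edges among
the remaining genes. Two patient classes differ by a mean shift on one
module's genes, and survival times are exponential with class-dependent
rates, so class membership, network structure and outcome are all known
ground truth for testing the full pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .errors import DataError
from .expression_io import ExpressionMatrix, SampleAnnotation

# Default hub-edge precision weight: scaled by 1/sqrt(hub_degree) so that a
# star block's minimum eigenvalue (1 - w*sqrt(degree)) keeps a stable
# positive-definiteness margin of 0.2 regardless of degree, while the edge
# partial correlations (~0.28 at degree 8) stay strong enough to be
# realistic, detectable co-expression.
DEFAULT_HUB_WEIGHT_SCALE = 0.8
DEFAULT_BACKGROUND_WEIGHT = 0.25
# Exponential survival rates: ~40% of high-risk patients experience the
# event before the two-year (730 day) cutoff; ~10% of low-risk do.
RATE_HIGH = -math.log(0.6) / 730.0
RATE_LOW = -math.log(0.9) / 730.0


@dataclass
class SyntheticModel:
    """Ground truth for a simulated cohort."""

    precision_true: sparse.csr_matrix   # P x P sparse symmetric PD
    gene_ids: list[str]
    module_truth: dict[str, int | None]  # gene -> planted module index (None = background)
    hub_truth: list[str]
    effect_size: float                   # overall shift scale, sigma units
    shifted_modules: tuple[int, ...]     # planted modules receiving the shift
    effect_profile: dict[str, float]     # gene -> signed per-gene shift (sigma units)
    rate_high: float                     # event rate (1/day) of the short-survival class
    rate_low: float
    rng_seed: int

    @property
    def p(self) -> int:
        return len(self.gene_ids)

    def true_edges(self) -> set[tuple[str, str]]:
        coo = sparse.triu(self.precision_true, k=1).tocoo()
        return {
            tuple(sorted((self.gene_ids[i], self.gene_ids[j])))
            for i, j, v in zip(coo.row, coo.col, coo.data)
            if v != 0
        }

    def module_genes(self, module: int) -> set[str]:
        return {g for g, m in self.module_truth.items() if m == module}

    def min_eigenvalue(self) -> float:
        return min(
            float(np.linalg.eigvalsh(block).min())
            for block, _ in _components(self.precision_true)
        )


def _components(theta: sparse.spmatrix) -> list[tuple[np.ndarray, np.ndarray]]:
    """Dense (block, index) pairs for each connected component of the support."""
    n, labels = connected_components(abs(theta) > 0, directed=False)
    out = []
    for c in range(n):
        idx = np.where(labels == c)[0]
        out.append((theta[np.ix_(idx, idx)].toarray(), idx))
    return out


def make_model(
    p: int,
    n_hubs: int = 2,
    hub_degree: int = 8,
    background_edges: int = 0,
    seed: int = 0,
    hub_weight: float | None = None,
    background_weight: float = DEFAULT_BACKGROUND_WEIGHT,
    effect_size: float = 0.0,
    shifted_module: int | Sequence[int] | None = 0,
    min_eig: float = 0.05,
    rate_high: float = RATE_HIGH,
    rate_low: float = RATE_LOW,
) -> SyntheticModel:
    """Build a sparse hub-structured precision matrix with known modules.

    Each of ``n_hubs`` star blocks uses ``hub_degree`` leaves with
    off-diagonal precision weight -hub_weight (default
    0.8/sqrt(hub_degree)); ``background_edges`` random edges are placed
    among the leftover genes. Any component whose minimum eigenvalue
    falls below ``min_eig`` is diagonally loaded up to it.
    """
    if n_hubs < 0 or hub_degree < 1 or p < 1:
        raise DataError("p >= 1, n_hubs >= 0 and hub_degree >= 1 required")
    block = hub_degree + 1
    if n_hubs * block > p:
        raise DataError(
            f"n_hubs*(hub_degree+1) = {n_hubs * block} exceeds p = {p}"
        )
    if hub_weight is None:
        hub_weight = DEFAULT_HUB_WEIGHT_SCALE / math.sqrt(hub_degree)
    width = len(str(p))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(p)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    theta = sparse.lil_matrix((p, p))
    theta.setdiag(1.0)
    module_truth: dict[str, int | None] = {g: None for g in gene_ids}
    hub_truth = []
    for h in range(n_hubs):
        base = h * block
        hub_truth.append(gene_ids[base])
        for g in range(base, base + block):
            module_truth[gene_ids[g]] = h
        for leaf in range(base + 1, base + block):
            theta[base, leaf] = theta[leaf, base] = -hub_weight

    free = list(range(n_hubs * block, p))
    if background_edges:
        pairs = [(i, j) for a, i in enumerate(free) for j in free[a + 1:]]
        if background_edges > len(pairs):
            raise DataError(
                f"{background_edges} background edges requested but only "
                f"{len(pairs)} background gene pairs exist"
            )
        chosen = rng.choice(len(pairs), size=background_edges, replace=False)
        for c in chosen:
            i, j = pairs[c]
            theta[i, j] = theta[j, i] = -background_weight

    theta = theta.tocsr()
    # diagonal loading per connected component to guarantee PD
    loading = np.zeros(p)
    for block_mat, idx in _components(theta):
        lo = float(np.linalg.eigvalsh(block_mat).min())
        if lo < min_eig:
            loading[idx] = min_eig - lo
    if loading.any():
        theta = (theta + sparse.diags(loading)).tocsr()

    if shifted_module is None:
        shifted = ()
    elif isinstance(shifted_module, int):
        shifted = (shifted_module,)
    else:
        shifted = tuple(shifted_module)
    if any(m >= n_hubs for m in shifted):
        raise DataError(f"shifted modules {shifted} exceed the {n_hubs} planted modules")

    # heterogeneous per-gene shifts: genes in an affected module move up or
    # down by 0.5-1.5x the overall effect, as in real disease modules where
    # member genes are dysregulated to different extents and directions
    effect_profile: dict[str, float] = {}
    if effect_size and shifted:
        shift_genes = sorted(
            g for g in gene_ids
            if module_truth[g] is not None and module_truth[g] in shifted
        )
        signs = rng.choice([-1.0, 1.0], size=len(shift_genes))
        scales = rng.uniform(0.5, 1.5, size=len(shift_genes))
        effect_profile = {
            g: float(effect_size * sg * sc)
            for g, sg, sc in zip(shift_genes, signs, scales)
        }

    return SyntheticModel(
        precision_true=theta,
        gene_ids=gene_ids,
        module_truth=module_truth,
        hub_truth=hub_truth,
        effect_size=float(effect_size),
        shifted_modules=shifted,
        effect_profile=effect_profile,
        rate_high=rate_high,
        rate_low=rate_low,
        rng_seed=seed,
    )


def model_covariance(model: SyntheticModel) -> np.ndarray:
    """Dense covariance implied by the true precision (small p only)."""
    cov = np.zeros((model.p, model.p))
    for block, idx in _components(model.precision_true):
        cov[np.ix_(idx, idx)] = np.linalg.inv(block)
    return cov


def sample_expression(
    model: SyntheticModel,
    n_per_class: int,
    seed: int | None = None,
    censor_max_days: int = 3650,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], dict[str, str]]:
    """Draw a two-class cohort from the model.

    Returns the expression matrix, per-sample annotation (survival days,
    event flag, class recorded as ``subtype`` class1/class2), and the
    sample -> class mapping. Class 2 receives the model's per-gene
    signed mean shifts (in units of each gene's marginal sd) and the
    shorter, higher-rate survival.
    """
    if n_per_class < 1:
        raise DataError("n_per_class must be >= 1")
    if seed is None:
        seed = model.rng_seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD47A]))
    n = 2 * n_per_class
    x = np.empty((model.p, n))
    # sample componentwise: the covariance is block diagonal over the
    # support's connected components, so each block is a small dense MVN
    for block, idx in _components(model.precision_true):
        cov = np.linalg.inv(block)
        chol = np.linalg.cholesky((cov + cov.T) / 2.0)
        x[idx, :] = chol @ rng.standard_normal((len(idx), n))

    classes = ["class1"] * n_per_class + ["class2"] * n_per_class
    if model.effect_profile:
        gidx = {g: i for i, g in enumerate(model.gene_ids)}
        for g, shift in model.effect_profile.items():
            i = gidx[g]
            sd_i = math.sqrt(_marginal_variance(model, i))
            x[i, n_per_class:] += shift * sd_i

    width = len(str(n))
    sample_ids = [f"s{j + 1:0{width}d}" for j in range(n)]
    mat = ExpressionMatrix(list(model.gene_ids), sample_ids, x)

    ann = []
    for j, (sid, cls) in enumerate(zip(sample_ids, classes)):
        rate = model.rate_low if cls == "class1" else model.rate_high
        t = rng.exponential(1.0 / rate)
        c = rng.uniform(0, censor_max_days)
        days = max(1, int(round(min(t, c))))
        ann.append(
            SampleAnnotation(sample_id=sid, survival_days=days, event=bool(t <= c), subtype=cls)
        )
    labels = dict(zip(sample_ids, classes))
    return mat, ann, labels


def _marginal_variance(model: SyntheticModel, i: int) -> float:
    for block, idx in _components(model.precision_true):
        pos = np.where(idx == i)[0]
        if pos.size:
            return float(np.linalg.inv(block)[pos[0], pos[0]])
    raise DataError(f"gene index {i} not found")  # pragma: no cover


def write_truth(model: SyntheticModel, path: str | Path) -> None:
    """Write the ground-truth table (gene, module, is_hub) as TSV."""
    with open(path, "w") as fh:
        fh.write("gene\tmodule\tis_hub\n")
        for g in model.gene_ids:
            m = model.module_truth[g]
            fh.write(f"{g}\t{'' if m is None else m}\t{int(g in model.hub_truth)}\n")
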