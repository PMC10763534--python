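"""PCA of regional gene co-expression.

The region x gene map is decomposed with genes as variables and regions as
observations, so the component *scores* are per-region values - the
length-N_region vectors that are correlated with centrality contrasts
downstream.  Gene columns are z-scored first (correlation-matrix PCA) because
microarray expression scales vary wildly between genes; centering-only is
available via ``scale="center"``.

PCA signs are arbitrary, so a deterministic orientation is imposed: PC-1 is
flipped, if needed, so that its region scores correlate non-negatively with
the map's per-region mean expression; higher components orient their largest
absolute gene loading positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import GeneMapError, ShapeMismatchError
from .io import GeneExpressionMap, RegionTable

logger = logging.getLogger("dfcgene")

DEFAULT_N_COMPONENTS = 5


def standardize_map(gmap: GeneExpressionMap, scale: str = "zscore") -> GeneExpressionMap:
    """Z-score (or merely center) each gene column across regions.

    Zero-variance genes cannot be z-scored and are dropped with a warning.
    Uses the sample standard deviation (ddof=1); the operation is idempotent.
    """
    if scale not in ("zscore", "center"):
        raise ShapeMismatchError(f"unknown scale mode {scale!r}")
    X = gmap.values
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(gmap.gene_symbols, keep) if not k]
        logger.warning("dropping %d zero-variance gene(s): %s", len(dropped), dropped)
    X = X[:, keep]
    Xc = X - X.mean(axis=0)
    if scale == "zscore":
        Xc = Xc / X.std(axis=0, ddof=1)
    return GeneExpressionMap(
        values=Xc,
        gene_symbols=tuple(g for g, k in zip(gmap.gene_symbols, keep) if k),
        region_table=gmap.region_table,
    )


@dataclass
class PCAResult:
    """Scores, loadings and variance fractions of a gene-map decomposition.

    ``region_scores`` and ``gene_loadings`` hold the first k components;
    ``variance_fraction`` always covers the full spectrum (non-increasing,
    summing to 1), so cumulative variance is available past k.
    """

    region_scores: np.ndarray
    gene_loadings: np.ndarray
    variance_fraction: np.ndarray
    region_table: RegionTable
    gene_symbols: tuple

    def __post_init__(self):
        self.region_scores = np.asarray(self.region_scores, dtype=float)
        self.gene_loadings = np.asarray(self.gene_loadings, dtype=float)
        self.variance_fraction = np.asarray(self.variance_fraction, dtype=float)
        if self.region_scores.shape[0] != self.region_table.n_regions:
            raise ShapeMismatchError("score rows != region count")
        if self.region_scores.shape[1] != self.gene_loadings.shape[1]:
            raise ShapeMismatchError("scores and loadings disagree on component count")
        if np.any(np.diff(self.variance_fraction) > 1e-12):
            raise ShapeMismatchError("variance fractions must be non-increasing")

    @property
    def k(self) -> int:
        return self.region_scores.shape[1]

    @property
    def pc1_scores(self) -> np.ndarray:
        """Per-region first-principal-component scores used downstream."""
        return self.region_scores[:, 0]


def pca_region_scores(gmap: GeneExpressionMap, k: int = DEFAULT_N_COMPONENTS) -> PCAResult:
    """Decompose a (standardized) region x gene map into k components.

    ``k`` beyond the matrix rank is truncated at the rank with a warning.
    The standardized map is reconstructed exactly by
    ``region_scores @ gene_loadings.T`` at full rank.
    """
    if k < 1:
        raise ShapeMismatchError("k must be >= 1")
    X = gmap.values
    max_k = min(X.shape)
    if k > max_k:
        logger.warning("k=%d exceeds min(N_region, N_gene)=%d; truncating", k, max_k)
        k = max_k
    col_means = X.mean(axis=0)
    if np.max(np.abs(col_means)) > 1e-6 * max(1.0, np.max(np.abs(X))):
        logger.warning(
            "gene map does not look standardized (max |column mean| %.3g); "
            "pass it through standardize_map first",
            np.max(np.abs(col_means)),
        )
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x components
    var_frac = pca.explained_variance_ratio_

    rank = int(np.sum(var_frac > 1e-12))
    if k > rank:
        logger.warning("k=%d exceeds matrix rank %d; truncating", k, rank)
        k = max(rank, 1)

    # deterministic orientation
    mean_expr = X.mean(axis=1)
    c = float(np.dot(scores[:, 0] - scores[:, 0].mean(), mean_expr - mean_expr.mean()))
    if c < 0:
        scores[:, 0] *= -1
        loadings[:, 0] *= -1
    for j in range(1, scores.shape[1]):
        jmax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[jmax, j] < 0:
            scores[:, j] *= -1
            loadings[:, j] *= -1

    return PCAResult(
        region_scores=scores[:, :k],
        gene_loadings=loadings[:, :k],
        variance_fraction=var_frac,
        region_table=gmap.region_table,
        gene_symbols=gmap.gene_symbols,
    )


def variance_explained(res: PCAResult, n_components: int) -> float:
    """Total variance fraction captured by the first ``n_components``."""
    if not 1 <= n_components <= len(res.variance_fraction):
        raise ShapeMismatchError(
            f"n_components must be in [1, {len(res.variance_fraction)}]"
        )
    return float(res.variance_fraction[:n_components].sum())


def rank_regions(res: PCAResult, top_fraction: float = 0.1):
    """Top and bottom regions by signed PC-1 score.

    Returns ``(positive, negative)``: ordered :class:`RegionTable` subsets of
    the ``ceil(top_fraction * N_region)`` highest- and lowest-scoring regions
    (each list ordered from most extreme inward).  Ties break by region_id.
    """
    if not 0 < top_fraction <= 0.5:
        raise ShapeMismatchError("top_fraction must be in (0, 0.5]")
    scores = res.pc1_scores
    ids = np.asarray(res.region_table.region_ids)
    n_top = math.ceil(top_fraction * len(scores))
    desc = np.lexsort((ids, -scores))  # primary: score descending; tie: id ascending
    asc = np.lexsort((ids, scores))
    pos = res.region_table.subset(desc[:n_top])
    neg = res.region_table.subset(asc[:n_top])
    return pos, neg
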