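"""Group contrasts of centrality profiles and their correlation with PC-1.

A contrast between two clinical groups is the difference of their per-region
centrality vectors after z-scoring each across regions (default), making the
contrast unit-free and antisymmetric in the group order.  The contrast is
then Pearson-correlated with the per-region first-principal-component scores
of a gene co-expression map; the analytic two-sided p-value uses the
t-distribution with n - 2 degrees of freedom.  Because brain regions are
spatially autocorrelated the analytic df is optimistic; a simple
region-permutation p-value is available as a check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import CentralityProfile
from .exceptions import FingerprintMismatchError, ShapeMismatchError, ZeroVarianceRegionError
from .gene_pca import PCAResult

logger = logging.getLogger("dfcgene")

GROUP_PAIRS = (("AD", "MCI"), ("AD", "HC"), ("MCI", "HC"))
CONTRAST_MODES = ("zdiff", "diffz")


def _zscore(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceRegionError([], context=f"cannot z-score constant {what}")
    return (x - x.mean()) / sd


@dataclass
class ContrastVector:
    """Per-region z-scored group difference for one centrality metric."""

    values: np.ndarray
    pair: tuple
    metric: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ShapeMismatchError("contrast contains non-finite values")


@dataclass
class AssociationResult:
    """One cell of the association table: r, p and its provenance."""

    r: float
    p: float
    n: int
    pair: tuple
    metric: str
    gene_set: str
    stars: str = ""
    note: str = ""

    @property
    def valid(self) -> bool:
        return np.isfinite(self.r)


def significance_stars(p: float) -> str:
    """Star binning used in the association table."""
    if not np.isfinite(p):
        return ""
    if p < 1e-5:
        return "****"
    if p < 1e-4:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_contrast(
    a: CentralityProfile, b: CentralityProfile, mode: str = "zdiff"
) -> ContrastVector:
    """Contrast two group-level profiles of the same metric.

    ``mode="zdiff"`` (default) z-scores each group's regional vector across
    regions and subtracts, ``z(a) - z(b)``; ``mode="diffz"`` z-scores the raw
    difference instead.
    """
    if mode not in CONTRAST_MODES:
        raise ShapeMismatchError(f"unknown contrast mode {mode!r}")
    for p in (a, b):
        if p.level != "group":
            raise ShapeMismatchError("contrast requires group-level profiles")
    if a.metric != b.metric:
        raise ShapeMismatchError("profiles mix centrality metrics")
    if a.region_table.fingerprint != b.region_table.fingerprint:
        raise FingerprintMismatchError("profiles carry different region orders")
    if mode == "zdiff":
        values = _zscore(a.values, "profile") - _zscore(b.values, "profile")
    else:
        values = _zscore(a.values - b.values, "profile difference")
    return ContrastVector(
        values=values, pair=(a.group_label, b.group_label), metric=a.metric
    )


def correlate_contrast_with_pc(
    contrast: ContrastVector,
    pc_scores: np.ndarray,
    gene_set: str = "",
    permutations: int = 0,
    seed: int | None = None,
) -> AssociationResult:
    """Pearson correlation between a contrast and z-scored PC-1 scores.

    With ``permutations > 0`` an additional region-permutation p-value is
    computed and logged (the analytic value is always the one reported, as
    in the table layout this mirrors).
    """
    x = np.asarray(contrast.values, dtype=float)
    y = np.asarray(pc_scores, dtype=float)
    if x.shape != y.shape:
        raise ShapeMismatchError("contrast and PC score lengths differ")
    n = len(x)
    if n < 4:
        raise ShapeMismatchError("need at least 4 regions for a correlation test")
    xz = _zscore(x, "contrast")
    yz = _zscore(y, "PC scores")
    r, p = stats.pearsonr(xz, yz)
    note = ""
    if permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            rp = stats.pearsonr(xz, rng.permutation(yz))[0]
            if abs(rp) >= abs(r):
                count += 1
        p_perm = (count + 1) / (permutations + 1)
        note = f"p_perm={p_perm:.4g} ({permutations} permutations)"
        logger.info(
            "%s %s %s: r=%.3f p=%.3g %s",
            contrast.pair,
            contrast.metric,
            gene_set,
            r,
            p,
            note,
        )
    return AssociationResult(
        r=float(r),
        p=float(p),
        n=n,
        pair=contrast.pair,
        metric=contrast.metric,
        gene_set=gene_set,
        stars=significance_stars(p),
        note=note,
    )


def association_table(
    group_profiles: dict,
    pca_results: dict,
    mode: str = "zdiff",
) -> list[AssociationResult]:
    """All group-pair x metric x gene-set correlations.

    Parameters
    ----------
    group_profiles : dict
        ``{(group_label, metric): CentralityProfile}`` with the three groups
        HC/MCI/AD and both metrics present.
    pca_results : dict
        ``{gene_set_label: PCAResult}`` with at least one gene set.

    Three group pairs x two metrics give 6 rows per gene set.  Cells whose
    contrast has zero variance are flagged (r and p set to NaN) rather than
    dropped, so the table shape is stable.
    """
    metrics = sorted({m for (_, m) in group_profiles})
    groups = {g for (g, _) in group_profiles}
    for pair in GROUP_PAIRS:
        for g in pair:
            if g not in groups:
                raise ShapeMismatchError(f"missing group {g!r} in profiles")
    if not pca_results:
        raise ShapeMismatchError("need at least one gene set PCA result")
    results = []
    for gene_set, res in pca_results.items():
        if not isinstance(res, PCAResult):
            raise ShapeMismatchError(f"{gene_set}: expected a PCAResult")
        for metric in metrics:
            for pair in GROUP_PAIRS:
                a = group_profiles[(pair[0], metric)]
                b = group_profiles[(pair[1], metric)]
                try:
                    contrast = group_contrast(a, b, mode=mode)
                    results.append(
                        correlate_contrast_with_pc(
                            contrast, res.pc1_scores, gene_set=gene_set
                        )
                    )
                except ZeroVarianceRegionError as err:
                    logger.warning("%s %s %s: %s", pair, metric, gene_set, err)
                    results.append(
                        AssociationResult(
                            r=float("nan"),
                            p=float("nan"),
                            n=a.region_table.n_regions,
                            pair=pair,
                            metric=metric,
                            gene_set=gene_set,
                            note="zero-variance contrast",
                        )
                    )
    return results


def association_dataframe(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy frame of the association table (one row per cell)."""
    return pd.DataFrame(
        {
            "pair": ["/".join(r.pair) for r in results],
            "metric": [r.metric for r in results],
            "gene_set": [r.gene_set for r in results],
            "r": [r.r for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
            "stars": [r.stars for r in results],
            "note": [r.note for r in results],
        }
    )
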