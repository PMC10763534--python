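"""Node strength and eigenvector centrality of weighted functional networks.

Node strength of node i is the sum of its retained link weights,
``kappa(i) = sum_j rho(i, j)`` (diagonal excluded; masked links contribute 0).
Eigenvector centrality is the principal eigenvector of the weight matrix:
the unit vector e with ``W e = lambda e`` for the largest *algebraic*
eigenvalue lambda.  Networks carry positive and negative weights, so
Perron-Frobenius positivity of e is not guaranteed; determinism comes from a
sign convention (sum of entries >= 0) and a fixed internal starting vector.
The eigenpair is computed by shifted power iteration; a dense eigensolver
serves as an independent oracle in the test suite, never here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    AllZeroNetworkError,
    DegenerateSpectrumError,
    FingerprintMismatchError,
    PowerIterationError,
    ShapeMismatchError,
)
from .io import RegionTable
from .networks import DynamicNetworkStack, FunctionalNetwork

logger = logging.getLogger("dfcgene")

METRICS = ("strength", "eigenvector")

# fixed pseudo-random start so power iteration is deterministic yet almost
# surely non-orthogonal to the principal eigenvector
_START_SEED = 20231203


@dataclass
class EigencentralityResult:
    """Principal eigenpair: unit-norm scores and the largest eigenvalue."""

    scores: np.ndarray
    eigenvalue: float

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if abs(np.linalg.norm(self.scores) - 1.0) > 1e-8:
            raise ShapeMismatchError("eigenvector centrality scores must have unit norm")


@dataclass
class CentralityProfile:
    """Per-region centrality vector at window, subject or group level."""

    metric: str
    values: np.ndarray
    level: str
    region_table: RegionTable
    group_label: str | None = None
    subject_id: str | None = None

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ShapeMismatchError(f"metric must be one of {METRICS}")
        if self.level not in ("window", "subject", "group"):
            raise ShapeMismatchError("level must be window, subject or group")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.region_table.n_regions,):
            raise ShapeMismatchError("profile length != region count")
        if not np.all(np.isfinite(self.values)):
            raise ShapeMismatchError("profile contains non-finite values")


def node_strength(net: FunctionalNetwork) -> np.ndarray:
    """Sum of retained link weights per node (masked links contribute 0)."""
    return net.weights.sum(axis=1)


def _sign_fix(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    if s < 0:
        return -v
    if s == 0:
        nz = np.nonzero(v)[0]
        if len(nz) and v[nz[0]] < 0:
            return -v
    return v


def _power_iteration(A: np.ndarray, v0: np.ndarray, tol: float, max_iter: int):
    """Power iteration on a symmetric PSD (shifted) matrix.

    Returns ``(lam, v, resid, converged)`` where ``lam`` is the final
    Rayleigh quotient and ``resid = ||A v - lam v||``.  The Rayleigh quotient
    of a symmetric matrix never exceeds its largest eigenvalue, which the
    degeneracy check below relies on.
    """
    v = v0 / np.linalg.norm(v0)
    lam, resid = 0.0, np.inf
    for _ in range(max_iter):
        w = A @ v
        lam = float(v @ w)
        resid = float(np.linalg.norm(w - lam * v))
        if resid <= tol:
            return lam, v, resid, True
        nw = np.linalg.norm(w)
        if nw == 0:
            raise PowerIterationError("iterate annihilated; matrix effectively zero")
        v = w / nw
    return lam, v, resid, False


def eigenvector_centrality(
    net: FunctionalNetwork,
    tol: float = 1e-12,
    max_iter: int = 200_000,
    gap_tol: float = 1e-9,
    check_gap: bool = True,
) -> EigencentralityResult:
    """Principal eigenpair of the (signed) weight matrix by power iteration.

    The matrix is shifted by its Frobenius norm so the largest algebraic
    eigenvalue of W becomes the dominant eigenvalue of W + sI.  With
    ``check_gap`` (default), a deflated second iteration estimates the gap to
    the next eigenvalue and a tie raises :class:`DegenerateSpectrumError`.
    """
    W = net.weights
    if not np.any(W):
        raise AllZeroNetworkError("all links masked; no principal direction")
    n = W.shape[0]
    fro = np.linalg.norm(W)
    shift = fro  # Frobenius norm bounds the spectral radius
    A = W + shift * np.eye(n)
    rng = np.random.default_rng(_START_SEED)
    v0 = rng.standard_normal(n)
    scale = max(fro, 1.0)
    lam_A, v, resid, ok = _power_iteration(
        A, v0, tol=max(tol * scale, 1e-15), max_iter=max_iter
    )
    if not ok:
        raise PowerIterationError(
            f"residual {resid:.2e} after {max_iter} iterations "
            "(near-degenerate leading eigenpair?)"
        )
    lam = lam_A - shift
    if check_gap:
        # Deflate the leading pair and take the Rayleigh quotient of the
        # remainder.  It lower-bounds the second eigenvalue, so the estimated
        # gap only ever overestimates: an exact tie is caught immediately,
        # while an unconverged estimate never raises spuriously.
        B = A - lam_A * np.outer(v, v)
        try:
            lam2_A, _, _, _ = _power_iteration(
                B, rng.standard_normal(n), tol=1e-9 * scale, max_iter=1000
            )
        except PowerIterationError:
            lam2_A = 0.0  # deflated matrix annihilates: remaining spectrum is 0
        gap = lam_A - lam2_A
        if gap < gap_tol * scale:
            raise DegenerateSpectrumError(gap)
    v = _sign_fix(v / np.linalg.norm(v))
    return EigencentralityResult(scores=v, eigenvalue=lam)


def _window_metric(net: FunctionalNetwork, metric: str) -> np.ndarray:
    if metric == "strength":
        return node_strength(net)
    return eigenvector_centrality(net).scores


def window_average(stack: DynamicNetworkStack, metric: str) -> CentralityProfile:
    """Arithmetic mean of the per-window metric vectors for one subject.

    Windows where the metric is undefined (all links masked, degenerate
    spectrum) are skipped with a warning; if every window fails the error is
    raised.
    """
    if metric not in METRICS:
        raise ShapeMismatchError(f"metric must be one of {METRICS}")
    if stack.n_windows == 0:
        raise ShapeMismatchError("empty window stack")
    vals = []
    for win, net in zip(stack.windows, stack.networks):
        try:
            vals.append(_window_metric(net, metric))
        except (AllZeroNetworkError, DegenerateSpectrumError, PowerIterationError) as err:
            logger.warning(
                "subject %s window %d: %s metric skipped (%s)",
                stack.subject_id,
                win.m,
                metric,
                err,
            )
    if not vals:
        raise AllZeroNetworkError(
            f"subject {stack.subject_id}: {metric} undefined in every window"
        )
    table = stack.reference.region_table
    if table is None:
        table = RegionTable.synthetic(stack.reference.n_nodes)
    return CentralityProfile(
        metric=metric,
        values=np.mean(vals, axis=0),
        level="subject",
        region_table=table,
        group_label=stack.group_label or None,
        subject_id=stack.subject_id or None,
    )


def group_average(profiles: list[CentralityProfile]) -> CentralityProfile:
    """Per-region mean of subject-level profiles -> one group-level profile."""
    if not profiles:
        raise ShapeMismatchError("cannot average an empty list of profiles")
    first = profiles[0]
    for p in profiles[1:]:
        if p.metric != first.metric:
            raise ShapeMismatchError("profiles mix centrality metrics")
        if p.region_table.fingerprint != first.region_table.fingerprint:
            raise FingerprintMismatchError(
                "profiles carry different region-order fingerprints"
            )
    values = np.mean([p.values for p in profiles], axis=0)
    labels = {p.group_label for p in profiles}
    label = labels.pop() if len(labels) == 1 else None
    return CentralityProfile(
        metric=first.metric,
        values=values,
        level="group",
        region_table=first.region_table,
        group_label=label,
    )
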