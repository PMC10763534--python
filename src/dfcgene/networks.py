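"""Static and sliding-window (dynamic) functional networks.

A functional network is the matrix of pairwise Pearson correlations between
regional BOLD signals, thresholded at a significance level alpha (two-sided
t-test on r, df = N_T - 2).  Dynamic networks recompute the correlations in
half-overlapping windows of ``delta_t`` samples and apply a dual rule: a
window link survives only if (a) it is retained in the subject's full-signal
reference network and (b) its window correlation magnitude is at least the
reference magnitude.  Rule (b) keeps, per window, the links that transiently
strengthen relative to the stationary picture - the fluctuating backbone the
dFC analysis is about.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ShapeMismatchError, ZeroVarianceRegionError
from .io import RegionalTimeSeriesSet, RegionTable

logger = logging.getLogger("dfcgene")

DEFAULT_WINDOW_LENGTH = 20
DEFAULT_ALPHA = 0.01
#: repetition time of the emulated acquisition protocol, seconds
DEFAULT_TR_SECONDS = 3.0


@dataclass(frozen=True)
class WindowSpec:
    """One half-overlapping sliding window: start t_m = m * delta_t / 2."""

    m: int
    start: int
    length: int

    def __post_init__(self):
        if self.length < 2 or self.length % 2:
            raise ShapeMismatchError("window length must be an even integer >= 2")
        if self.start != self.m * self.length // 2:
            raise ShapeMismatchError("window start must equal m * delta_t / 2")

    @property
    def stop(self) -> int:
        return self.start + self.length


def sliding_windows(n_timepoints: int, delta_t: int) -> list[WindowSpec]:
    """Enumerate half-overlapping windows that fit entirely in the signal.

    Window m starts at ``m * delta_t / 2``; the last window is the largest m
    with ``start + delta_t <= n_timepoints``, so trailing samples that do not
    fill a window are never covered.  For 197 timepoints and ``delta_t=20``
    this yields 18 windows starting at 0, 10, ..., 170.
    """
    delta_t = int(delta_t)
    n_timepoints = int(n_timepoints)
    if delta_t % 2:
        raise ShapeMismatchError(f"delta_t must be even, got {delta_t}")
    if delta_t < 2 or delta_t > n_timepoints:
        raise ShapeMismatchError(
            f"need 2 <= delta_t <= n_timepoints, got delta_t={delta_t}, "
            f"n_timepoints={n_timepoints}"
        )
    half = delta_t // 2
    n_windows = (n_timepoints - delta_t) // half + 1
    return [WindowSpec(m=m, start=m * half, length=delta_t) for m in range(n_windows)]


def window_duration_minutes(delta_t: int, tr_seconds: float = DEFAULT_TR_SECONDS) -> float:
    """Window length in minutes of scan time (delta_t samples at one TR each)."""
    return delta_t * tr_seconds / 60.0


def correlation_pvalues(r: np.ndarray, n_samples: int) -> np.ndarray:
    """Two-sided p-values for Pearson r via the t-transform, df = n - 2."""
    df = n_samples - 2
    if df < 1:
        raise ShapeMismatchError("need at least 3 samples for a correlation test")
    rc = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rc * np.sqrt(df / (1.0 - rc**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(rc) >= 1.0, 0.0, p)
    return p


def critical_correlation(alpha: float, n_samples: int) -> float:
    """Smallest |r| retained at significance level alpha (bisection on p)."""
    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if correlation_pvalues(np.array(mid), n_samples) < alpha:
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class FunctionalNetwork:
    """Significance-thresholded correlation network for one subject/window.

    ``weights`` holds Pearson r on retained links and exactly 0 elsewhere;
    ``mask`` marks retained links.  The diagonal is always excluded.
    """

    weights: np.ndarray
    mask: np.ndarray
    alpha: float
    region_table: RegionTable | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        w, m = self.weights, self.mask
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape != m.shape:
            raise ShapeMismatchError("weights/mask must be square and congruent")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ShapeMismatchError("weights must be symmetric")
        if np.any(np.abs(w) > 1 + 1e-12):
            raise ShapeMismatchError("correlation weights must lie in [-1, 1]")
        if np.any(np.diag(m)) or np.any(np.diag(w) != 0):
            raise ShapeMismatchError("diagonal must be excluded (mask False, weight 0)")
        if np.any(w[~m] != 0):
            raise ShapeMismatchError("masked-out entries must be stored as 0")
        if not (0 < self.alpha < 1):
            raise ShapeMismatchError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def retained_fraction(self) -> float:
        """Fraction of off-diagonal (unordered) links retained."""
        n = self.n_nodes
        iu = np.triu_indices(n, k=1)
        return float(self.mask[iu].mean())


def _pearson_matrix(data: np.ndarray) -> np.ndarray:
    r = np.corrcoef(data)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return 0.5 * (r + r.T)


def static_network(
    ts: RegionalTimeSeriesSet, alpha: float = DEFAULT_ALPHA
) -> FunctionalNetwork:
    """Full-signal Pearson network with the significance mask.

    Links whose two-sided p-value is >= alpha are removed (weights set to 0);
    the network is weighted with both positive and negative correlations.
    """
    if not (0 < alpha < 1):
        raise ShapeMismatchError(f"alpha must be in (0, 1), got {alpha}")
    zv = np.where(np.ptp(ts.data, axis=1) == 0)[0]
    if len(zv):
        raise ZeroVarianceRegionError(
            [ts.region_table.region_ids[i] for i in zv],
            context=f"subject {ts.subject_id}",
        )
    r = _pearson_matrix(ts.data)
    p = correlation_pvalues(r, ts.n_timepoints)
    mask = p < alpha
    np.fill_diagonal(mask, False)
    weights = np.where(mask, r, 0.0)
    return FunctionalNetwork(weights, mask, alpha, ts.region_table)


@dataclass
class DynamicNetworkStack:
    """Ordered windowed networks for one subject plus discard bookkeeping.

    ``discarded_fraction`` counts reference-retained candidate links that
    failed the window rule, over all off-diagonal link-window slots.
    """

    windows: list
    networks: list
    reference: FunctionalNetwork
    discarded_fraction: float
    subject_id: str = ""
    group_label: str = ""

    def __post_init__(self):
        if len(self.windows) != len(self.networks):
            raise ShapeMismatchError("one network per window required")
        n = self.reference.n_nodes
        for net in self.networks:
            if net.n_nodes != n:
                raise ShapeMismatchError("all windows must share the node count")
        if not 0 <= self.discarded_fraction <= 1:
            raise ShapeMismatchError("discarded_fraction must be in [0, 1]")

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def dynamic_networks(
    ts: RegionalTimeSeriesSet,
    delta_t: int,
    reference: FunctionalNetwork,
    threshold_mode: str = "abs",
) -> DynamicNetworkStack:
    """Sliding-window networks thresholded against the full-signal reference.

    Per window, a link (i, j) is retained iff it is retained in ``reference``
    and its window correlation is at least the reference correlation -
    compared in absolute value by default (``threshold_mode="abs"``), or as
    signed values with ``threshold_mode="signed"``.  A region whose signal is
    constant within a window has its links zeroed for that window (logged,
    not fatal).
    """
    if threshold_mode not in ("abs", "signed"):
        raise ShapeMismatchError(f"unknown threshold_mode {threshold_mode!r}")
    if reference.n_nodes != ts.n_regions:
        raise ShapeMismatchError("reference network node count != region count")
    windows = sliding_windows(ts.n_timepoints, delta_t)
    n = ts.n_regions
    iu = np.triu_indices(n, k=1)
    nets = []
    discarded = 0
    for win in windows:
        seg = ts.data[:, win.start : win.stop]
        zv = np.where(np.ptp(seg, axis=1) == 0)[0]
        valid = np.ones(n, dtype=bool)
        if len(zv):
            valid[zv] = False
            logger.warning(
                "subject %s window %d: zero-variance segment in regions %s; "
                "their links set to 0 for this window",
                ts.subject_id,
                win.m,
                [ts.region_table.region_ids[i] for i in zv],
            )
        r = np.zeros((n, n))
        if valid.sum() >= 2:
            sub = _pearson_matrix(seg[valid])
            r[np.ix_(valid, valid)] = sub
        if threshold_mode == "abs":
            keep_b = np.abs(r) >= np.abs(reference.weights)
        else:
            keep_b = r >= reference.weights
        mask = reference.mask & keep_b & np.outer(valid, valid)
        np.fill_diagonal(mask, False)
        discarded += int(reference.mask[iu].sum() - mask[iu].sum())
        nets.append(
            FunctionalNetwork(np.where(mask, r, 0.0), mask, reference.alpha, ts.region_table)
        )
    total_slots = len(windows) * len(iu[0])
    frac = discarded / total_slots if total_slots else 0.0
    return DynamicNetworkStack(
        windows=windows,
        networks=nets,
        reference=reference,
        discarded_fraction=frac,
        subject_id=ts.subject_id,
        group_label=ts.group_label,
    )
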