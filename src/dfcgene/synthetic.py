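"""Synthetic cohorts with planted, recoverable structure.

The generator stands in for the two real data sources the analysis was
designed for - resting-state BOLD time series of three clinical cohorts and
a regional gene-expression map - while keeping a known ground truth:

* **BOLD**: each subject's regional signal is drawn from a latent two-state
  symmetric Markov chain.  State 0 uses the group's base covariance; state 1
  adds a planted perturbation built from the group's contrast profile ``c``
  (pairwise covariance boost ``c_i * c_j`` with the diagonal left untouched,
  so variances are unchanged and the planted group difference sits exactly
  on the regions where ``c`` is non-zero).  Innovations are Gaussian and
  serially independent within a state; the switching produces the
  window-to-window correlation fluctuation the sliding-window analysis is
  about.
* **Genes**: each gene column is a positive multiple of a per-region loading
  vector plus independent Gaussian noise, i.e. a rank-1 map plus noise whose
  first principal component recovers the loading.  Tying the loading to the
  planted contrast profile makes the full pipeline's contrast-PC correlation
  positive by construction.

All randomness flows from one explicit seed (numpy ``SeedSequence``); there
is no global random state, and identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    NonPositiveSemidefiniteError,
    ShapeMismatchError,
    ZeroNormLoadingError,
)
from .io import (
    GROUP_LABELS,
    GeneExpressionMap,
    RegionalTimeSeriesSet,
    RegionTable,
    write_gene_map,
    write_region_table,
    write_timeseries,
)

logger = logging.getLogger("dfcgene")

# Defaults emulating the study conditions: 197 timepoints per scan,
# 30 subjects per group for the recovery experiments, equicorrelated
# baseline connectivity and ~4 covariance-state switches per scan.
DEFAULT_N_TIMEPOINTS = 197
DEFAULT_N_SUBJECTS = 30
DEFAULT_BASE_CORRELATION = 0.15
DEFAULT_SWITCHING_RATE = 4.0
DEFAULT_CONTRAST_AMPLITUDE = 0.7
DEFAULT_N_TARGETS = 10
DEFAULT_GENE_NOISE_SD = 0.1
GROUP_CONTRAST_SCALE = {"HC": 0.0, "MCI": 0.5, "AD": 1.0}


@dataclass
class GroupSpec:
    """Generation parameters for one cohort.

    ``contrast_profile`` is the per-region vector c that defines the planted
    perturbation of the second covariance state; ``switching_rate`` is the
    expected number of state switches per scan.
    """

    group_label: str
    n_subjects: int
    base_covariance: np.ndarray
    contrast_profile: np.ndarray
    switching_rate: float = DEFAULT_SWITCHING_RATE

    def __post_init__(self):
        if self.group_label not in GROUP_LABELS:
            raise ShapeMismatchError(f"group_label must be one of {GROUP_LABELS}")
        if self.n_subjects < 1:
            raise ShapeMismatchError("n_subjects must be >= 1")
        if self.switching_rate < 0:
            raise ShapeMismatchError("switching_rate must be >= 0")
        self.base_covariance = np.asarray(self.base_covariance, dtype=float)
        self.contrast_profile = np.asarray(self.contrast_profile, dtype=float)
        S = self.base_covariance
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ShapeMismatchError("base_covariance must be square")
        if not np.allclose(S, S.T, atol=1e-12):
            raise ShapeMismatchError("base_covariance must be symmetric")
        wmin = float(np.linalg.eigvalsh(S)[0])
        if wmin < -1e-10 * max(1.0, float(np.abs(S).max())):
            raise NonPositiveSemidefiniteError(wmin, context="base_covariance")
        if self.contrast_profile.shape != (S.shape[0],):
            raise ShapeMismatchError("contrast_profile length != covariance dimension")

    @property
    def n_regions(self) -> int:
        return self.base_covariance.shape[0]


@dataclass
class SyntheticTruth:
    """Planted vectors stored alongside every generated dataset."""

    planted_contrast: np.ndarray
    planted_gene_loading: np.ndarray
    seed: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        self.planted_contrast = np.asarray(self.planted_contrast, dtype=float)
        self.planted_gene_loading = np.asarray(self.planted_gene_loading, dtype=float)
        if self.planted_contrast.shape != self.planted_gene_loading.shape:
            raise ShapeMismatchError("planted vectors must have equal length")

    def to_dict(self) -> dict:
        return {
            "planted_contrast": self.planted_contrast.tolist(),
            "planted_gene_loading": self.planted_gene_loading.tolist(),
            "seed": int(self.seed),
            "parameters": self.parameters,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            planted_contrast=np.array(d["planted_contrast"], dtype=float),
            planted_gene_loading=np.array(d["planted_gene_loading"], dtype=float),
            seed=int(d["seed"]),
            parameters=d.get("parameters", {}),
        )


def contrast_perturbation(contrast_profile: np.ndarray) -> np.ndarray:
    """Covariance perturbation planted by a contrast profile c.

    Off-diagonal entries gain ``c_i * c_j``; the diagonal is left at zero so
    regional variances are unchanged and correlations shift directly.
    """
    c = np.asarray(contrast_profile, dtype=float)
    P = np.outer(c, c)
    np.fill_diagonal(P, 0.0)
    return P


def state_covariances(spec: GroupSpec) -> tuple[np.ndarray, np.ndarray]:
    """The two covariance states (base, base + planted perturbation).

    Raises :class:`NonPositiveSemidefiniteError` if the perturbed state loses
    positive semidefiniteness (perturbation magnitude too large).
    """
    S0 = spec.base_covariance
    S1 = S0 + contrast_perturbation(spec.contrast_profile)
    wmin = float(np.linalg.eigvalsh(S1)[0])
    if wmin < -1e-10 * max(1.0, float(np.abs(S1).max())):
        raise NonPositiveSemidefiniteError(
            wmin, context=f"perturbed state of group {spec.group_label}"
        )
    return S0, S1


def _factor(S: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition (handles singular)."""
    w, U = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def _markov_states(n_timepoints: int, switching_rate: float, rng) -> np.ndarray:
    """Two-state symmetric chain; stationary start, switch prob per step."""
    q = min(1.0, switching_rate / max(n_timepoints - 1, 1))
    states = np.empty(n_timepoints, dtype=np.int8)
    states[0] = rng.integers(2)
    flips = rng.random(n_timepoints - 1) < q
    states[1:] = (states[0] + np.cumsum(flips)) % 2
    return states


def generate_group_bold(
    spec: GroupSpec,
    n_regions: int,
    n_timepoints: int,
    seed: int,
    region_table: RegionTable | None = None,
) -> list[RegionalTimeSeriesSet]:
    """Draw one cohort of regional BOLD matrices (one per subject).

    Each subject runs an independent latent two-state Markov chain; at every
    timepoint the regional vector is drawn from the current state's
    covariance with independent Gaussian innovations.  Deterministic for a
    fixed seed.
    """
    if spec.n_regions != n_regions:
        raise ShapeMismatchError(
            f"covariance dimension {spec.n_regions} != n_regions {n_regions}"
        )
    if n_timepoints < 2:
        raise ShapeMismatchError("need at least 2 timepoints")
    if region_table is None:
        region_table = RegionTable.synthetic(n_regions)
    S0, S1 = state_covariances(spec)
    F0, F1 = _factor(S0), _factor(S1)
    rng = np.random.default_rng(seed)
    subjects = []
    for s in range(spec.n_subjects):
        states = _markov_states(n_timepoints, spec.switching_rate, rng)
        z = rng.standard_normal((n_timepoints, n_regions))
        x0 = z @ F0.T
        x1 = z @ F1.T
        data = np.where(states[:, None] == 1, x1, x0).T
        subjects.append(
            RegionalTimeSeriesSet(
                subject_id=f"{spec.group_label}_{s:03d}",
                group_label=spec.group_label,
                data=data,
                region_table=region_table,
            )
        )
    return subjects


def generate_gene_map(
    n_regions: int,
    n_genes: int,
    loading: np.ndarray,
    noise_sd: float,
    seed: int,
    region_table: RegionTable | None = None,
    gene_prefix: str = "GENE",
) -> GeneExpressionMap:
    """Rank-1 loading-vector map plus independent Gaussian noise.

    Gene g's column is ``a_g * loading + eps`` with ``a_g ~ Uniform(0.5, 1.5)``
    (positive) and ``eps ~ N(0, noise_sd^2)`` iid.  With ``noise_sd = 0`` the
    map is exactly rank 1 and its first principal component explains all of
    the variance.
    """
    loading = np.asarray(loading, dtype=float)
    if loading.shape != (n_regions,):
        raise ShapeMismatchError("loading length != n_regions")
    if np.linalg.norm(loading) == 0:
        raise ZeroNormLoadingError("loading vector has zero norm")
    if n_genes < 2:
        raise ShapeMismatchError("n_genes must be >= 2")
    if noise_sd < 0:
        raise ShapeMismatchError("noise_sd must be >= 0")
    if region_table is None:
        region_table = RegionTable.synthetic(n_regions)
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.5, 1.5, size=n_genes)
    values = loading[:, None] * a[None, :]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=(n_regions, n_genes))
    symbols = tuple(f"{gene_prefix}{g:03d}" for g in range(1, n_genes + 1))
    return GeneExpressionMap(values=values, gene_symbols=symbols, region_table=region_table)


def default_base_covariance(
    n_regions: int, base_correlation: float = DEFAULT_BASE_CORRELATION
) -> np.ndarray:
    """Equicorrelated baseline: unit variances, common correlation r0."""
    if not 0 <= base_correlation < 1:
        raise ShapeMismatchError("base_correlation must be in [0, 1)")
    S = np.full((n_regions, n_regions), base_correlation)
    np.fill_diagonal(S, 1.0)
    return S


def default_contrast_profile(
    n_regions: int,
    n_targets: int = DEFAULT_N_TARGETS,
    amplitude: float = DEFAULT_CONTRAST_AMPLITUDE,
    target_regions: list | None = None,
) -> np.ndarray:
    """Contrast concentrated on a chosen region subset (first n by default)."""
    c = np.zeros(n_regions)
    idx = target_regions if target_regions is not None else range(min(n_targets, n_regions))
    for i in idx:
        c[i] = amplitude
    return c


@dataclass
class Cohort:
    """A full generated dataset: time series per group, gene maps, truth."""

    timeseries: dict
    gene_maps: dict
    truth: SyntheticTruth
    region_table: RegionTable

    @property
    def groups(self) -> tuple:
        return tuple(self.timeseries)


def generate_cohort(
    n_regions: int = 121,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    n_subjects=DEFAULT_N_SUBJECTS,
    groups: tuple = GROUP_LABELS,
    base_correlation: float = DEFAULT_BASE_CORRELATION,
    contrast_amplitude: float = DEFAULT_CONTRAST_AMPLITUDE,
    n_targets: int = DEFAULT_N_TARGETS,
    switching_rate: float = DEFAULT_SWITCHING_RATE,
    gene_sets: dict | None = None,
    gene_noise_sd: float = DEFAULT_GENE_NOISE_SD,
    loading_mode: str = "contrast",
    seed: int = 0,
) -> Cohort:
    """Generate the three-cohort study layout with planted structure.

    The AD group carries the full contrast profile, MCI half of it and HC
    none.  Gene maps (by default an "ADG"-like 71-gene and an "AChG"-like
    13-gene set) share one loading vector: the z-scored planted contrast
    profile when ``loading_mode="contrast"``, or an independent Gaussian
    vector when ``loading_mode="random"`` (the null configuration).
    """
    if loading_mode not in ("contrast", "random"):
        raise ShapeMismatchError(f"unknown loading_mode {loading_mode!r}")
    if gene_sets is None:
        gene_sets = {"ADG": 71, "AChG": 13}
    if isinstance(n_subjects, int):
        n_subjects = {g: n_subjects for g in groups}
    region_table = RegionTable.synthetic(n_regions)
    base = default_base_covariance(n_regions, base_correlation)
    contrast = default_contrast_profile(n_regions, n_targets, contrast_amplitude)

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(groups) + len(gene_sets) + 1)]
    timeseries = {}
    for gi, g in enumerate(groups):
        scale = GROUP_CONTRAST_SCALE.get(g, 1.0)
        spec = GroupSpec(
            group_label=g,
            n_subjects=n_subjects[g],
            base_covariance=base,
            contrast_profile=scale * contrast,
            switching_rate=switching_rate,
        )
        timeseries[g] = generate_group_bold(
            spec, n_regions, n_timepoints, seed=child_seeds[gi], region_table=region_table
        )

    if loading_mode == "contrast":
        sd = contrast.std(ddof=1)
        if sd == 0:
            # degenerate (null) contrast: fall back to an independent loading
            loading = np.random.default_rng(child_seeds[-1]).standard_normal(n_regions)
        else:
            loading = (contrast - contrast.mean()) / sd
    else:
        loading = np.random.default_rng(child_seeds[-1]).standard_normal(n_regions)

    gene_maps = {}
    for si, (name, n_genes) in enumerate(gene_sets.items()):
        gene_maps[name] = generate_gene_map(
            n_regions,
            n_genes,
            loading,
            gene_noise_sd,
            seed=child_seeds[len(groups) + si],
            region_table=region_table,
            gene_prefix=f"{name}_",
        )

    truth = SyntheticTruth(
        planted_contrast=contrast,
        planted_gene_loading=loading,
        seed=seed,
        parameters={
            "n_regions": n_regions,
            "n_timepoints": n_timepoints,
            "n_subjects": {g: int(n_subjects[g]) for g in groups},
            "base_correlation": base_correlation,
            "contrast_amplitude": contrast_amplitude,
            "n_targets": n_targets,
            "switching_rate": switching_rate,
            "gene_sets": {k: int(v) for k, v in gene_sets.items()},
            "gene_noise_sd": gene_noise_sd,
            "loading_mode": loading_mode,
        },
    )
    return Cohort(
        timeseries=timeseries, gene_maps=gene_maps, truth=truth, region_table=region_table
    )


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Serialize a cohort: <group>/<subject>.tsv, gene maps, region table, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_region_table(cohort.region_table, out / "regions.tsv")
    for group, subjects in cohort.timeseries.items():
        gdir = out / group
        gdir.mkdir(exist_ok=True)
        for ts in subjects:
            write_timeseries(ts, gdir / f"{ts.subject_id}.tsv")
    for name, gmap in cohort.gene_maps.items():
        write_gene_map(gmap, out / f"gene_map_{name}.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth.to_dict(), fh, indent=2)
        fh.write("\n")
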