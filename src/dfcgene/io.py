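"""Core containers and file formats.

Matrix orientation is fixed package-wide: regional BOLD time series are stored
regions-in-rows (``N_node x N_T``) and expression maps regions-in-rows /
genes-in-columns (``N_region x N_gene``).  Every tabular artifact written by
the package carries a ``region_fingerprint`` comment so that region ordering
can be asserted identical across the files of one run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    GeneMapError,
    GridMismatchError,
    NonNumericValueError,
    ShapeMismatchError,
    ZeroVarianceRegionError,
)

logger = logging.getLogger("dfcgene")

GROUP_LABELS = ("HC", "MCI", "AD")
HEMISPHERES = ("L", "R", "bilateral")


def _delimiter_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass(frozen=True)
class RegionTable:
    """Atlas parcel table defining node identity and matrix row order.

    ``region_ids`` are unique positive integers; their order here is the row
    order of every matrix in a run.
    """

    region_ids: tuple
    names: tuple
    hemispheres: tuple

    def __post_init__(self):
        ids = tuple(int(r) for r in self.region_ids)
        object.__setattr__(self, "region_ids", ids)
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        object.__setattr__(self, "hemispheres", tuple(str(h) for h in self.hemispheres))
        if len(set(ids)) != len(ids):
            raise ShapeMismatchError("region_ids must be unique")
        if any(r < 1 for r in ids):
            raise ShapeMismatchError("region_ids must be >= 1 (0 is background)")
        if not len(ids) == len(self.names) == len(self.hemispheres):
            raise ShapeMismatchError("region table columns have unequal lengths")
        bad = [h for h in self.hemispheres if h not in HEMISPHERES]
        if bad:
            raise ShapeMismatchError(f"unknown hemisphere labels {sorted(set(bad))}")

    def __len__(self):
        return len(self.region_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def fingerprint(self) -> str:
        """12-hex-digit digest of the ordered region identifiers."""
        payload = ",".join(str(r) for r in self.region_ids)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def subset(self, indices) -> "RegionTable":
        """Ordered subset by positional indices (used by region ranking)."""
        idx = list(indices)
        return RegionTable(
            tuple(self.region_ids[i] for i in idx),
            tuple(self.names[i] for i in idx),
            tuple(self.hemispheres[i] for i in idx),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "name": self.names,
                "hemisphere": self.hemispheres,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegionTable":
        return cls(
            tuple(df["region_id"]), tuple(df["name"]), tuple(df["hemisphere"])
        )

    @classmethod
    def synthetic(cls, n_regions: int) -> "RegionTable":
        """Placeholder parcellation for generated data (L/R alternating)."""
        ids = tuple(range(1, n_regions + 1))
        hemis = tuple("L" if i % 2 else "R" for i in range(n_regions))
        names = tuple(
            f"synthetic region {i:03d} {h}" for i, h in zip(ids, hemis)
        )
        return cls(ids, names, hemis)


def read_region_table(path) -> RegionTable:
    df = pd.read_csv(path, sep=_delimiter_for(path), comment="#")
    required = {"region_id", "name", "hemisphere"}
    if not required.issubset(df.columns):
        raise ShapeMismatchError(
            f"region table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return RegionTable.from_dataframe(df)


def write_region_table(table: RegionTable, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# region_fingerprint={table.fingerprint}\n")
        table.to_dataframe().to_csv(fh, sep=_delimiter_for(path), index=False)


@dataclass
class RegionalTimeSeriesSet:
    """One subject's regional BOLD matrix (``N_node x N_T``) plus labels."""

    subject_id: str
    group_label: str
    data: np.ndarray
    region_table: RegionTable
    zero_variance_regions: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.group_label not in GROUP_LABELS:
            raise ShapeMismatchError(
                f"group_label must be one of {GROUP_LABELS}, got {self.group_label!r}"
            )
        if self.data.ndim != 2:
            raise ShapeMismatchError("time-series data must be 2-D (regions x time)")
        if self.data.shape[0] != self.region_table.n_regions:
            raise ShapeMismatchError(
                f"{self.data.shape[0]} rows but region table has "
                f"{self.region_table.n_regions} regions"
            )
        if self.data.shape[1] < 2:
            raise ShapeMismatchError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise NonNumericValueError(
                f"subject {self.subject_id}: non-finite values in time series"
            )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def _zero_variance_rows(data: np.ndarray) -> np.ndarray:
    return np.where(np.ptp(data, axis=1) == 0)[0]


def read_timeseries(
    path,
    region_table: RegionTable,
    group_label: str,
    subject_id: str | None = None,
    zero_variance: str = "raise",
) -> RegionalTimeSeriesSet:
    """Read one subject's regions-x-timepoints matrix from TSV/CSV.

    The file must have a header row and region IDs as the first (index)
    column, in ``region_table`` order.  Constant rows break Pearson
    correlation downstream; by default they raise
    :class:`ZeroVarianceRegionError` naming the region (``zero_variance="flag"``
    records them on the returned object instead).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0, comment="#")
    if df.shape[0] != region_table.n_regions:
        raise ShapeMismatchError(
            f"{path.name}: {df.shape[0]} rows, expected {region_table.n_regions}"
        )
    file_ids = [int(i) for i in df.index]
    if file_ids != list(region_table.region_ids):
        raise ShapeMismatchError(
            f"{path.name}: region IDs do not match the region table order"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for i, row in enumerate(values):
            for cell in row:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise NonNumericValueError(
                        f"{path.name}: non-numeric cell in row {i} "
                        f"(region {region_table.region_ids[i]}): {cell!r}"
                    ) from None
        values = values.astype(float)
    zv = _zero_variance_rows(values)
    zv_ids = tuple(region_table.region_ids[i] for i in zv)
    if len(zv) and zero_variance == "raise":
        raise ZeroVarianceRegionError(zv_ids, context=path.name)
    if len(zv):
        logger.warning("%s: zero-variance regions flagged: %s", path.name, zv_ids)
    return RegionalTimeSeriesSet(
        subject_id=subject_id or path.stem,
        group_label=group_label,
        data=values,
        region_table=region_table,
        zero_variance_regions=zv_ids,
    )


def write_timeseries(ts: RegionalTimeSeriesSet, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        ts.data,
        index=pd.Index(ts.region_table.region_ids, name="region_id"),
        columns=[f"t{t:04d}" for t in range(ts.n_timepoints)],
    )
    with open(path, "w") as fh:
        fh.write(
            f"# region_fingerprint={ts.region_table.fingerprint} "
            f"group={ts.group_label} subject={ts.subject_id}\n"
        )
        df.to_csv(fh, sep=_delimiter_for(path), float_format="%.17g")


@dataclass
class GeneExpressionMap:
    """Region x gene expression matrix aligned to a region table."""

    values: np.ndarray
    gene_symbols: tuple
    region_table: RegionTable

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_symbols = tuple(str(g) for g in self.gene_symbols)
        if self.values.ndim != 2:
            raise GeneMapError("expression values must be 2-D (regions x genes)")
        if self.values.shape != (self.region_table.n_regions, len(self.gene_symbols)):
            raise GeneMapError(
                f"expression shape {self.values.shape} inconsistent with "
                f"{self.region_table.n_regions} regions x {len(self.gene_symbols)} genes"
            )
        if len(self.gene_symbols) < 2:
            raise GeneMapError("need at least 2 genes")
        if not np.all(np.isfinite(self.values)):
            raise GeneMapError("expression map contains non-finite values after ingestion")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def read_gene_map(path, region_table: RegionTable) -> GeneExpressionMap:
    """Read a region x gene table (header = gene symbols, index = region IDs).

    Genes with any missing value are dropped with a logged warning; regions
    are never dropped, because the region set must stay aligned with the
    network nodes.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0, comment="#")
    df.index = [int(i) for i in df.index]
    wanted = list(region_table.region_ids)
    missing = [r for r in wanted if r not in df.index]
    if len(missing) == len(wanted):
        raise GeneMapError(f"{path.name}: no overlapping regions with the region table")
    if missing:
        raise GeneMapError(
            f"{path.name}: {len(missing)} region(s) absent from the map: {missing[:5]}..."
        )
    extra = [r for r in df.index if r not in set(wanted)]
    if extra:
        logger.warning("%s: ignoring %d rows not in the region table", path.name, len(extra))
    df = df.loc[wanted]
    n_before = df.shape[1]
    df = df.dropna(axis=1, how="any")
    dropped = n_before - df.shape[1]
    if dropped:
        logger.warning("%s: dropped %d gene(s) with missing values", path.name, dropped)
    if df.shape[1] < 2:
        raise GeneMapError(f"{path.name}: fewer than 2 genes survive missing-value filtering")
    return GeneExpressionMap(
        values=df.to_numpy(dtype=float),
        gene_symbols=tuple(df.columns),
        region_table=region_table,
    )


def write_gene_map(gmap: GeneExpressionMap, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        gmap.values,
        index=pd.Index(gmap.region_table.region_ids, name="region_id"),
        columns=list(gmap.gene_symbols),
    )
    with open(path, "w") as fh:
        fh.write(f"# region_fingerprint={gmap.region_table.fingerprint}\n")
        df.to_csv(fh, sep=_delimiter_for(path), float_format="%.17g")


def extract_regional_signals(
    volume_4d,
    labels,
    region_table: RegionTable,
    group_label: str = "HC",
    subject_id: str = "volume",
) -> RegionalTimeSeriesSet:
    """Average a 4-D BOLD image over the voxels of each labelled region.

    Parameters
    ----------
    volume_4d : nibabel image or ndarray
        4-D BOLD data (x, y, z, t).
    labels : nibabel image or ndarray
        Integer label volume on the same grid; 0 is background and every
        non-zero label must appear in ``region_table``.

    Regions with zero voxels are reported via warning and filled with zeros
    (they surface downstream as zero-variance regions).
    """
    import nibabel as nib

    def _as_array(img, ndim):
        if isinstance(img, np.ndarray):
            return img, None
        arr = np.asanyarray(img.dataobj)
        return arr, img.affine

    vol, vol_aff = _as_array(volume_4d, 4)
    lab, lab_aff = _as_array(labels, 3)
    if vol.ndim != 4 or lab.ndim != 3:
        raise GridMismatchError(
            f"expected 4-D volume and 3-D labels, got {vol.ndim}-D and {lab.ndim}-D"
        )
    if vol.shape[:3] != lab.shape:
        raise GridMismatchError(
            f"spatial grids differ: {vol.shape[:3]} vs {lab.shape}"
        )
    if vol_aff is not None and lab_aff is not None and not np.allclose(vol_aff, lab_aff):
        raise GridMismatchError("affines of 4-D image and label volume differ")
    lab = lab.astype(int)
    present = set(np.unique(lab)) - {0}
    if not present:
        raise GridMismatchError("label volume contains no non-background labels")
    unknown = present - set(region_table.region_ids)
    if unknown:
        raise GridMismatchError(f"labels {sorted(unknown)} not in the region table")

    n_t = vol.shape[3]
    flat = vol.reshape(-1, n_t)
    lab_flat = lab.reshape(-1)
    out = np.zeros((region_table.n_regions, n_t))
    empty = []
    for i, rid in enumerate(region_table.region_ids):
        mask = lab_flat == rid
        if not mask.any():
            empty.append(rid)
            continue
        out[i] = flat[mask].mean(axis=0)
    if empty:
        logger.warning("regions with zero voxels (filled with 0): %s", empty)
    return RegionalTimeSeriesSet(
        subject_id=subject_id,
        group_label=group_label,
        data=out,
        region_table=region_table,
        zero_variance_regions=tuple(empty),
    )


def write_profile_tsv(values, region_table: RegionTable, path, **metadata) -> None:
    """Write a per-region vector as (region_id, name, hemisphere, value)."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.shape != (region_table.n_regions,):
        raise ShapeMismatchError("profile length does not match region table")
    df = region_table.to_dataframe()
    df["value"] = values
    with open(path, "w") as fh:
        meta = " ".join(f"{k}={v}" for k, v in metadata.items())
        fh.write(f"# region_fingerprint={region_table.fingerprint} {meta}".rstrip() + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_fingerprint(path) -> str | None:
    """Pull the region fingerprint out of a file's leading comment, if any."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "region_fingerprint=" in first:
        return first.split("region_fingerprint=")[1].split()[0]
    return None


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
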