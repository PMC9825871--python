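"""Community matrices, sample metadata, and their readers/writers.

The central container is :class:`CommunityMatrix`, a validated sample x taxon
table of non-negative integer read counts.  Metadata is carried as a plain
:class:`pandas.DataFrame` indexed by sample id and validated by
:func:`read_metadata` / :func:`validate_metadata`.  Counts are never stored as
relative abundances; each analysis normalizes on demand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "ValidationError",
    "SchemaError",
    "MetadataMismatchWarning",
    "read_community_table",
    "write_community_table",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "align",
    "rarefy",
]

#: aridity-index window for the arid class (exclusive bounds)
ARID_AI_RANGE = (0.03, 0.2)
#: lower bound of the humid class (exclusive)
HUMID_AI_MIN = 0.65

REQUIRED_METADATA_COLUMNS = ("sample_id", "latitude", "longitude", "region")

#: full metadata schema; everything beyond the required four is optional
METADATA_COLUMNS = (
    "sample_id", "site_id", "replicate", "latitude", "longitude", "region",
    "aridity_index", "MAT", "MAP", "pH", "TC", "TN", "DOC", "DON", "NO3", "NH4",
)


class ValidationError(ValueError):
    """An invariant of the data model is violated."""


class SchemaError(ValueError):
    """A required column or label is missing from an input table."""


class MetadataMismatchWarning(UserWarning):
    """Region label inconsistent with the aridity index (non-fatal)."""


@dataclass(frozen=True)
class CommunityMatrix:
    """Sample x taxon table of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with sample ids as the index and taxon ids as columns.
        Validated on construction: integer-valued, non-negative, unique
        labels, at least 2 samples and 2 taxa, positive row sums.
    """

    counts: pd.DataFrame = field()

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate taxon id: {dup!r}")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValidationError(
                f"need at least 2 samples and 2 taxa, got shape {df.shape}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("counts contain missing values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        if not np.allclose(values, np.round(values.astype(float))):
            raise ValidationError("counts must be integers (reads)")
        if (values.sum(axis=1) == 0).any():
            empty = df.index[values.sum(axis=1) == 0][0]
            raise ValidationError(f"sample {empty!r} has zero total count")
        # normalize dtype and axis names without mutating caller's frame
        df = df.astype(np.int64)
        df = df.rename_axis(index="sample_id", columns="taxon_id")
        object.__setattr__(self, "counts", df)

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def values(self) -> np.ndarray:
        """Counts as an int64 array (samples x taxa)."""
        return self.counts.to_numpy()

    def relative(self) -> np.ndarray:
        """Row-normalized relative abundances (samples x taxa)."""
        v = self.values().astype(float)
        return v / v.sum(axis=1, keepdims=True)

    def select_samples(self, sample_ids) -> "CommunityMatrix":
        return CommunityMatrix(self.counts.loc[list(sample_ids)])

    def select_taxa(self, taxon_ids) -> "CommunityMatrix":
        return CommunityMatrix(self.counts.loc[:, list(taxon_ids)])

    def drop_empty_taxa(self) -> "CommunityMatrix":
        """Drop taxa with zero total count (e.g. after subsetting samples)."""
        keep = self.counts.sum(axis=0) > 0
        return CommunityMatrix(self.counts.loc[:, keep])


def read_community_table(path, orientation: str = "samples_as_rows") -> CommunityMatrix:
    """Read a TSV count table into a validated :class:`CommunityMatrix`.

    The file must have one header row and one leading label column.
    ``orientation`` states what the file's rows are; the result is always
    samples x taxa.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise SchemaError(
                f"non-numeric cell in column {col!r} at row {row!r} of {path}"
            )
    if orientation == "taxa_as_rows":
        df = df.T
    return CommunityMatrix(df)


def write_community_table(matrix: CommunityMatrix, path) -> None:
    """Write counts as TSV (samples as rows, '.' decimal, UTF-8)."""
    matrix.counts.to_csv(path, sep="\t", index_label="sample_id")


def validate_metadata(meta: pd.DataFrame, strict_region: bool = True) -> pd.DataFrame:
    """Validate a metadata table (indexed by sample_id) in place and return it.

    Checks coordinate ranges, region labels, and consistency of the region
    label with the aridity index (warning, not fatal).
    """
    if meta.index.has_duplicates:
        raise ValidationError("duplicate sample_id in metadata")
    lat = meta["latitude"].astype(float)
    lon = meta["longitude"].astype(float)
    if (lat.abs() > 90).any():
        bad = meta.index[lat.abs() > 90][0]
        raise ValidationError(f"latitude out of [-90, 90] for sample {bad!r}")
    if (lon.abs() > 180).any():
        bad = meta.index[lon.abs() > 180][0]
        raise ValidationError(f"longitude out of [-180, 180] for sample {bad!r}")
    regions = set(meta["region"].dropna().unique())
    if strict_region and not regions <= {"arid", "humid"}:
        raise ValidationError(f"unknown region labels: {regions - {'arid', 'humid'}}")
    if "aridity_index" in meta.columns:
        ai = pd.to_numeric(meta["aridity_index"], errors="coerce")
        lo, hi = ARID_AI_RANGE
        arid_bad = (meta["region"] == "arid") & ai.notna() & ~((ai > lo) & (ai < hi))
        humid_bad = (meta["region"] == "humid") & ai.notna() & ~(ai > HUMID_AI_MIN)
        for bad_mask, label in ((arid_bad, "arid"), (humid_bad, "humid")):
            if bad_mask.any():
                sid = meta.index[bad_mask][0]
                warnings.warn(
                    f"sample {sid!r}: region={label!r} inconsistent with "
                    f"aridity_index={ai[sid]:g}",
                    MetadataMismatchWarning,
                    stacklevel=2,
                )
    return meta


def read_metadata(path, strict_region: bool = True) -> pd.DataFrame:
    """Read and validate a sample metadata TSV.

    Requires columns sample_id, latitude, longitude, region; everything else
    (site, replicate, aridity index, climatic and edaphic covariates) is
    optional and may contain missing values.
    """
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata missing required column(s): {missing}")
    meta = meta.set_index("sample_id")
    return validate_metadata(meta, strict_region=strict_region)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def align(matrix: CommunityMatrix, meta: pd.DataFrame):
    """Restrict matrix and metadata to their shared samples, same order.

    Order follows the matrix. Raises on an empty intersection. Idempotent.
    """
    shared = [s for s in matrix.sample_ids if s in meta.index]
    if not shared:
        raise ValidationError("no shared sample ids between matrix and metadata")
    return matrix.select_samples(shared), meta.loc[shared]


def rarefy(matrix: CommunityMatrix, depth: int | None = None, seed: int = 0) -> CommunityMatrix:
    """Subsample each sample without replacement to a common depth.

    ``depth`` defaults to the minimum row sum. Not applied anywhere by
    default; exposed for users who want even depths before diversity
    calculations.
    """
    counts = matrix.values()
    if depth is None:
        depth = int(counts.sum(axis=1).min())
    if depth < 1 or depth > counts.sum(axis=1).min():
        raise ValueError(f"rarefaction depth {depth} exceeds the smallest sample")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(counts)
    for i, row in enumerate(counts):
        pool = np.repeat(np.arange(len(row)), row)
        picked = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(picked, minlength=len(row))
    df = pd.DataFrame(out, index=matrix.counts.index, columns=matrix.counts.columns)
    # rarefaction can empty a taxon but never a sample (depth >= 1)
    return CommunityMatrix(df)
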