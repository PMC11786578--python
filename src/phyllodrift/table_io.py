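"""Readers, writers and validation for ASV count tables and sample metadata.

The on-disk TSV convention follows common amplicon exports: ASVs as rows,
samples as columns. In memory everything is samples x ASVs. Orientation is
declared explicitly (``orientation`` argument), never guessed from shape —
silent transposition is the classic microbiome-I/O bug.

Presence downstream of here always means count >= ``min_count`` (default 1)
in the raw, non-rarefied table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AsvTable",
    "SampleFrame",
    "Dataset",
    "TableFormatError",
    "TableValidationError",
    "read_asv_table",
    "write_asv_table",
    "read_sample_frame",
    "write_sample_frame",
    "align",
]

SAMPLE_FRAME_COLUMNS = (
    "sample_id",
    "site_id",
    "position_m",
    "host_species",
    "replicate_id",
    "sample_type",
)

SAMPLE_TYPES = ("phyllosphere", "soil")
HOST_GROUPS = ("focal", "neighbour")


class TableFormatError(ValueError):
    """A file does not parse in the declared dialect."""


class TableValidationError(ValueError):
    """Parsed content violates a table invariant (negative count, duplicate id, ...)."""


@dataclass(frozen=True)
class AsvTable:
    """Integer read-count matrix, samples x ASVs.

    Parameters
    ----------
    counts
        DataFrame indexed by sample_id with ASV ids as columns; entries are
        non-negative integers (sequencing reads).

    Attributes
    ----------
    zero_count_asvs
        ASV ids whose total count across all samples is zero. Such ASVs are
        accepted on input but flagged so downstream stages can report them.
    """

    counts: pd.DataFrame
    zero_count_asvs: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.name is not None or df.columns.name is not None:
            df = df.rename_axis(index=None, columns=None)
            object.__setattr__(self, "counts", df)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate ASV identifiers: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # reject fractional values, accept float-typed integers
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
                bad = np.argwhere(arr != np.floor(arr))
                r, c = bad[0]
                raise TableValidationError(
                    f"non-integer count at sample {df.index[r]!r}, ASV {df.columns[c]!r}"
                )
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
            arr = df.to_numpy()
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise TableValidationError(
                f"negative count at sample {df.index[r]!r}, ASV {df.columns[c]!r}"
            )
        zero = tuple(df.columns[df.sum(axis=0) == 0].astype(str))
        object.__setattr__(self, "zero_count_asvs", zero)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.counts.index]

    @property
    def asv_ids(self) -> list[str]:
        return [str(a) for a in self.counts.columns]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def presence(self, min_count: int = 1) -> pd.DataFrame:
        """Boolean samples x ASVs presence matrix at the given detection threshold."""
        return self.counts >= int(min_count)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        return AsvTable(self.counts.loc[list(sample_ids)])

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised composition; zero-sum rows become all-zero rows."""
        sums = self.counts.sum(axis=1).to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts.to_numpy(dtype=float) / sums[:, None]
        rel[~np.isfinite(rel)] = 0.0
        return pd.DataFrame(rel, index=self.counts.index, columns=self.counts.columns)


@dataclass(frozen=True)
class SampleFrame:
    """Per-sample metadata: site, transect position, host species and group.

    ``host_group`` is derived deterministically: ``focal`` where host_species
    equals the declared focal species, ``neighbour`` otherwise (soil samples
    keep the group of the tree they were collected under).
    """

    frame: pd.DataFrame
    focal_species: str

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in SAMPLE_FRAME_COLUMNS if c not in df.columns]
        if missing:
            raise TableValidationError(f"missing metadata columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise TableValidationError(f"duplicate sample identifiers: {dups}")
        pos = pd.to_numeric(df["position_m"], errors="coerce")
        if pos.isna().any() or (pos < 0).any():
            bad = df.loc[pos.isna() | (pos < 0), "sample_id"].tolist()
            raise TableValidationError(f"invalid position_m (must be >= 0) for samples: {bad}")
        bad_type = ~df["sample_type"].isin(SAMPLE_TYPES)
        if bad_type.any():
            raise TableValidationError(
                f"sample_type must be one of {SAMPLE_TYPES}; offending samples: "
                f"{df.loc[bad_type, 'sample_id'].tolist()}"
            )
        if self.focal_species not in set(df["host_species"]):
            raise TableValidationError(
                f"focal species {self.focal_species!r} absent from host_species column"
            )
        # all phyllosphere samples at a site share one position
        phyl = df[df["sample_type"] == "phyllosphere"]
        per_site = phyl.groupby("site_id")["position_m"].nunique()
        if (per_site > 1).any():
            sites = per_site[per_site > 1].index.tolist()
            raise TableValidationError(
                f"inconsistent position_m among phyllosphere samples at sites: {sites}"
            )
        df = df.copy()
        df["position_m"] = pos
        df["host_group"] = np.where(
            df["host_species"] == self.focal_species, "focal", "neighbour"
        )
        df = df.set_index("sample_id", drop=False)
        df.index.name = None
        object.__setattr__(self, "frame", df)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame["sample_id"]]

    @property
    def site_ids(self) -> list[str]:
        return sorted(str(s) for s in self.frame["site_id"].unique())

    @property
    def host_species(self) -> list[str]:
        return sorted(str(s) for s in self.frame["host_species"].unique())

    def phyllosphere(self) -> pd.DataFrame:
        return self.frame[self.frame["sample_type"] == "phyllosphere"]

    def soil(self) -> pd.DataFrame:
        return self.frame[self.frame["sample_type"] == "soil"]

    def subset(self, sample_ids: Sequence[str]) -> "SampleFrame":
        df = self.frame.loc[list(sample_ids)].reset_index(drop=True)
        return SampleFrame(df, self.focal_species)


@dataclass(frozen=True)
class Dataset:
    """An AsvTable and SampleFrame restricted to their common samples, in canonical order."""

    table: AsvTable
    meta: SampleFrame
    dropped_table_samples: tuple[str, ...] = ()
    dropped_meta_samples: tuple[str, ...] = ()

    @property
    def sample_ids(self) -> list[str]:
        return self.table.sample_ids

    def phyllosphere_samples(
        self, site_id: str | None = None, host_group: str | None = None,
        host_species: str | None = None,
    ) -> list[str]:
        df = self.meta.phyllosphere()
        if site_id is not None:
            df = df[df["site_id"] == site_id]
        if host_group is not None:
            df = df[df["host_group"] == host_group]
        if host_species is not None:
            df = df[df["host_species"] == host_species]
        return [str(s) for s in df["sample_id"]]

    def soil_samples(self) -> list[str]:
        return [str(s) for s in self.meta.soil()["sample_id"]]


# ---------------------------------------------------------------------------
# TSV I/O


def read_asv_table(
    path: str | Path,
    format: Literal["tsv", "biom-json"] = "tsv",
    orientation: Literal["asvs-as-rows", "samples-as-rows"] = "asvs-as-rows",
) -> AsvTable:
    """Read a count table from TSV or BIOM (JSON flavour).

    TSV: first column holds ASV identifiers (under ``orientation``
    "asvs-as-rows", the default export convention), header row holds sample
    identifiers. The orientation is declared, never inferred from shape.
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise TableFormatError(f"cannot parse {path} as TSV: {exc}") from exc
        df = _coerce_counts(df, path)
        if orientation == "asvs-as-rows":
            df = df.T
        return AsvTable(df)
    if format == "biom-json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise TableFormatError(
                f"cannot parse {path} as BIOM JSON (line {exc.lineno}): {exc.msg}"
            ) from exc
        return _biom_to_table(payload, path)
    raise ValueError(f"unknown format: {format!r}")


def _coerce_counts(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index.astype(str))
    for col in df.columns:
        try:
            vals = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"non-numeric value in column {col!r} of {path}") from exc
        out[str(col)] = vals
    arr = out.to_numpy()
    if np.any(arr != np.floor(arr)):
        r, c = np.argwhere(arr != np.floor(arr))[0]
        raise TableValidationError(
            f"non-integer count at row {out.index[r]!r}, column {out.columns[c]!r}"
        )
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise TableValidationError(
            f"negative count at row {out.index[r]!r}, column {out.columns[c]!r}"
        )
    return out.astype(np.int64)


def write_asv_table(
    table: AsvTable,
    path: str | Path,
    format: Literal["tsv", "biom-json"] = "tsv",
    orientation: Literal["asvs-as-rows", "samples-as-rows"] = "asvs-as-rows",
) -> None:
    path = Path(path)
    if format == "tsv":
        df = table.counts.T if orientation == "asvs-as-rows" else table.counts
        label = "asv_id" if orientation == "asvs-as-rows" else "sample_id"
        df.rename_axis(label).to_csv(path, sep="\t")
        return
    if format == "biom-json":
        path.write_text(json.dumps(_table_to_biom(table)))
        return
    raise ValueError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
# BIOM 1.0 JSON flavour (sparse, observations = ASVs as rows per the BIOM spec)


def _table_to_biom(table: AsvTable) -> dict:
    counts = table.counts.to_numpy()
    rows, cols = np.nonzero(counts.T)  # BIOM rows are observations (ASVs)
    data = [[int(r), int(c), int(counts[c, r])] for r, c in zip(rows, cols)]
    return {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "phyllodrift",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_asvs, table.n_samples],
        "rows": [{"id": a, "metadata": None} for a in table.asv_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }


def _biom_to_table(payload: dict, path: Path) -> AsvTable:
    for key in ("rows", "columns", "data", "shape", "matrix_type"):
        if key not in payload:
            raise TableFormatError(f"BIOM file {path} lacks required key {key!r}")
    asv_ids = [r["id"] for r in payload["rows"]]
    sample_ids = [c["id"] for c in payload["columns"]]
    n_obs, n_samp = payload["shape"]
    counts = np.zeros((n_samp, n_obs), dtype=np.int64)
    if payload["matrix_type"] == "sparse":
        for r, c, v in payload["data"]:
            if v != int(v):
                raise TableValidationError(
                    f"non-integer count at ASV {asv_ids[r]!r}, sample {sample_ids[c]!r}"
                )
            counts[c, r] = int(v)
    elif payload["matrix_type"] == "dense":
        arr = np.asarray(payload["data"])
        if np.any(arr != np.floor(arr)):
            raise TableValidationError(f"non-integer counts in dense BIOM {path}")
        counts = arr.T.astype(np.int64)
    else:
        raise TableFormatError(f"unsupported BIOM matrix_type {payload['matrix_type']!r}")
    df = pd.DataFrame(counts, index=pd.Index(sample_ids), columns=pd.Index(asv_ids))
    return AsvTable(df)


# ---------------------------------------------------------------------------
# Sample metadata


def read_sample_frame(path: str | Path, focal_species: str) -> SampleFrame:
    """Read TSV sample metadata and derive host_group from the declared focal species."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise TableFormatError(f"cannot parse {path} as TSV: {exc}") from exc
    return SampleFrame(df, focal_species)


def write_sample_frame(meta: SampleFrame, path: str | Path) -> None:
    cols = list(SAMPLE_FRAME_COLUMNS) + ["host_group"]
    meta.frame[cols].to_csv(Path(path), sep="\t", index=False)


def align(table: AsvTable, meta: SampleFrame) -> Dataset:
    """Join a count table with its metadata on the sample-id intersection.

    Ordering is canonicalised by (site, host_species, replicate). Samples
    present on only one side are reported in the returned Dataset, never
    silently dropped. Aligning an already-aligned dataset is a no-op.
    """
    table_ids = set(table.sample_ids)
    meta_ids = set(meta.sample_ids)
    common = table_ids & meta_ids
    if not common:
        raise TableValidationError("no samples in common between table and metadata")
    dropped_table = tuple(sorted(table_ids - common))
    dropped_meta = tuple(sorted(meta_ids - common))
    sub = meta.frame[meta.frame["sample_id"].isin(common)]
    order = sub.sort_values(
        ["site_id", "sample_type", "host_species", "replicate_id", "sample_id"]
    )["sample_id"].tolist()
    return Dataset(
        table=table.subset_samples(order),
        meta=meta.subset(order),
        dropped_table_samples=dropped_table,
        dropped_meta_samples=dropped_meta,
    )
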