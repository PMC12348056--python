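"""Domain types and on-disk formats shared by every pipeline stage.

A dataset directory holds a CellRanger-style triplet — ``matrix.mtx[.gz]``
(features x droplets, Matrix-Market coordinate, 1-based), ``barcodes.tsv[.gz]``
(one droplet barcode per line) and ``features.tsv[.gz]`` (three columns:
feature id, feature name, feature type) — plus, for simulated data,
``truth.tsv`` with the per-droplet ground truth and, after evaluation,
``report.json``.

Sample tags are distinguished from genes by the feature type ``SampleTag``;
a tag's *name* column carries its 6-bp sample-index sequence.  For genes the
name column carries the gene class (``species:human``, ``species:mouse`` or a
``marker:<type>`` label), which is what the reference annotation consumes.
Droplet order is the barcodes-file order everywhere; nothing re-sorts.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

TAG_FEATURE_TYPE = "SampleTag"
GENE_FEATURE_TYPE = "Gene Expression"

TRUTH_COLUMNS = [
    "droplet_id",
    "status",
    "sample_1",
    "sample_2",
    "cell_type_1",
    "cell_type_2",
    "species_1",
    "species_2",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


class ConsistencyError(ValueError):
    """Raised when files in a dataset directory disagree with each other."""


@dataclass
class TagCountMatrix:
    """Droplet-by-tag UMI counts.

    ``counts`` is a dense integer array of shape (n_droplets, n_tags): tag
    panels are small (2-12 tags), so density costs nothing and keeps the
    classifier arithmetic simple.  ``tag_indices`` are the 6-bp sample-index
    sequences, aligned with ``tag_ids``.
    """

    droplet_ids: list[str]
    tag_ids: list[str]
    tag_indices: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.droplet_ids), len(self.tag_ids)):
            raise ConsistencyError(
                f"tag count matrix shape {self.counts.shape} does not match "
                f"{len(self.droplet_ids)} droplets x {len(self.tag_ids)} tags"
            )
        if len(self.tag_indices) != len(self.tag_ids):
            raise ConsistencyError("tag_indices and tag_ids lengths differ")
        if len(set(self.droplet_ids)) != len(self.droplet_ids):
            raise ConsistencyError("droplet_ids are not unique")
        if len(set(self.tag_ids)) != len(self.tag_ids):
            raise ConsistencyError("tag_ids are not unique")
        if len(set(self.tag_indices)) != len(self.tag_indices):
            raise ConsistencyError("tag index sequences are not unique")
        for seq in self.tag_indices:
            if len(seq) != 6:
                raise FormatError(f"tag index {seq!r} is not 6 characters")
        if self.counts.size and (
            not np.issubdtype(self.counts.dtype, np.integer) or self.counts.min() < 0
        ):
            raise FormatError("tag counts must be non-negative integers")

    @property
    def n_droplets(self) -> int:
        return len(self.droplet_ids)

    @property
    def n_tags(self) -> int:
        return len(self.tag_ids)


@dataclass
class ExpressionMatrix:
    """Droplet-by-gene UMI counts with a per-gene class label.

    ``gene_class`` entries are ``species:human`` / ``species:mouse`` for
    barnyard designs or ``marker:<cell type>`` / ``common`` for single-species
    designs.  ``counts`` is CSR, droplets x genes, integer.
    """

    droplet_ids: list[str]
    gene_ids: list[str]
    gene_class: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.droplet_ids), len(self.gene_ids)):
            raise ConsistencyError(
                f"expression matrix shape {self.counts.shape} does not match "
                f"{len(self.droplet_ids)} droplets x {len(self.gene_ids)} genes"
            )
        if len(self.gene_class) != len(self.gene_ids):
            raise ConsistencyError("gene_class and gene_ids lengths differ")
        if self.counts.nnz and (
            not np.issubdtype(self.counts.dtype, np.integer)
            or self.counts.data.min() < 0
        ):
            raise FormatError("gene counts must be non-negative integers")

    @property
    def n_droplets(self) -> int:
        return len(self.droplet_ids)


@dataclass
class DemuxCall:
    """Per-droplet demultiplexing call.

    ``assigned_tags`` holds 0 (negative), 1 (singlet) or 2 (doublet) tag ids;
    ``confidence_ratio`` is the top tag's share of the background-corrected
    tag total.  ``ambiguous`` flags exact top-count ties, which are broken
    toward the lowest tag index.
    """

    droplet_id: str
    call_status: str  # singlet | doublet | negative
    assigned_tags: tuple[str, ...]
    confidence_ratio: float
    total_tag_umis: int
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.call_status not in ("singlet", "doublet", "negative"):
            raise ValueError(f"bad call_status {self.call_status!r}")
        if not 0.0 <= self.confidence_ratio <= 1.0:
            raise ValueError("confidence_ratio outside [0, 1]")
        expected = {"singlet": 1, "doublet": 2, "negative": 0}[self.call_status]
        if len(self.assigned_tags) != expected:
            raise ValueError(
                f"{self.call_status} call with {len(self.assigned_tags)} tags"
            )


def calls_to_frame(calls: Sequence[DemuxCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "droplet_id": [c.droplet_id for c in calls],
            "call_status": [c.call_status for c in calls],
            "tags": [",".join(c.assigned_tags) for c in calls],
            "confidence_ratio": [c.confidence_ratio for c in calls],
            "total_tag_umis": [c.total_tag_umis for c in calls],
            "ambiguous": [c.ambiguous for c in calls],
        }
    )


def frame_to_calls(frame: pd.DataFrame) -> list[DemuxCall]:
    calls = []
    for row in frame.itertuples(index=False):
        tags = tuple(t for t in str(row.tags).split(",") if t) if isinstance(row.tags, str) else ()
        calls.append(
            DemuxCall(
                droplet_id=row.droplet_id,
                call_status=row.call_status,
                assigned_tags=tags,
                confidence_ratio=float(row.confidence_ratio),
                total_tag_umis=int(row.total_tag_umis),
                ambiguous=bool(getattr(row, "ambiguous", False)),
            )
        )
    return calls


@dataclass
class RunConfig:
    """All pipeline knobs in one place.

    The singlet threshold of 0.9 is the classifier's defining parameter; the
    remainder are documented operational defaults (see docs/methods.md for
    the rationale behind each).
    """

    singlet_threshold: float = 0.9
    min_tag_umis: int = 10
    doublet_second_tag_min_fraction: float = 0.2
    background_mode: str = "per-tag-subtract"  # or "none"
    knn_k: int = 20
    n_pcs: int = 30
    synthetic_doublet_ratio: float = 2.0
    expected_doublet_rate: float = 0.0542
    depth_outlier_sd: float = 1.96
    random_seed: int = 0
    plex: int = 2
    species_threshold: float = 0.9
    min_species_umis: int = 100

    def __post_init__(self) -> None:
        if not 0.5 < self.singlet_threshold <= 1.0:
            raise ValueError(
                f"singlet_threshold must be in (0.5, 1], got {self.singlet_threshold}"
            )
        if not 0.0 < self.species_threshold <= 1.0:
            raise ValueError(
                f"species_threshold must be in (0, 1], got {self.species_threshold}"
            )
        if self.min_tag_umis < 1:
            raise ValueError("min_tag_umis must be >= 1")
        if self.background_mode not in ("none", "per-tag-subtract"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")
        if not 0.0 <= self.expected_doublet_rate < 1.0:
            raise ValueError("expected_doublet_rate must be in [0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def load_config(path: str | os.PathLike | None = None, **overrides) -> RunConfig:
    """Read a flat key-value YAML config; keyword overrides win over the file.

    An empty or absent file yields all defaults (singlet threshold 0.9).
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise FormatError(f"config {path} is not a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


# ---------------------------------------------------------------------------
# dataset directory IO


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] in {dirpath}")


def _read_tsv(path: Path, n_cols: int) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame({i: pd.Series(dtype=str) for i in range(n_cols)})
    if frame.shape[1] != n_cols:
        raise FormatError(f"{path} has {frame.shape[1]} columns, expected {n_cols}")
    return frame


def write_counts(
    tags: TagCountMatrix,
    expr: ExpressionMatrix,
    path: str | os.PathLike,
    gzipped: bool = False,
) -> None:
    """Write a dataset directory readable by :func:`read_counts`.

    Tags and genes are stacked into one features-x-droplets matrix; the
    feature-type column keeps them apart.
    """
    if tags.droplet_ids != expr.droplet_ids:
        raise ConsistencyError("tag and expression matrices are not droplet-aligned")
    dirpath = Path(path)
    dirpath.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""

    features = pd.DataFrame(
        {
            "id": tags.tag_ids + expr.gene_ids,
            "name": tags.tag_indices + expr.gene_class,
            "feature_type": [TAG_FEATURE_TYPE] * tags.n_tags
            + [GENE_FEATURE_TYPE] * len(expr.gene_ids),
        }
    )
    features.to_csv(
        dirpath / f"features.tsv{suffix}", sep="\t", header=False, index=False
    )
    pd.Series(tags.droplet_ids).to_csv(
        dirpath / f"barcodes.tsv{suffix}", sep="\t", header=False, index=False
    )

    stacked = sp.vstack(
        [sp.csr_matrix(tags.counts.T), expr.counts.T.tocsr()], format="csr"
    ).astype(np.int64)
    mtx_path = dirpath / f"matrix.mtx{suffix}"
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, stacked.tocoo(), field="integer")
    opener = gzip.open if gzipped else open
    with opener(mtx_path, "wb") as fh:
        fh.write(buf.getvalue())


def read_counts(path: str | os.PathLike) -> tuple[TagCountMatrix, ExpressionMatrix]:
    """Read a dataset directory back into aligned tag and expression matrices."""
    dirpath = Path(path)
    mtx_path = _find(dirpath, "matrix.mtx")
    barcodes = _read_tsv(_find(dirpath, "barcodes.tsv"), 1)[0].tolist()
    features = _read_tsv(_find(dirpath, "features.tsv"), 3)
    features.columns = ["id", "name", "feature_type"]

    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # scipy raises ValueError on malformed headers
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(features), len(barcodes)):
        raise ConsistencyError(
            f"matrix is {mat.shape[0]}x{mat.shape[1]} but features.tsv lists "
            f"{len(features)} features and barcodes.tsv lists {len(barcodes)} barcodes"
        )
    if mat.nnz and not np.issubdtype(mat.dtype, np.integer):
        if not np.all(mat.data == np.round(mat.data)):
            raise FormatError(f"{mtx_path} contains non-integer entries")
        mat = mat.astype(np.int64)
    mat = mat.tocsr().astype(np.int64)

    is_tag = (features["feature_type"] == TAG_FEATURE_TYPE).to_numpy()
    tag_rows = np.flatnonzero(is_tag)
    gene_rows = np.flatnonzero(~is_tag)
    tags = TagCountMatrix(
        droplet_ids=barcodes,
        tag_ids=features["id"].to_numpy()[tag_rows].tolist(),
        tag_indices=features["name"].to_numpy()[tag_rows].tolist(),
        counts=np.asarray(mat[tag_rows].todense()).T.astype(np.int64),
    )
    expr = ExpressionMatrix(
        droplet_ids=barcodes,
        gene_ids=features["id"].to_numpy()[gene_rows].tolist(),
        gene_class=features["name"].to_numpy()[gene_rows].tolist(),
        counts=mat[gene_rows].T.tocsr(),
    )
    return tags, expr


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ConsistencyError(f"truth table missing columns {missing}")
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", dtype={"droplet_id": str}, keep_default_na=False)
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise FormatError(f"truth table missing columns {missing}")
    return truth
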