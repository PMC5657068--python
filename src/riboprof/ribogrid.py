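"""Per-gene read-length × position count matrices, persisted as HDF5.

Counts are keyed by the 5'-end transcript position, not the A-site:
A-site shifting is a downstream view, so one store serves any offset
table. HDF5 layout (schema 1.0)::

    /                      attrs: schema_version, dataset_id, config (JSON)
    /<dataset_id>/<gene_id>/reads/data   int64 matrix [n_lengths, n_positions]
    /<dataset_id>/<gene_id>             attrs: lengths, buffer_left,
                                         buffer_right, start_codon_pos,
                                         stop_codon_pos, reads_total
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet
from .errors import DataError
from .read_prep import Alignment

SCHEMA_VERSION = "1.0"


@dataclass
class GeneFingerprint:
    """Annotation coordinates a store carries for one gene."""

    buffer_left: int
    buffer_right: int
    start_codon_pos: int
    stop_codon_pos: int

    @property
    def orf_length(self) -> int:
        return self.stop_codon_pos - self.start_codon_pos + 3


@dataclass
class GeneCountMatrix:
    """Integer counts indexed by (read length, 5'-end position) for one gene."""

    gene_id: str
    lmin: int
    lmax: int
    counts: np.ndarray  # shape (lmax - lmin + 1, n_positions)

    def __post_init__(self) -> None:
        expected_rows = self.lmax - self.lmin + 1
        if self.counts.shape[0] != expected_rows:
            raise DataError(
                f"{self.gene_id}: {self.counts.shape[0]} rows != "
                f"{expected_rows} lengths"
            )
        if (self.counts < 0).any():
            raise DataError(f"{self.gene_id}: negative counts")

    @property
    def n_positions(self) -> int:
        return self.counts.shape[1]

    @property
    def reads_total(self) -> int:
        return int(self.counts.sum())

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.lmin, self.lmax + 1)

    def row(self, read_length: int) -> np.ndarray:
        if not self.lmin <= read_length <= self.lmax:
            raise DataError(f"read length {read_length} outside [{self.lmin},{self.lmax}]")
        return self.counts[read_length - self.lmin]


@dataclass
class DatasetStore:
    """All gene matrices for one dataset plus annotation fingerprint/provenance."""

    dataset_id: str
    lmin: int
    lmax: int
    matrices: dict[str, GeneCountMatrix]
    fingerprint: dict[str, GeneFingerprint]
    config: dict = field(default_factory=dict)
    n_skipped_window: int = 0

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.matrices

    def __getitem__(self, gene_id: str) -> GeneCountMatrix:
        if gene_id not in self.matrices:
            raise DataError(f"gene {gene_id!r} not in store {self.dataset_id!r}")
        return self.matrices[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrices)

    @property
    def reads_total(self) -> int:
        return sum(m.reads_total for m in self.matrices.values())


def build_count_matrices(
    alignments: Iterable[Alignment],
    annotation: AnnotationSet,
    lmin: int,
    lmax: int,
    dataset_id: str = "dataset",
    config: dict | None = None,
) -> DatasetStore:
    """Tally alignments into per-gene (length × 5'-end position) matrices.

    Every gene in the annotation gets a matrix (all-zero if unobserved).
    Alignments outside [lmin, lmax] are excluded and tallied in
    ``n_skipped_window``. An alignment to a gene absent from the
    annotation is fatal: it should have been rejected upstream.
    """
    n_lengths = lmax - lmin + 1
    counts = {
        gid: np.zeros((n_lengths, rec.length), dtype=np.int64)
        for gid, rec in annotation.records.items()
    }
    skipped = 0
    for a in alignments:
        if a.gene_id not in counts:
            raise DataError(f"alignment to unknown gene {a.gene_id!r}")
        if not lmin <= a.read_length <= lmax:
            skipped += 1
            continue
        rec = annotation.records[a.gene_id]
        if not 0 <= a.pos_5p <= rec.length - a.read_length:
            raise DataError(
                f"alignment out of bounds: {a.gene_id} pos {a.pos_5p} len {a.read_length}"
            )
        counts[a.gene_id][a.read_length - lmin, a.pos_5p] += 1

    matrices = {
        gid: GeneCountMatrix(gid, lmin, lmax, mat) for gid, mat in counts.items()
    }
    fingerprint = {
        gid: GeneFingerprint(
            rec.buffer_left, rec.buffer_right, rec.start_codon_pos, rec.stop_codon_pos
        )
        for gid, rec in annotation.records.items()
    }
    return DatasetStore(
        dataset_id=dataset_id,
        lmin=lmin,
        lmax=lmax,
        matrices=matrices,
        fingerprint=fingerprint,
        config=dict(config or {}),
        n_skipped_window=skipped,
    )


# ---------------------------------------------------------------------------
# HDF5 persistence

def write_h5(store: DatasetStore, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["dataset_id"] = store.dataset_id
        f.attrs["config"] = json.dumps(store.config, sort_keys=True)
        f.attrs["n_skipped_window"] = store.n_skipped_window
        root = f.create_group(store.dataset_id)
        for gid, mat in store.matrices.items():
            grp = root.create_group(gid)
            fp = store.fingerprint[gid]
            grp.attrs["lengths"] = mat.lengths
            grp.attrs["buffer_left"] = fp.buffer_left
            grp.attrs["buffer_right"] = fp.buffer_right
            grp.attrs["start_codon_pos"] = fp.start_codon_pos
            grp.attrs["stop_codon_pos"] = fp.stop_codon_pos
            grp.attrs["reads_total"] = mat.reads_total
            reads = grp.create_group("reads")
            reads.create_dataset(
                "data", data=mat.counts, compression="gzip",
                chunks=mat.counts.shape,
            )


def read_h5(path, genes: Iterable[str] | None = None) -> DatasetStore:
    """Load a store written by :func:`write_h5`, optionally a gene subset."""
    if not Path(path).exists():
        raise DataError(f"HDF5 store not found: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise DataError(f"cannot open HDF5 store {path}: {exc}") from exc
    with f:
        version = f.attrs.get("schema_version", "")
        if not str(version).startswith("1."):
            raise DataError(f"unknown schema_version {version!r} in {path}")
        dataset_id = f.attrs["dataset_id"]
        config = json.loads(f.attrs.get("config", "{}"))
        skipped = int(f.attrs.get("n_skipped_window", 0))
        root = f[dataset_id]
        wanted = list(genes) if genes is not None else list(root)
        matrices: dict[str, GeneCountMatrix] = {}
        fingerprint: dict[str, GeneFingerprint] = {}
        lmin = lmax = None
        for gid in wanted:
            if gid not in root:
                raise DataError(f"gene {gid!r} absent from store {path}")
            grp = root[gid]
            lengths = np.asarray(grp.attrs["lengths"])
            lmin, lmax = int(lengths[0]), int(lengths[-1])
            counts = grp["reads"]["data"][()]
            matrices[gid] = GeneCountMatrix(gid, lmin, lmax, counts)
            fingerprint[gid] = GeneFingerprint(
                int(grp.attrs["buffer_left"]),
                int(grp.attrs["buffer_right"]),
                int(grp.attrs["start_codon_pos"]),
                int(grp.attrs["stop_codon_pos"]),
            )
    if lmin is None:
        raise DataError(f"no genes loaded from {path}")
    return DatasetStore(
        dataset_id=str(dataset_id),
        lmin=lmin,
        lmax=lmax,
        matrices=matrices,
        fingerprint=fingerprint,
        config=config,
        n_skipped_window=skipped,
    )


def stores_equal(a: DatasetStore, b: DatasetStore) -> bool:
    """Element-wise equality of matrices and fingerprints (order-insensitive)."""
    if a.dataset_id != b.dataset_id or set(a.matrices) != set(b.matrices):
        return False
    for gid in a.matrices:
        if not np.array_equal(a.matrices[gid].counts, b.matrices[gid].counts):
            return False
        if a.fingerprint[gid] != b.fingerprint[gid]:
            return False
    return True


# ---------------------------------------------------------------------------
# TSV export

def export_gene_tsv(store: DatasetStore, out_dir) -> dict[str, Path]:
    """Write one TSV per gene (position × read-length counts) plus a summary.

    Per-gene files have a `position` column and one `len_<L>` column per
    read length; the summary TSV lists reads_total per gene. Returns the
    mapping gene_id → file path (summary under key "__summary__").
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    summary_rows = []
    for gid, mat in store.matrices.items():
        df = pd.DataFrame(
            mat.counts.T,
            columns=[f"len_{L}" for L in mat.lengths],
        )
        df.insert(0, "position", np.arange(mat.n_positions))
        p = out_dir / f"{gid}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[gid] = p
        summary_rows.append(
            {"gene_id": gid, "reads_total": mat.reads_total,
             "n_positions": mat.n_positions}
        )
    summary = out_dir / f"{store.dataset_id}_summary.tsv"
    pd.DataFrame(summary_rows).to_csv(summary, sep="\t", index=False)
    paths["__summary__"] = summary
    return paths


def import_gene_tsv(path, gene_id: str | None = None) -> GeneCountMatrix:
    """Re-import a per-gene TSV written by :func:`export_gene_tsv`."""
    df = pd.read_csv(path, sep="\t")
    len_cols = [c for c in df.columns if c.startswith("len_")]
    if not len_cols or "position" not in df.columns:
        raise DataError(f"{path}: not a gene count TSV")
    lengths = [int(c.split("_")[1]) for c in len_cols]
    counts = df[len_cols].to_numpy(dtype=np.int64).T
    gid = gene_id or Path(path).stem
    return GeneCountMatrix(gid, min(lengths), max(lengths), counts)
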