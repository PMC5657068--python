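"""Gene-level quantification: RPKM, feature correlations, relative abundance.

RPKM = 1e9 × orf_read_count / (n_total_orf_reads × orf_length_nt), with ORF
membership decided by a read's 5'-end position (consistent with the store's
keying, and independent of any A-site offset table). Correlations with
sequence features use Spearman's rank coefficient: the features span orders
of magnitude and rank correlation is monotone-invariant, so no log
transform is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .ribogrid import DatasetStore

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = (
    "orf_length", "utr5_length", "utr5_gc", "utr3_gc",
    "n_upstream_atg", "folding_energy", "polya_length",
)


@dataclass
class ExpressionTable:
    """Per-gene ORF read counts and RPKM for one dataset."""

    dataset_id: str
    table: pd.DataFrame  # index gene_id; columns orf_read_count, rpkm
    n_total_orf_reads: int

    def rpkm(self, gene: str) -> float:
        if gene not in self.table.index:
            raise DataError(f"gene {gene!r} not in expression table {self.dataset_id!r}")
        return float(self.table.loc[gene, "rpkm"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "gene_id", out.index)
        with open(path, "w") as fh:
            fh.write(f"# dataset_id={self.dataset_id}\tn_total_orf_reads={self.n_total_orf_reads}\n")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise DataError(f"{path}: missing metadata header line")
            meta = dict(kv.split("=", 1) for kv in header[1:].strip().split("\t"))
            df = pd.read_csv(fh, sep="\t")
        return cls(
            dataset_id=meta["dataset_id"],
            table=df.set_index("gene_id"),
            n_total_orf_reads=int(meta["n_total_orf_reads"]),
        )


def compute_rpkm(store: DatasetStore) -> ExpressionTable:
    """Quantify each gene as reads per kilobase of ORF per million mapped.

    A read counts toward a gene when its 5' end lies within the ORF
    (start codon through end of stop codon). Fatal when the dataset has
    zero ORF reads in total.
    """
    rows = []
    for gid, mat in store.matrices.items():
        fp = store.fingerprint[gid]
        count = int(mat.counts[:, fp.start_codon_pos : fp.stop_codon_pos + 3].sum())
        rows.append({"gene_id": gid, "orf_read_count": count,
                     "orf_length": fp.orf_length})
    df = pd.DataFrame(rows).set_index("gene_id")
    total = int(df["orf_read_count"].sum())
    if total == 0:
        raise DataError("no ORF reads in dataset; cannot compute RPKM")
    df["rpkm"] = 1e9 * df["orf_read_count"] / (total * df["orf_length"])
    return ExpressionTable(
        dataset_id=store.dataset_id,
        table=df[["orf_read_count", "rpkm"]],
        n_total_orf_reads=total,
    )


def feature_correlations(
    expr: ExpressionTable,
    features: pd.DataFrame,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Spearman rank correlation of RPKM against each sequence feature.

    Pairwise-complete: for each feature, genes missing either value are
    dropped; average ranks handle ties. Features with fewer than
    ``min_genes`` complete pairs are reported as missing with their n.
    Returns a DataFrame indexed by feature with columns rho and n.
    """
    joined = features.join(expr.table["rpkm"], how="inner")
    rows = []
    for feat in FEATURE_COLUMNS:
        if feat not in joined.columns:
            continue
        sub = joined[[feat, "rpkm"]].dropna()
        n = len(sub)
        if n < min_genes or sub[feat].nunique() < 2 or sub["rpkm"].nunique() < 2:
            rows.append({"feature": feat, "rho": np.nan, "n": n})
            continue
        rho = stats.spearmanr(sub[feat], sub["rpkm"]).statistic
        rows.append({"feature": feat, "rho": float(rho), "n": n})
    return pd.DataFrame(rows).set_index("feature")


def relative_abundance(
    gene: str,
    expr: ExpressionTable,
    reference_panel: list[ExpressionTable],
    floor: float = 0.01,
) -> tuple[float, bool]:
    """log2 abundance of a gene relative to the median of a reference panel.

    The panel median is over reference datasets in which the gene has
    rpkm > 0. When the gene's own rpkm is 0, a pseudo-RPKM floor is
    substituted in the numerator and flagged in the second return value.
    """
    if not reference_panel:
        raise DataError("empty reference panel")
    ref_values = [
        ref.rpkm(gene)
        for ref in reference_panel
        if gene in ref.table.index and ref.rpkm(gene) > 0
    ]
    if not ref_values:
        raise DataError(f"gene {gene!r} has no positive RPKM in any reference dataset")
    median = float(np.median(ref_values))
    value = expr.rpkm(gene)
    floored = value == 0
    if floored:
        value = floor
        logger.warning("gene %s has rpkm 0; floored to %g", gene, floor)
    return float(np.log2(value / median)), floored


def load_reference_panel(panel_dir) -> list[ExpressionTable]:
    """Load a directory of ExpressionTable TSVs (one per dataset)."""
    paths = sorted(Path(panel_dir).glob("*.tsv"))
    if not paths:
        raise DataError(f"no ExpressionTable TSVs in {panel_dir}")
    return [ExpressionTable.from_tsv(p) for p in paths]
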