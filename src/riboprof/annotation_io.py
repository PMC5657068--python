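"""ORF-centric transcriptome annotation: loading, validation, sequence features.

The reference model is one transcript per gene: a fixed-width 5' buffer, the
CDS (ATG through stop, length divisible by 3), and a fixed-width 3' buffer.
All internal coordinates are 0-based half-open on the transcript; GFF3 input
is 1-based inclusive and converted at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class TranscriptRecord:
    """One gene's transcript with UTR buffers and CDS coordinates.

    The coordinate frame for every downstream positional statistic:
    ``sequence[start_codon_pos:start_codon_pos + orf_length]`` is the ORF
    (including the stop codon), flanked by ``buffer_left`` and
    ``buffer_right`` nucleotides of UTR buffer.
    """

    gene_id: str
    sequence: str
    buffer_left: int
    buffer_right: int
    start_codon_pos: int
    stop_codon_pos: int
    orf_length: int

    def __post_init__(self) -> None:
        if set(self.sequence) - VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise ValidationError(f"{self.gene_id}: invalid bases {bad}")
        if len(self.sequence) != self.buffer_left + self.orf_length + self.buffer_right:
            raise ValidationError(
                f"{self.gene_id}: length {len(self.sequence)} != "
                f"{self.buffer_left} + {self.orf_length} + {self.buffer_right}"
            )
        if self.start_codon_pos != self.buffer_left:
            raise ValidationError(f"{self.gene_id}: start_codon_pos != buffer_left")
        if self.orf_length % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: ORF length {self.orf_length} not divisible by 3"
            )
        if self.stop_codon_pos != self.start_codon_pos + self.orf_length - 3:
            raise ValidationError(f"{self.gene_id}: stop_codon_pos inconsistent")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_codons(self) -> int:
        """Number of codons in the ORF, stop codon included."""
        return self.orf_length // 3

    @property
    def utr5(self) -> str:
        return self.sequence[: self.buffer_left]

    @property
    def utr3(self) -> str:
        return self.sequence[self.buffer_left + self.orf_length :]

    @property
    def orf(self) -> str:
        return self.sequence[self.start_codon_pos : self.start_codon_pos + self.orf_length]


@dataclass
class AnnotationSet:
    """Validated collection of TranscriptRecord, keyed by gene_id."""

    records: dict[str, TranscriptRecord]
    fasta_path: str | None = None
    gff_path: str | None = None
    excluded: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> TranscriptRecord:
        return self.records[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)


def load_transcriptome(fasta_path, gff_path) -> AnnotationSet:
    """Load an ORF-centric transcriptome from FASTA + GFF3.

    The GFF3 must carry one CDS feature per FASTA sequence, in transcript
    coordinates (1-based inclusive, per the GFF standard); the feature's
    seqid (or its gene_id/Name attribute) names the gene. Records whose CDS
    length is not divisible by 3 are excluded and listed in
    ``AnnotationSet.excluded``; a non-ATG start codon is a warning only.

    Raises
    ------
    DataError
        Missing file, unparsable input, or FASTA/GFF gene-id mismatch.
    """
    try:
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
    except FileNotFoundError as exc:
        raise DataError(f"FASTA not found: {fasta_path}") from exc
    if not seqs:
        raise DataError(f"no sequences parsed from {fasta_path}")

    try:
        db = gffutils.create_db(
            str(gff_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="error",
        )
    except FileNotFoundError as exc:
        raise DataError(f"GFF not found: {gff_path}") from exc

    cds: dict[str, tuple[int, int]] = {}
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("gene_id", [feat.seqid])[0]
        if gene_id in cds:
            raise DataError(f"duplicate CDS feature for gene {gene_id}")
        cds[gene_id] = (feat.start, feat.end)  # 1-based inclusive

    only_fasta = sorted(set(seqs) - set(cds))
    only_gff = sorted(set(cds) - set(seqs))
    if only_fasta or only_gff:
        raise DataError(
            f"FASTA/GFF gene-id mismatch: FASTA-only={only_fasta[:10]}, "
            f"GFF-only={only_gff[:10]}"
        )

    records: dict[str, TranscriptRecord] = {}
    excluded: dict[str, str] = {}
    warnings: list[str] = []
    for gene_id, seq in seqs.items():
        start1, end1 = cds[gene_id]
        buffer_left = start1 - 1          # 0-based start of CDS
        orf_length = end1 - start1 + 1
        buffer_right = len(seq) - end1
        if orf_length % 3 != 0:
            excluded[gene_id] = f"ORF length {orf_length} not divisible by 3"
            logger.warning("excluding %s: %s", gene_id, excluded[gene_id])
            continue
        try:
            rec = TranscriptRecord(
                gene_id=gene_id,
                sequence=seq,
                buffer_left=buffer_left,
                buffer_right=buffer_right,
                start_codon_pos=buffer_left,
                stop_codon_pos=buffer_left + orf_length - 3,
                orf_length=orf_length,
            )
        except ValidationError as exc:
            excluded[gene_id] = str(exc)
            logger.warning("excluding %s: %s", gene_id, exc)
            continue
        if rec.orf[:3] != "ATG":
            warnings.append(f"{gene_id}: start codon is {rec.orf[:3]}, not ATG")
        records[gene_id] = rec

    return AnnotationSet(
        records=records,
        fasta_path=str(fasta_path),
        gff_path=str(gff_path),
        excluded=excluded,
        warnings=warnings,
    )


def write_transcriptome(records, fasta_path, gff_path, source: str = "riboprof") -> None:
    """Write TranscriptRecords as FASTA plus a matching GFF3 of CDS features."""
    if not isinstance(records, dict):
        records = {r.gene_id: r for r in records}
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=gid, description="")
        for gid, rec in records.items()
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, rec in records.items():
            start1 = rec.start_codon_pos + 1
            end1 = rec.start_codon_pos + rec.orf_length
            fh.write(
                f"{gid}\t{source}\tCDS\t{start1}\t{end1}\t.\t+\t0\t"
                f"ID={gid}_CDS;gene_id={gid}\n"
            )


def _gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


def count_upstream_atg(utr5: str) -> int:
    """Count ATG occurrences in the 5' buffer, any frame, overlaps allowed."""
    n = 0
    i = utr5.find("ATG")
    while i != -1:
        n += 1
        i = utr5.find("ATG", i + 1)
    return n


def compute_sequence_features(annotation: AnnotationSet) -> pd.DataFrame:
    """Per-gene sequence-derived features used in expression correlations.

    Returns a DataFrame indexed by gene_id with columns orf_length,
    utr5_length, utr5_gc, utr3_gc, n_upstream_atg, folding_energy,
    polya_length. The last two are externally measured quantities and are
    left missing for :func:`join_external_features`.
    """
    rows = []
    for gid, rec in annotation.records.items():
        rows.append(
            {
                "gene_id": gid,
                "orf_length": rec.orf_length,
                "utr5_length": rec.buffer_left,
                "utr5_gc": _gc_fraction(rec.utr5),
                "utr3_gc": _gc_fraction(rec.utr3),
                "n_upstream_atg": count_upstream_atg(rec.utr5),
                "folding_energy": np.nan,
                "polya_length": np.nan,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "orf_length", "utr5_length", "utr5_gc", "utr3_gc",
            "n_upstream_atg", "folding_energy", "polya_length",
        ],
    )
    return df.set_index("gene_id")


def join_external_features(features: pd.DataFrame, tsv_path) -> pd.DataFrame:
    """Merge externally supplied features (folding energy, poly-A length).

    The TSV is tab-delimited with a header row, a gene_id column, and "NA"
    for missing values. Duplicate gene_id rows are fatal; unmatched ids on
    either side are logged.
    """
    ext = pd.read_csv(tsv_path, sep="\t", na_values=["NA"])
    if "gene_id" not in ext.columns:
        raise DataError(f"{tsv_path}: no gene_id column")
    if ext["gene_id"].duplicated().any():
        dups = ext.loc[ext["gene_id"].duplicated(), "gene_id"].tolist()
        raise DataError(f"{tsv_path}: duplicate gene_id rows: {dups[:10]}")
    ext = ext.set_index("gene_id")

    missing = features.index.difference(ext.index)
    extra = ext.index.difference(features.index)
    if len(missing):
        logger.warning("%d genes absent from external feature TSV", len(missing))
    if len(extra):
        logger.warning("%d external TSV genes not in annotation (ignored)", len(extra))

    out = features.copy()
    for col in ("folding_energy", "polya_length"):
        if col in ext.columns:
            out[col] = ext[col].reindex(out.index)
    return out
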