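"""Read preparation: adapter trimming, length and rRNA filtering, alignment.

Alignment is either the built-in exact substring aligner (sense strand,
unique placements only) or ingestion of SAM/BAM produced by an external
aligner against the same transcriptome reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotation_io import AnnotationSet
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

# seed length for the exact aligner's k-mer index; reads shorter than this
# fall back to a naive per-transcript scan
SEED_K = 15

DEFAULT_LMIN, DEFAULT_LMAX = 15, 50
FOOTPRINT_LMIN, FOOTPRINT_LMAX = 25, 35


class SequencedRead(NamedTuple):
    read_id: str
    bases: str
    quals: str

    def __len__(self) -> int:
        return len(self.bases)


class Alignment(NamedTuple):
    """A read placed on a transcript: the atomic observation.

    pos_5p is the 0-based transcript coordinate of the read's 5' end.
    """

    read_id: str
    gene_id: str
    pos_5p: int
    read_length: int


@dataclass
class PrepStats:
    """Read accounting across the preparation stages.

    Partition invariant:
    n_input == n_too_short + n_rrna_removed + n_unaligned + n_multimapped
    + n_accepted. n_adapter_trimmed is informational (not part of the
    partition: a trimmed read continues through the pipeline).
    """

    n_input: int = 0
    n_adapter_trimmed: int = 0
    n_too_short: int = 0
    n_rrna_removed: int = 0
    n_unaligned: int = 0
    n_multimapped: int = 0
    n_accepted: int = 0

    def check_partition(self) -> None:
        total = (
            self.n_too_short + self.n_rrna_removed + self.n_unaligned
            + self.n_multimapped + self.n_accepted
        )
        if total != self.n_input:
            raise DataError(
                f"PrepStats partition violated: {total} != n_input {self.n_input}"
            )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_adapter_trimmed": self.n_adapter_trimmed,
            "n_too_short": self.n_too_short,
            "n_rrna_removed": self.n_rrna_removed,
            "n_unaligned": self.n_unaligned,
            "n_multimapped": self.n_multimapped,
            "n_accepted": self.n_accepted,
        }


# ---------------------------------------------------------------------------
# FASTQ I/O

def read_fastq(path) -> list[SequencedRead]:
    """Read a FASTQ (Phred+33) file into SequencedReads."""
    reads = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            reads.append(SequencedRead(title.split()[0], seq.upper(), qual))
    return reads


def write_fastq(reads: Iterable[SequencedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{r.quals}\n")


# ---------------------------------------------------------------------------
# Adapter trimming

def trim_adapter(
    read: SequencedRead,
    adapter: str,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.1,
) -> tuple[SequencedRead, bool]:
    """Trim a 3' sequencing adapter from a read.

    Scanning 5'→3', the first position where the read's remaining suffix
    matches a prefix of the adapter (overlap ≥ min_overlap, mismatch
    fraction ≤ max_mismatch_rate) wins: everything from that position on is
    removed. A full internal adapter occurrence is the special case where
    the overlap spans the whole adapter. An empty read may result; callers
    filter by length.
    """
    if not 1 <= min_overlap <= len(adapter):
        raise ConfigError("require adapter length >= min_overlap >= 1")
    bases, quals = read.bases, read.quals
    n, m = len(bases), len(adapter)
    for i in range(0, n - min_overlap + 1):
        overlap = min(m, n - i)
        max_mm = int(max_mismatch_rate * overlap)
        mm = 0
        for j in range(overlap):
            if bases[i + j] != adapter[j]:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return SequencedRead(read.read_id, bases[:i], quals[:i]), True
    return read, False


# ---------------------------------------------------------------------------
# Filters

def filter_length(
    reads: Iterable[SequencedRead], lmin: int, lmax: int
) -> tuple[list[SequencedRead], int]:
    """Keep reads with lmin <= length <= lmax; return (kept, discarded_count)."""
    if lmin > lmax:
        raise ConfigError(f"lmin {lmin} > lmax {lmax}")
    kept, discarded = [], 0
    for r in reads:
        if lmin <= len(r.bases) <= lmax:
            kept.append(r)
        else:
            discarded += 1
    return kept, discarded


def build_kmer_set(seqs: Iterable[str], k: int) -> set[str]:
    kmers: set[str] = set()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            kmers.add(seq[i : i + k])
    return kmers


def load_contaminants(fasta_path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")]


def filter_rrna(
    reads: Iterable[SequencedRead],
    contaminant_seqs: Iterable[str],
    k: int = 15,
) -> tuple[list[SequencedRead], int]:
    """Remove reads sharing at least one exact k-mer with any contaminant.

    Reads are sense-strand by library design, so only the given strand of
    each read is checked. An empty contaminant set passes everything
    through with a warning.
    """
    contaminant_seqs = list(contaminant_seqs)
    if not contaminant_seqs:
        logger.warning("empty contaminant set: rRNA filter is a no-op")
        return list(reads), 0
    index = build_kmer_set(contaminant_seqs, k)
    kept, removed = [], 0
    for r in reads:
        bases = r.bases
        hit = any(
            bases[i : i + k] in index for i in range(len(bases) - k + 1)
        )
        if hit:
            removed += 1
        else:
            kept.append(r)
    return kept, removed


# ---------------------------------------------------------------------------
# Built-in exact aligner

def _build_seed_index(annotation: AnnotationSet, k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for gid, rec in annotation.records.items():
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((gid, i))
    return index


def _naive_occurrences(read: str, annotation: AnnotationSet) -> list[tuple[str, int]]:
    occ = []
    for gid, rec in annotation.records.items():
        start = rec.sequence.find(read)
        while start != -1:
            occ.append((gid, start))
            start = rec.sequence.find(read, start + 1)
    return occ


def align_exact(
    reads: Iterable[SequencedRead],
    annotation: AnnotationSet,
    stats: PrepStats | None = None,
) -> tuple[list[Alignment], PrepStats]:
    """Align reads as exact sense-strand substrings of the transcripts.

    A read with exactly one occurrence across all transcripts yields one
    Alignment; zero occurrences count as unaligned, two or more (any
    transcript, any position) as multimapped and discarded. Occurrence
    search is seed-and-verify on a k-mer index (k=15), which is exhaustive
    for reads of length >= 15; shorter reads use a naive scan.
    """
    reads = list(reads)
    if stats is None:
        stats = PrepStats(n_input=len(reads))
    index = _build_seed_index(annotation, SEED_K)
    alignments: list[Alignment] = []
    for r in reads:
        bases = r.bases
        if len(bases) < SEED_K:
            occ = _naive_occurrences(bases, annotation)
        else:
            occ = [
                (gid, pos)
                for gid, pos in index.get(bases[:SEED_K], ())
                if annotation.records[gid].sequence.startswith(bases, pos)
            ]
        if len(occ) == 1:
            gid, pos = occ[0]
            alignments.append(Alignment(r.read_id, gid, pos, len(bases)))
            stats.n_accepted += 1
        elif not occ:
            stats.n_unaligned += 1
        else:
            stats.n_multimapped += 1
    return alignments, stats


# ---------------------------------------------------------------------------
# SAM/BAM ingestion

def read_alignments_sam(
    path,
    annotation: AnnotationSet,
    lmin: int = DEFAULT_LMIN,
    lmax: int = DEFAULT_LMAX,
) -> tuple[list[Alignment], PrepStats]:
    """Ingest transcriptome alignments from SAM/BAM.

    Keeps primary, mapped, forward-strand, unclipped records whose length
    is within [lmin, lmax]. pos_5p is the 0-based leftmost position, so it
    always means the sequenced 5' terminus (hence the clip rejection).
    Secondary/supplementary records are skipped without counting: they
    duplicate a read already counted once. Reverse-strand and clipped
    records are tallied with the unaligned (no alignment is produced).
    """
    stats = PrepStats()
    alignments: list[Alignment] = []
    try:
        sam = pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot open alignments {path}: {exc}") from exc
    with sam:
        try:
            for rec in sam.fetch(until_eof=True):
                if rec.is_secondary or rec.is_supplementary:
                    continue
                stats.n_input += 1
                if rec.is_unmapped:
                    stats.n_unaligned += 1
                    continue
                if rec.is_reverse:
                    stats.n_unaligned += 1
                    continue
                cigar = rec.cigartuples or []
                if any(op in (4, 5) for op, _ in cigar):  # soft/hard clip
                    stats.n_unaligned += 1
                    continue
                gene_id = rec.reference_name
                if gene_id not in annotation:
                    raise DataError(
                        f"SAM reference {gene_id!r} absent from annotation"
                    )
                length = rec.query_length or rec.infer_query_length()
                if not lmin <= length <= lmax:
                    stats.n_too_short += 1
                    continue
                alignments.append(
                    Alignment(rec.query_name, gene_id, rec.reference_start, length)
                )
                stats.n_accepted += 1
        except OSError as exc:
            raise DataError(f"truncated or corrupt alignment file {path}") from exc
    return alignments, stats


# ---------------------------------------------------------------------------
# Stage composition & alignment TSV persistence

@dataclass
class PrepConfig:
    adapter: str | None = None
    min_overlap: int = 5
    max_mismatch_rate: float = 0.1
    lmin: int = DEFAULT_LMIN
    lmax: int = DEFAULT_LMAX
    rrna_k: int = 15


def prepare_reads(
    reads: Iterable[SequencedRead],
    annotation: AnnotationSet,
    cfg: PrepConfig | None = None,
    contaminants: Iterable[str] | None = None,
) -> tuple[list[Alignment], PrepStats, list[SequencedRead]]:
    """Run trim → length filter → rRNA filter → exact alignment.

    Returns the accepted alignments, the full PrepStats partition, and the
    post-trim reads that survived filtering (for nucleotide-bias QC).
    """
    cfg = cfg or PrepConfig()
    reads = list(reads)
    stats = PrepStats(n_input=len(reads))

    if cfg.adapter:
        trimmed = []
        for r in reads:
            r2, did = trim_adapter(r, cfg.adapter, cfg.min_overlap, cfg.max_mismatch_rate)
            if did:
                stats.n_adapter_trimmed += 1
            trimmed.append(r2)
        reads = trimmed

    reads, stats.n_too_short = filter_length(reads, cfg.lmin, cfg.lmax)
    if contaminants is not None:
        reads, stats.n_rrna_removed = filter_rrna(reads, contaminants, cfg.rrna_k)
    alignments, stats = align_exact(reads, annotation, stats)
    stats.check_partition()
    kept_ids = {a.read_id for a in alignments}
    kept_reads = [r for r in reads if r.read_id in kept_ids]
    return alignments, stats, kept_reads


def write_alignments_tsv(alignments: Iterable[Alignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgene_id\tpos_5p\tread_length\n")
        for a in alignments:
            fh.write(f"{a.read_id}\t{a.gene_id}\t{a.pos_5p}\t{a.read_length}\n")


def read_alignments_tsv(path) -> list[Alignment]:
    alignments = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["read_id", "gene_id", "pos_5p", "read_length"]:
            raise DataError(f"{path}: unexpected alignment TSV header {header}")
        for line in fh:
            rid, gid, pos, length = line.rstrip("\n").split("\t")
            alignments.append(Alignment(rid, gid, int(pos), int(length)))
    return alignments
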