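"""Metagene and QC statistics for footprint data.

Covers the standard ribosome-profiling diagnostic suite: reading-frame and
three-nucleotide-periodicity checks along ORFs, start/stop metagene
profiles, read-length distributions, positional distributions along ORF
lengths, position-specific nucleotide frequencies, and A-site assignment
from length-specific offsets.

Frame is defined on 5'-end positions, not A-sites, so the frame statistic
does not depend on the offset table it helps calibrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet, TranscriptRecord
from .errors import ConfigError, DataError
from .read_prep import Alignment, SequencedRead
from .ribogrid import DatasetStore

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATE_PERIODS = tuple(range(2, 11))
DEFAULT_PEAK_RATIO = 2.0
DEFAULT_MIN_READS = 64
BASES = ("A", "C", "G", "T", "N")


# ---------------------------------------------------------------------------
# A-site offsets

@dataclass(frozen=True)
class OffsetTable:
    """Read length → offset (nt) from the 5' end to the A-site codon start."""

    offsets: Mapping[int, int]

    def __post_init__(self) -> None:
        for length, off in self.offsets.items():
            if not 0 <= off < length:
                raise ConfigError(
                    f"offset {off} invalid for read length {length}"
                )

    def __contains__(self, read_length: int) -> bool:
        return read_length in self.offsets

    def __getitem__(self, read_length: int) -> int:
        return self.offsets[read_length]


def load_offsets(tsv_path) -> OffsetTable:
    df = pd.read_csv(tsv_path, sep="\t")
    if not {"read_length", "asite_offset"} <= set(df.columns):
        raise DataError(f"{tsv_path}: need read_length and asite_offset columns")
    return OffsetTable(dict(zip(df["read_length"].astype(int), df["asite_offset"].astype(int))))


def default_offsets() -> OffsetTable:
    """Packaged default: 15 nt for 28-30 nt footprints (yeast convention)."""
    with resources.files("riboprof.data").joinpath("asite_offsets.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return OffsetTable(dict(zip(df["read_length"].astype(int), df["asite_offset"].astype(int))))


OUTSIDE_ORF = -1  # codon_index marker for A-sites outside the ORF


def asite_assign(
    alignment: Alignment,
    offsets: OffsetTable,
    record: TranscriptRecord,
) -> tuple[int, int] | None:
    """Map an alignment to its A-site position and codon index.

    Returns (asite_pos, codon_index) where codon_index counts ORF codons
    from the start codon, or OUTSIDE_ORF when the A-site falls outside the
    ORF (stop codon included). Returns None when the read length has no
    offset (the caller counts skips).
    """
    if alignment.read_length not in offsets:
        return None
    asite_pos = alignment.pos_5p + offsets[alignment.read_length]
    start, stop = record.start_codon_pos, record.stop_codon_pos
    if start <= asite_pos < stop + 3:
        codon_index = (asite_pos - start) // 3
    else:
        codon_index = OUTSIDE_ORF
    return asite_pos, codon_index


# ---------------------------------------------------------------------------
# Frame distribution

@dataclass
class FrameDistribution:
    counts: np.ndarray        # length 3
    fractions: np.ndarray | None  # None when no eligible reads
    n_reads: int


def frame_distribution(
    store: DatasetStore,
    lengths: Iterable[int] | None = None,
) -> FrameDistribution:
    """Distribution of reading frames of 5' ends within ORFs.

    frame = (pos_5p − start_codon_pos) mod 3, over reads whose 5' end lies
    in [start_codon_pos, stop_codon_pos + 3). Translating footprints
    concentrate in frame 0; RNA-seq-like data is uniform across frames.
    """
    counts = np.zeros(3, dtype=np.int64)
    for gid, mat in store.matrices.items():
        fp = store.fingerprint[gid]
        start, stop = fp.start_codon_pos, fp.stop_codon_pos
        sub = _select_lengths(mat, lengths)
        pos_counts = sub[:, start : stop + 3].sum(axis=0)
        offsets = np.arange(pos_counts.size) % 3
        for f in range(3):
            counts[f] += int(pos_counts[offsets == f].sum())
    n = int(counts.sum())
    fractions = counts / n if n > 0 else None
    return FrameDistribution(counts=counts, fractions=fractions, n_reads=n)


def _select_lengths(mat, lengths: Iterable[int] | None) -> np.ndarray:
    if lengths is None:
        return mat.counts
    rows = []
    for L in lengths:
        if not mat.lmin <= L <= mat.lmax:
            raise DataError(f"length {L} outside store window [{mat.lmin},{mat.lmax}]")
        rows.append(L - mat.lmin)
    if not rows:
        raise DataError("empty length subset")
    return mat.counts[rows]


# ---------------------------------------------------------------------------
# Pooled positional profiles

def orf_profile(
    store: DatasetStore,
    lengths: Iterable[int] | None = None,
) -> np.ndarray:
    """Pooled 5'-end counts by position relative to the start codon, over ORFs.

    Position i holds the summed count at (start_codon_pos + i) across all
    genes whose ORF extends that far; the substrate for the periodicity
    spectrum.
    """
    max_orf = max(
        fp.orf_length for fp in store.fingerprint.values()
    )
    profile = np.zeros(max_orf, dtype=np.int64)
    for gid, mat in store.matrices.items():
        fp = store.fingerprint[gid]
        sub = _select_lengths(mat, lengths)
        orf_counts = sub[:, fp.start_codon_pos : fp.stop_codon_pos + 3].sum(axis=0)
        profile[: orf_counts.size] += orf_counts
    return profile


def start_anchored_profile(
    store: DatasetStore,
    window_up: int = 20,
    window_down: int = 100,
    lengths: Iterable[int] | None = None,
) -> pd.Series:
    """Pooled raw 5'-end counts in a window around the start codon.

    Unlike :func:`metagene_profile` this pools counts without per-gene
    normalisation, which makes peak-height ratios directly comparable to a
    generative model's density ratios.
    """
    positions = np.arange(-window_up, window_down + 1)
    pooled = np.zeros(positions.size, dtype=np.int64)
    for gid, mat in store.matrices.items():
        fp = store.fingerprint[gid]
        anchor = fp.start_codon_pos
        lo, hi = anchor - window_up, anchor + window_down + 1
        if lo < 0 or hi > mat.n_positions:
            continue
        sub = _select_lengths(mat, lengths)
        pooled += sub[:, lo:hi].sum(axis=0)
    return pd.Series(pooled, index=positions, name="count")


# ---------------------------------------------------------------------------
# Periodicity spectrum

@dataclass
class SpectrumResult:
    periods: np.ndarray
    power: np.ndarray
    dominant_period: int | None
    peak_to_mean: float


def _candidate_power(y: np.ndarray, periods: np.ndarray) -> np.ndarray:
    """DFT power of a mean-subtracted signal at frequency 1/p per period."""
    y = y - y.mean()
    x = np.arange(y.size)
    power = np.empty(periods.size)
    for i, p in enumerate(periods):
        z = np.exp(-2j * np.pi * x / p) @ y
        power[i] = (z.real**2 + z.imag**2) / y.size
    return power


def periodicity_spectrum(
    profile: Sequence[float],
    candidate_periods: Iterable[int] = DEFAULT_CANDIDATE_PERIODS,
    min_total: int = 100,
    peak_ratio_threshold: float = DEFAULT_PEAK_RATIO,
) -> SpectrumResult:
    """Detect the dominant spatial period of a positional count profile.

    Discrete Fourier power of the mean-subtracted profile is evaluated at
    each candidate period p (frequency 1/p cycles per nt). The dominant
    period is the argmax if its power is at least ``peak_ratio_threshold``
    times the mean power over candidates, else None; ties break toward the
    smaller period. Translating ribosomes produce period 3; RNA-seq-like
    coverage produces no dominant period.
    """
    y = np.asarray(profile, dtype=float)
    periods = np.array(sorted(set(int(p) for p in candidate_periods)))
    if periods.size < 2 or (periods < 2).any():
        raise ConfigError("need >= 2 candidate periods, all >= 2")
    if y.size < 3 * periods.max():
        raise DataError(
            f"profile length {y.size} < 3 x max candidate period {periods.max()}"
        )
    total = float(y.sum())
    if total < min_total:
        raise DataError(f"profile total {total} below min_total {min_total}")
    power = _candidate_power(y, periods)
    mean_power = power.mean()
    if mean_power <= 0:
        return SpectrumResult(periods, power, None, 0.0)
    best = int(np.argmax(power))  # argmax takes first maximum: smaller period
    ratio = float(power[best] / mean_power)
    ties = np.flatnonzero(power == power[best])
    if ties.size > 1:
        logger.info("periodicity tie among periods %s; choosing smallest",
                    periods[ties].tolist())
    dominant = int(periods[best]) if ratio >= peak_ratio_threshold else None
    return SpectrumResult(periods, power, dominant, ratio)


def dataset_periodicity(
    store: DatasetStore,
    candidate_periods: Iterable[int] = DEFAULT_CANDIDATE_PERIODS,
    min_reads: int = DEFAULT_MIN_READS,
    peak_ratio_threshold: float = DEFAULT_PEAK_RATIO,
    lengths: Iterable[int] | None = None,
) -> SpectrumResult:
    """Dataset-level periodicity by gene-averaged relative spectral power.

    For each gene with at least ``min_reads`` reads and an ORF long enough
    for the candidate periods, the DFT power of its mean-subtracted ORF
    5'-end profile is evaluated at the candidate periods and normalised by
    that gene's mean candidate power; the relative power vectors are then
    averaged with equal gene weight. Averaging over genes concentrates the
    noise spectrum near 1 (a Welch-style averaged periodogram), so the
    peak-to-mean decision rule separates codon-phased footprints (period 3)
    from RNA-seq-like coverage far more reliably than a single pooled
    profile, which carries a gene-length coverage trend.
    """
    periods = np.array(sorted(set(int(p) for p in candidate_periods)))
    if periods.size < 2 or (periods < 2).any():
        raise ConfigError("need >= 2 candidate periods, all >= 2")
    acc = np.zeros(periods.size)
    n_genes = 0
    for gid, mat in store.matrices.items():
        if mat.reads_total < min_reads:
            continue
        fp = store.fingerprint[gid]
        if fp.orf_length < 3 * periods.max():
            continue
        sub = _select_lengths(mat, lengths)
        y = sub[:, fp.start_codon_pos : fp.stop_codon_pos + 3].sum(axis=0).astype(float)
        power = _candidate_power(y, periods)
        mean_power = power.mean()
        if mean_power <= 0:
            continue
        acc += power / mean_power
        n_genes += 1
    if n_genes == 0:
        raise DataError(
            f"no genes eligible for periodicity (min_reads={min_reads})"
        )
    rel = acc / n_genes
    best = int(np.argmax(rel))
    ratio = float(rel[best] / rel.mean())
    dominant = int(periods[best]) if ratio >= peak_ratio_threshold else None
    return SpectrumResult(periods, rel, dominant, ratio)


# ---------------------------------------------------------------------------
# Metagene profiles

@dataclass
class MetageneProfile:
    anchor: str                # "start" | "stop"
    positions: np.ndarray      # relative to anchor, contiguous
    density: np.ndarray        # mean normalized density per position
    n_genes: int


def metagene_profile(
    store: DatasetStore,
    anchor: str = "start",
    window_up: int = 20,
    window_down: int = 60,
    min_reads: int = DEFAULT_MIN_READS,
) -> MetageneProfile:
    """Average normalized 5'-end density around the start or stop codon.

    For each eligible gene (total reads >= min_reads; window inside the
    transcript), the per-position count vector over the window is divided
    by that gene's mean count over the window, then genes are averaged
    with equal weight — so high-coverage genes do not dominate the shape.
    """
    if anchor not in ("start", "stop"):
        raise ConfigError(f"anchor must be 'start' or 'stop', got {anchor!r}")
    positions = np.arange(-window_up, window_down + 1)
    acc = np.zeros(positions.size)
    n_genes = 0
    n_skipped_window = n_skipped_reads = n_skipped_zero = 0
    for gid, mat in store.matrices.items():
        if mat.reads_total < min_reads:
            n_skipped_reads += 1
            continue
        fp = store.fingerprint[gid]
        a = fp.start_codon_pos if anchor == "start" else fp.stop_codon_pos
        lo, hi = a - window_up, a + window_down + 1
        if lo < 0 or hi > mat.n_positions:
            n_skipped_window += 1
            continue
        window = mat.counts[:, lo:hi].sum(axis=0).astype(float)
        mean = window.mean()
        if mean == 0:
            n_skipped_zero += 1
            continue
        acc += window / mean
        n_genes += 1
    if n_genes == 0:
        raise DataError(
            f"no genes eligible for metagene profile "
            f"(min_reads={min_reads}: {n_skipped_reads} below threshold, "
            f"{n_skipped_window} window out of bounds, {n_skipped_zero} empty windows)"
        )
    return MetageneProfile(anchor, positions, acc / n_genes, n_genes)


# ---------------------------------------------------------------------------
# Read length histogram / positional distribution

def read_length_hist(store: DatasetStore, gene: str | None = None) -> pd.Series:
    """Histogram of mapped read lengths, dataset-wide or for one gene."""
    lengths = np.arange(store.lmin, store.lmax + 1)
    if gene is not None:
        counts = store[gene].counts.sum(axis=1)
    else:
        counts = np.zeros(lengths.size, dtype=np.int64)
        for mat in store.matrices.values():
            counts += mat.counts.sum(axis=1)
    return pd.Series(counts, index=pd.Index(lengths, name="read_length"), name="count")


def positional_distribution(
    store: DatasetStore,
    n_bins: int = 50,
    min_reads: int = DEFAULT_MIN_READS,
) -> np.ndarray:
    """Mean distribution of 5'-end positions along ORF lengths.

    Each read's relative position (pos_5p − start)/orf_length is clipped
    to [0, 1) and binned into n_bins equal bins; per-gene bin vectors are
    normalised to unit mass and averaged with equal weight over genes with
    at least min_reads. The result sums to 1.
    """
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    acc = np.zeros(n_bins)
    n_genes = 0
    for gid, mat in store.matrices.items():
        if mat.reads_total < min_reads:
            continue
        fp = store.fingerprint[gid]
        pos_counts = mat.counts.sum(axis=0)
        positions = np.arange(mat.n_positions)
        # integer floor division keeps bin edges exact
        bins = (positions - fp.start_codon_pos) * n_bins // fp.orf_length
        bins = np.clip(bins, 0, n_bins - 1)
        vec = np.bincount(bins, weights=pos_counts, minlength=n_bins)
        total = vec.sum()
        if total == 0:
            continue
        acc += vec / total
        n_genes += 1
    if n_genes == 0:
        raise DataError(f"no genes with >= {min_reads} reads for positional distribution")
    return acc / n_genes


# ---------------------------------------------------------------------------
# Nucleotide frequencies

def nucleotide_freqs(
    alignments: Iterable[Alignment],
    reads: Iterable[SequencedRead] | Mapping[str, str],
    lmax: int,
) -> pd.DataFrame:
    """Position-specific base frequencies of mapped reads.

    Rows are read positions 1..lmax (5'→3'); columns A, C, G, T, N.
    Positions beyond a read's length do not contribute; each covered
    position's frequencies sum to 1. Flags library-preparation and
    sequencing biases (e.g. ligation preferences at read ends).
    """
    if isinstance(reads, Mapping):
        seq_by_id = dict(reads)
    else:
        seq_by_id = {r.read_id: r.bases for r in reads}
    counts = np.zeros((lmax, len(BASES)), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for a in alignments:
        bases = seq_by_id.get(a.read_id)
        if bases is None:
            raise DataError(f"no read sequence for aligned read {a.read_id!r}")
        for j, b in enumerate(bases[:lmax]):
            counts[j, base_idx.get(b, base_idx["N"])] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, np.nan)
    return pd.DataFrame(
        freqs, index=pd.Index(np.arange(1, lmax + 1), name="read_position"),
        columns=list(BASES),
    )


# ---------------------------------------------------------------------------
# Gene-specific view

def gene_profile(
    store: DatasetStore,
    gene: str,
    lengths: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Per-position 5'-end counts for one gene, summed over selected lengths.

    Positions are annotated relative to the start codon; the gene-level
    view of where reads of specific lengths fall along an ORF.
    """
    mat = store[gene]
    sub = _select_lengths(mat, lengths)
    fp = store.fingerprint[gene]
    return pd.DataFrame(
        {
            "position": np.arange(mat.n_positions) - fp.start_codon_pos,
            "count": sub.sum(axis=0),
        }
    )
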