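"""Synthetic transcriptomes and reads with known ground truth.

The generator emulates the statistical structure the QC suite assumes in
real footprint data: a read-length distribution with its mode at ~30 nt
(the footprint of a translating ribosome), codon-phased 5' ends with a
configurable frame fidelity, initiation/termination peaks, optional
position-specific base bias, adapter contamination, and rRNA contaminant
reads — plus uniform RNA-seq-like reads as the no-periodicity control.
Every emitted read is recorded in a truth table so each pipeline stage can
be verified exactly.

All generators are pure functions of (annotation, config, seed); each
stage derives its own numpy Generator from the single config seed so the
fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .annotation_io import AnnotationSet, TranscriptRecord, write_transcriptome
from .errors import ConfigError, DataError
from .read_prep import SequencedRead

NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
STOP_CODONS = ("TAA", "TAG", "TGA")

# stage tags for per-stage RNG substreams derived from the config seed
_STAGE = {"transcriptome": 1, "weights": 2, "footprints": 3,
          "rnaseq": 4, "contaminate": 5, "rrna": 6}

DEFAULT_LENGTH_DIST = {28: 0.10, 29: 0.20, 30: 0.40, 31: 0.20, 32: 0.10}
# the linker historically used in yeast footprinting libraries
DEFAULT_ADAPTER = "CTGTAGGCACCATCAAT"


@dataclass
class SimConfig:
    """Parameters of the synthetic study conditions.

    asite_offset is the generator's internal distance (nt) from a
    footprint's 5' end to the A-site codon start; it matches the packaged
    default offset table so downstream A-site assignment is consistent.
    """

    n_genes: int = 100
    orf_length_range: tuple[int, int] = (80, 500)   # codons, stop included
    buffer_left: int = 25
    buffer_right: int = 25
    n_reads: int = 50_000
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    frame_fidelity: float = 0.9
    start_peak_factor: float = 5.0
    stop_peak_factor: float = 3.0
    asite_offset: int = 15
    nuc_bias: dict[int, dict[str, float]] | None = None
    adapter: str | None = None
    adapter_fraction: float = 1.0
    rrna_fraction: float = 0.0
    n_rrna_seqs: int = 2
    rrna_length: int = 2000
    gene_weight_sigma: float = 1.0   # lognormal sigma of per-gene abundance
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array(list(self.length_distribution.values()))
        if not np.isclose(probs.sum(), 1.0):
            raise ConfigError("length_distribution probabilities must sum to 1")
        if not 0.0 <= self.frame_fidelity <= 1.0:
            raise ConfigError("frame_fidelity must be in [0, 1]")
        if self.start_peak_factor < 1 or self.stop_peak_factor < 1:
            raise ConfigError("peak factors must be >= 1")
        if not 0.0 <= self.rrna_fraction <= 1.0:
            raise ConfigError("rrna_fraction must be in [0, 1]")
        if self.nuc_bias:
            for pos, dist in self.nuc_bias.items():
                if pos < 1:
                    raise ConfigError("nuc_bias positions are 1-based")
                if sum(dist.values()) > 1 + 1e-9:
                    raise ConfigError(f"nuc_bias at position {pos} exceeds 1")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["orf_length_range"] = list(self.orf_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "orf_length_range" in d:
            d["orf_length_range"] = tuple(d["orf_length_range"])
        if "length_distribution" in d:
            d["length_distribution"] = {
                int(k): float(v) for k, v in d["length_distribution"].items()
            }
        if d.get("nuc_bias"):
            d["nuc_bias"] = {
                int(k): {str(b): float(p) for b, p in v.items()}
                for k, v in d["nuc_bias"].items()
            }
        return cls(**d)


def _rng(cfg: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2**31), _STAGE[stage]])


# ---------------------------------------------------------------------------
# Transcriptome

def generate_transcriptome(cfg: SimConfig) -> dict[str, TranscriptRecord]:
    """Random ORF-centric transcripts: ATG start, sense codons, one stop.

    Internal in-frame stop codons cannot occur by construction (codons are
    drawn from the 61 sense codons); the terminal codon is a random stop.
    Buffers are uniform random sequence of the configured fixed widths.
    """
    rng = _rng(cfg, "transcriptome")
    lo, hi = cfg.orf_length_range
    if lo < 3 or hi < lo:
        raise ConfigError(f"bad orf_length_range {cfg.orf_length_range}")
    records: dict[str, TranscriptRecord] = {}
    bases = np.array(list("ACGT"))
    for i in range(cfg.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        idx = rng.integers(0, len(NON_STOP_CODONS), size=n_codons - 2)
        body = "".join(NON_STOP_CODONS[j] for j in idx)
        orf = "ATG" + body + STOP_CODONS[int(rng.integers(3))]
        utr5 = "".join(bases[rng.integers(0, 4, size=cfg.buffer_left)])
        utr3 = "".join(bases[rng.integers(0, 4, size=cfg.buffer_right)])
        gid = f"GSIM{i:04d}"
        records[gid] = TranscriptRecord(
            gene_id=gid,
            sequence=utr5 + orf + utr3,
            buffer_left=cfg.buffer_left,
            buffer_right=cfg.buffer_right,
            start_codon_pos=cfg.buffer_left,
            stop_codon_pos=cfg.buffer_left + n_codons * 3 - 3,
            orf_length=n_codons * 3,
        )
    return records


def plant_duplicate_block(
    records: dict[str, TranscriptRecord],
    src_gene: str,
    dst_gene: str,
    n_codons: int = 20,
) -> dict[str, TranscriptRecord]:
    """Copy a codon-aligned ORF block from one gene into another.

    Produces deliberate multimapping fixtures: reads drawn from the block
    occur in both genes. Codon alignment keeps the no-internal-stop
    invariant intact. Returns a new records dict.
    """
    src, dst = records[src_gene], records[dst_gene]
    if src.n_codons - 2 < n_codons or dst.n_codons - 2 < n_codons:
        raise ConfigError("ORFs too short for the requested duplicate block")
    block = src.orf[3 : 3 + n_codons * 3]
    new_orf = dst.orf[:3] + block + dst.orf[3 + n_codons * 3 :]
    new_seq = dst.utr5 + new_orf + dst.utr3
    out = dict(records)
    out[dst_gene] = TranscriptRecord(
        gene_id=dst.gene_id, sequence=new_seq,
        buffer_left=dst.buffer_left, buffer_right=dst.buffer_right,
        start_codon_pos=dst.start_codon_pos, stop_codon_pos=dst.stop_codon_pos,
        orf_length=dst.orf_length,
    )
    return out


def gene_weights(annotation: AnnotationSet, cfg: SimConfig) -> pd.Series:
    """Deterministic per-gene abundance weights (lognormal), normalised."""
    rng = _rng(cfg, "weights")
    gids = sorted(annotation.records)
    w = rng.lognormal(mean=0.0, sigma=cfg.gene_weight_sigma, size=len(gids))
    return pd.Series(w / w.sum(), index=gids)


# ---------------------------------------------------------------------------
# Footprints

def _codon_weights(record: TranscriptRecord, cfg: SimConfig) -> np.ndarray:
    u = np.ones(record.n_codons)
    u[0] = cfg.start_peak_factor
    u[-1] = cfg.stop_peak_factor
    return u


def expected_fiveprime_density(
    record: TranscriptRecord, cfg: SimConfig
) -> np.ndarray:
    """Exact per-position 5'-end probability for one gene's footprints.

    The generator's sampling model in closed form: the A-site codon is
    drawn with start/stop peak weights; with probability frame_fidelity
    the 5' end sits at (codon start − asite_offset), otherwise ±1 nt with
    equal probability. Valid whenever buffers cover the offset so no
    boundary resampling occurs (true under the defaults).
    """
    u = _codon_weights(record, cfg)
    p_codon = u / u.sum()
    density = np.zeros(record.length)
    f = cfg.frame_fidelity
    for k, pk in enumerate(p_codon):
        pos0 = record.start_codon_pos + 3 * k - cfg.asite_offset
        density[pos0] += f * pk
        density[pos0 - 1] += (1 - f) / 2 * pk
        density[pos0 + 1] += (1 - f) / 2 * pk
    return density


def _apply_nuc_bias(bases: str, bias: dict[int, dict[str, float]],
                    rng: np.random.Generator) -> str:
    chars = list(bases)
    for pos, dist in bias.items():
        if pos > len(chars):
            continue
        specified = list(dist.items())
        probs = [p for _, p in specified]
        rest = [b for b in "ACGT" if b not in dist]
        leftover = 1.0 - sum(probs)
        choices = [b for b, _ in specified] + rest
        probs = probs + ([leftover / len(rest)] * len(rest) if rest else [])
        chars[pos - 1] = choices[rng.choice(len(choices), p=np.array(probs) / sum(probs))]
    return "".join(chars)


def _emit_reads(
    annotation: AnnotationSet,
    cfg: SimConfig,
    rng: np.random.Generator,
    positional_model: str,
    id_prefix: str,
) -> tuple[list[SequencedRead], pd.DataFrame]:
    weights = gene_weights(annotation, cfg)
    gids = list(weights.index)
    lengths = np.array(sorted(cfg.length_distribution))
    length_probs = np.array([cfg.length_distribution[L] for L in lengths])

    codon_cum = {}
    if positional_model == "footprint":
        for gid in gids:
            u = _codon_weights(annotation[gid], cfg)
            codon_cum[gid] = np.cumsum(u / u.sum())

    gene_idx = rng.choice(len(gids), size=cfg.n_reads, p=weights.to_numpy())
    read_lengths = lengths[rng.choice(lengths.size, size=cfg.n_reads, p=length_probs)]

    reads: list[SequencedRead] = []
    truth_rows = []
    n_skipped = 0
    for i in range(cfg.n_reads):
        gid = gids[gene_idx[i]]
        rec = annotation[gid]
        L = int(read_lengths[i])
        pos = None
        for _ in range(10):  # bounded resampling at transcript edges
            if positional_model == "footprint":
                k = int(np.searchsorted(codon_cum[gid], rng.random()))
                cand = rec.start_codon_pos + 3 * k - cfg.asite_offset
                if rng.random() >= cfg.frame_fidelity:
                    cand += -1 if rng.random() < 0.5 else 1
            else:  # uniform RNA-seq-like
                cand = int(rng.integers(0, rec.length - L + 1))
            if 0 <= cand and cand + L <= rec.length:
                pos = cand
                break
        if pos is None:
            n_skipped += 1
            continue
        bases = rec.sequence[pos : pos + L]
        if cfg.nuc_bias:
            bases = _apply_nuc_bias(bases, cfg.nuc_bias, rng)
        with_adapter = bool(
            cfg.adapter and rng.random() < cfg.adapter_fraction
        )
        if with_adapter:
            bases = bases + cfg.adapter
        rid = f"{id_prefix}{i:07d}"
        reads.append(SequencedRead(rid, bases, "I" * len(bases)))
        truth_rows.append(
            {
                "read_id": rid,
                "origin": "gene",
                "gene_id": gid,
                "true_pos_5p": pos,
                "true_length": L,
                "frame": (pos - rec.start_codon_pos) % 3,
                "was_adapter_appended": with_adapter,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "origin", "gene_id", "true_pos_5p", "true_length",
                 "frame", "was_adapter_appended"],
    )
    truth.attrs["n_skipped"] = n_skipped
    return reads, truth


def simulate_footprints(
    annotation: AnnotationSet, cfg: SimConfig
) -> tuple[list[SequencedRead], pd.DataFrame]:
    """Footprint-like reads: codon-phased 5' ends, initiation/termination peaks."""
    return _emit_reads(annotation, cfg, _rng(cfg, "footprints"), "footprint", "fp")


def simulate_rnaseq(
    annotation: AnnotationSet, cfg: SimConfig
) -> tuple[list[SequencedRead], pd.DataFrame]:
    """RNA-seq-like reads: uniform positions, no frame structure."""
    return _emit_reads(annotation, cfg, _rng(cfg, "rnaseq"), "uniform", "rna")


# ---------------------------------------------------------------------------
# Contamination

def generate_rrna(annotation: AnnotationSet, cfg: SimConfig, k: int = 15) -> list[str]:
    """Random contaminant sequences sharing no k-mer with the transcriptome.

    Colliding k-mer windows are mutated until the sequences are k-mer
    disjoint from every transcript, so exact-k-mer contaminant filtering
    removes planted contaminant reads and nothing else.
    """
    rng = _rng(cfg, "rrna")
    forbidden: set[str] = set()
    for rec in annotation.records.values():
        seq = rec.sequence
        forbidden.update(seq[i : i + k] for i in range(len(seq) - k + 1))
    bases = "ACGT"
    seqs = []
    for _ in range(cfg.n_rrna_seqs):
        chars = [bases[j] for j in rng.integers(0, 4, size=cfg.rrna_length)]
        for _ in range(200):  # passes until k-mer clean
            dirty = False
            i = 0
            while i <= len(chars) - k:
                if "".join(chars[i : i + k]) in forbidden:
                    j = i + k // 2
                    chars[j] = bases[(bases.index(chars[j]) + 1 + int(rng.integers(3))) % 4]
                    dirty = True
                i += 1
            if not dirty:
                break
        else:
            raise DataError("could not make contaminant k-mer disjoint")
        seqs.append("".join(chars))
    return seqs


def contaminate(
    reads: list[SequencedRead],
    truth: pd.DataFrame,
    cfg: SimConfig,
    rrna_seqs: list[str],
) -> tuple[list[SequencedRead], pd.DataFrame]:
    """Replace a fraction of reads with verbatim contaminant substrings.

    Each read is independently replaced with probability rrna_fraction by
    a substring of one of ``rrna_seqs`` of the same total length; the
    truth table is updated (origin="rrna"). Fatal if a chosen contaminant
    is shorter than the read.
    """
    if cfg.rrna_fraction > 0 and not rrna_seqs:
        raise ConfigError("rrna_fraction > 0 requires rrna_seqs")
    rng = _rng(cfg, "contaminate")
    out_reads = list(reads)
    truth = truth.copy()
    replace = rng.random(len(reads)) < cfg.rrna_fraction
    for i in np.flatnonzero(replace):
        r = reads[i]
        L = len(r.bases)
        src = rrna_seqs[int(rng.integers(len(rrna_seqs)))]
        if len(src) < L:
            raise DataError(f"contaminant shorter than read length {L}")
        start = int(rng.integers(0, len(src) - L + 1))
        out_reads[i] = SequencedRead(r.read_id, src[start : start + L], r.quals)
        truth.iloc[i, truth.columns.get_loc("origin")] = "rrna"
        truth.iloc[i, truth.columns.get_loc("gene_id")] = ""
        truth.iloc[i, truth.columns.get_loc("true_pos_5p")] = -1
        truth.iloc[i, truth.columns.get_loc("frame")] = -1
        truth.iloc[i, truth.columns.get_loc("was_adapter_appended")] = False
    return out_reads, truth


# ---------------------------------------------------------------------------
# Truth table I/O

def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"read_id": str, "origin": str, "gene_id": str},
        keep_default_na=False,
    )


def expected_accepted_counts(
    truth: pd.DataFrame, lmin: int, lmax: int
) -> pd.Series:
    """Per-gene counts of non-contaminant, in-window truth reads.

    The reference for end-to-end truth recovery: with unique placements
    (the generated transcriptomes have no repeated blocks unless planted),
    these are exactly the reads the pipeline should accept per gene.
    """
    ok = (
        (truth["origin"] == "gene")
        & (truth["true_length"] >= lmin)
        & (truth["true_length"] <= lmax)
    )
    return truth.loc[ok].groupby("gene_id").size()
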