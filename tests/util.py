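"""Independent brute-force oracles and store-crafting helpers for tests.

Each oracle re-derives a quantity by the most direct method available
(exhaustive scan, explicit rank formula, autocorrelation) so that the
package implementation is checked against an independent path.
"""

import numpy as np

import riboprof as rp
from riboprof.ribogrid import DatasetStore, GeneCountMatrix, GeneFingerprint


def naive_occurrences(read_bases, records):
    """All (gene, position) occurrences of a read across transcripts."""
    hits = []
    for gid, rec in records.items():
        seq = rec.sequence
        for i in range(len(seq) - len(read_bases) + 1):
            if seq[i : i + len(read_bases)] == read_bases:
                hits.append((gid, i))
    return hits


def brute_trim(bases, adapter, min_overlap, max_mismatch_rate):
    """Exhaustive suffix-prefix adapter scan: leftmost qualifying cut."""
    n, m = len(bases), len(adapter)
    for i in range(n):
        overlap = min(m, n - i)
        if overlap < min_overlap:
            break
        mismatches = sum(
            1 for a, b in zip(bases[i : i + overlap], adapter[:overlap]) if a != b
        )
        if mismatches <= int(max_mismatch_rate * overlap):
            return bases[:i], True
    return bases, False


def average_ranks(values):
    """Average (midrank) ranks computed by explicit sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Spearman rho as the Pearson correlation of average ranks."""
    rx = np.array(average_ranks(list(x)))
    ry = np.array(average_ranks(list(y)))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def autocorr_dominant(profile, periods):
    """Dominant period by lag autocorrelation of the mean-subtracted profile."""
    y = np.asarray(profile, dtype=float)
    y = y - y.mean()
    scores = {p: float(y[:-p] @ y[p:]) for p in periods}
    return max(sorted(scores), key=lambda p: scores[p])


def tally_counts(truth, lmin, lmax):
    """Brute-force per-(gene, length, pos) tally from a truth table."""
    tally = {}
    for row in truth.itertuples():
        if row.origin != "gene" or not lmin <= row.true_length <= lmax:
            continue
        key = (row.gene_id, row.true_length, row.true_pos_5p)
        tally[key] = tally.get(key, 0) + 1
    return tally


def has_internal_stop(record):
    """Codon-scan: any in-frame stop before the terminal codon."""
    orf = record.orf
    for i in range(0, len(orf) - 3, 3):
        if orf[i : i + 3] in ("TAA", "TAG", "TGA"):
            return True
    return False


def make_store(gene_counts, start_codon_pos, orf_length, lmin, lmax,
               dataset_id="crafted"):
    """Craft a DatasetStore directly from count matrices.

    gene_counts: gene_id -> 2D int array [(lmax-lmin+1), n_positions].
    All genes share start_codon_pos/orf_length (scalars) or per-gene dicts.
    """
    matrices, fingerprint = {}, {}
    for gid, counts in gene_counts.items():
        counts = np.asarray(counts, dtype=np.int64)
        start = start_codon_pos[gid] if isinstance(start_codon_pos, dict) else start_codon_pos
        orf = orf_length[gid] if isinstance(orf_length, dict) else orf_length
        n_pos = counts.shape[1]
        matrices[gid] = GeneCountMatrix(gid, lmin, lmax, counts)
        fingerprint[gid] = GeneFingerprint(
            buffer_left=start,
            buffer_right=n_pos - start - orf,
            start_codon_pos=start,
            stop_codon_pos=start + orf - 3,
        )
    return DatasetStore(
        dataset_id=dataset_id, lmin=lmin, lmax=lmax,
        matrices=matrices, fingerprint=fingerprint,
    )
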