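# riboprof

A processing core for ribosome-profiling (riboseq) data: from raw
footprint or RNA-seq reads in FASTQ to per-gene read-length × position
count matrices (HDF5), metagene and periodicity QC, and RPKM
quantification with sequence-feature correlations.

## Who this is for

Ribosome profiling sequences the ~28–32 nt mRNA fragments protected by
translating ribosomes, giving a positional snapshot of translation.
Turning those reads into interpretable per-gene signals requires a chain
of domain-specific steps — adapter trimming, rRNA contaminant removal,
transcriptome alignment, A-site offset assignment, reading-frame QC —
that generic RNA-seq tooling does not provide. `riboprof` implements
that chain as a tested library plus a thin CLI, against an ORF-centric
reference (one transcript per gene: fixed-width UTR buffers flanking a
CDS from ATG through stop). A synthetic-data generator with a per-read
truth table makes every stage verifiable end to end without downloading
any dataset.

## The statistics at its core

* **Count matrices.** For each gene, reads are tallied into an integer
  matrix `C[l, x]` indexed by read length `l` and the 0-based transcript
  coordinate `x` of the read's 5′ end, persisted in HDF5. A-site
  positions are a downstream view: `a = x + δ(l)` with a per-length
  offset table `δ` (default 15 nt for 28–30-mers), so one store serves
  any offset convention.
* **Frame and periodicity.** Frame is `(x − x_start) mod 3` over 5′ ends
  inside the ORF. Three-nucleotide periodicity — the codon-step
  signature of translating ribosomes, absent from RNA-seq — is detected
  from discrete Fourier power at candidate periods 2–10 nt of
  mean-subtracted ORF count profiles, averaged over genes; a period is
  called dominant when its power is ≥ 2× the mean candidate power.
* **Metagene profiles.** Per-position 5′-end counts in a window around
  the start or stop codon, mean-normalised per gene then averaged with
  equal gene weight.
* **Quantification.** RPKM = 10⁹ · n_g / (N · L_g) with `n_g` the ORF
  5′-end count for gene g, `N` the dataset total, `L_g` the ORF length
  in nt; Spearman rank correlations relate RPKM to sequence features
  (ORF length, 5′ UTR length and GC, upstream ATG count, and externally
  supplied folding energies / poly-A lengths); relative abundance is
  log₂(RPKM / median reference-panel RPKM).

## Worked example

Run the full pipeline on a simulated dataset (15 genes, 4 000 footprint
reads with adapters and 10 % rRNA contamination):

```sh
riboprof all --outdir demo --seed 42 --dataset-id demo \
    --adapter CTGTAGGCACCATCAAT
```

or from Python:

```python
from riboprof.cli import RunConfig, run_all
cfg = RunConfig(outdir="demo", seed=42, dataset_id="demo",
                adapter="CTGTAGGCACCATCAAT",
                sim={"n_genes": 15, "n_reads": 4000, "rrna_fraction": 0.1,
                     "adapter": "CTGTAGGCACCATCAAT"})
results = run_all(cfg)
print(results["prep"])
print(results["qc"])
```

prints

```
{'n_input': 4000, 'n_adapter_trimmed': 3566, 'n_too_short': 0,
 'n_rrna_removed': 434, 'n_unaligned': 0, 'n_multimapped': 0,
 'n_accepted': 3566}
{'frame0_fraction': 0.8975552968568102, 'dominant_period': 3,
 'peak_to_mean': 8.043692113860569, 'metagene_start_n_genes': 11,
 'metagene_stop_n_genes': 11}
```

Reading: of 4 000 input reads, 434 planted rRNA contaminants were
removed and the remaining 3 566 aligned uniquely (the accounting always
partitions `n_input`). The QC recovers the generator's structure: ~90 %
of in-ORF 5′ ends fall in frame 0 (the simulation's frame fidelity is
0.9) and the dominant spectral period along ORFs is 3 nt. `demo/`
contains the HDF5 store, per-gene count TSVs, all QC tables
(`frame_distribution.tsv`, `periodicity_spectrum.tsv`,
`metagene_start.tsv`, …), `expression.tsv` (RPKM) and
`feature_correlations.tsv`, plus provenance JSONs.

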