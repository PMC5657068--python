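"""Metagene/QC statistics: frames, periodicity, profiles, biases, A-sites."""

import dataclasses

import numpy as np
import pytest

import riboprof as rp
from riboprof.errors import ConfigError, DataError
from riboprof.qc_metagene import (
    OUTSIDE_ORF, OffsetTable, asite_assign, dataset_periodicity, default_offsets,
    frame_distribution, gene_profile, load_offsets, metagene_profile,
    nucleotide_freqs, orf_profile, periodicity_spectrum,
    positional_distribution, read_length_hist, start_anchored_profile,
)
from riboprof.read_prep import Alignment, SequencedRead
from util import autocorr_dominant, make_store


class TestAsiteAssign:
    RECORD_KW = dict(gene_id="g", buffer_left=25, buffer_right=25,
                     start_codon_pos=25, orf_length=300, stop_codon_pos=322)

    @pytest.fixture()
    def record(self, annotation):
        return annotation[annotation.gene_ids[0]]

    def test_codon_index_arithmetic(self, record):
        offsets = OffsetTable({28: 15})
        a = Alignment("r", record.gene_id, 100, 28)
        asite_pos, codon = asite_assign(a, offsets, record)
        assert asite_pos == 115
        assert codon == (115 - record.start_codon_pos) // 3 == 30

    def test_outside_orf_marker(self, record):
        offsets = OffsetTable({28: 15})
        a = Alignment("r", record.gene_id, 0, 28)  # A-site at 15 < start 25
        _, codon = asite_assign(a, offsets, record)
        assert codon == OUTSIDE_ORF

    def test_missing_length_skipped(self, record):
        assert asite_assign(Alignment("r", record.gene_id, 100, 33),
                            OffsetTable({28: 15}), record) is None

    def test_packaged_default_offsets(self):
        offsets = default_offsets()
        assert all(offsets[L] == 15 for L in (28, 29, 30))
        assert 33 not in offsets

    def test_offset_table_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "off.tsv"
        p.write_text("read_length\tasite_offset\n28\t15\n31\t16\n")
        table = load_offsets(p)
        assert table[31] == 16

    def test_invalid_offset_rejected(self):
        with pytest.raises(ConfigError):
            OffsetTable({28: 28})


class TestFrameDistribution:
    def test_pure_frame0_store(self):
        counts = np.zeros((1, 400), dtype=np.int64)
        counts[0, 25:325:3] = 7  # all 5' ends at start + 3k
        store = make_store({"g": counts}, 25, 300, 28, 28)
        fd = frame_distribution(store)
        assert np.array_equal(fd.fractions, [1.0, 0.0, 0.0])

    def test_zero_reads_reported_missing(self):
        store = make_store({"g": np.zeros((1, 400), dtype=np.int64)}, 25, 300, 28, 28)
        fd = frame_distribution(store)
        assert fd.fractions is None and fd.n_reads == 0

    def test_uniform_positions_uniform_frames(self, annotation, sim_cfg):
        cfg = dataclasses.replace(sim_cfg, n_reads=30_000, seed=17)
        reads, _ = rp.simulate_rnaseq(annotation, cfg)
        alignments, _ = rp.align_exact(reads, annotation)
        store = rp.build_count_matrices(alignments, annotation, 15, 50)
        fd = frame_distribution(store)
        se = np.sqrt((1 / 3) * (2 / 3) / fd.n_reads)
        assert np.all(np.abs(fd.fractions - 1 / 3) < 4 * se)

    def test_frame_fidelity_recovered(self, footprint_run, sim_cfg):
        fd = frame_distribution(footprint_run["store"])
        p = sim_cfg.frame_fidelity
        se = np.sqrt(p * (1 - p) / fd.n_reads)
        assert abs(fd.fractions[0] - p) < 4 * se


class TestPeriodicitySpectrum:
    def test_period3_comb(self):
        profile = np.array([1 + (p % 3 == 0) for p in range(300)]) * 10
        res = periodicity_spectrum(profile)
        assert res.dominant_period == 3

    def test_constant_profile_none(self):
        res = periodicity_spectrum(np.full(300, 5))
        assert res.dominant_period is None

    # candidate harmonics matter: a period-4 comb puts equal DFT power at
    # its period-2 harmonic (ties break to the smaller period by contract),
    # so only harmonic-free periods identify uniquely
    @pytest.mark.parametrize("period", [2, 3, 5, 7])
    def test_comb_periods_match_autocorrelation_oracle(self, period):
        profile = np.array([5 + 3 * (p % period == 0) for p in range(300)])
        res = periodicity_spectrum(profile)
        assert res.dominant_period == period
        assert res.dominant_period == autocorr_dominant(profile, range(2, 11))
        # power at the true period strictly exceeds all other candidates
        best = res.power[list(res.periods).index(period)]
        assert all(best > pw for p, pw in zip(res.periods, res.power) if p != period)

    def test_short_profile_rejected(self):
        with pytest.raises(DataError, match="profile length"):
            periodicity_spectrum(np.ones(20))

    def test_low_total_rejected(self):
        with pytest.raises(DataError, match="min_total"):
            periodicity_spectrum(np.zeros(300), min_total=100)


class TestMetagene:
    def test_uniform_gene_flat_profile(self):
        counts = np.full((1, 400), 3, dtype=np.int64)
        store = make_store({"g": counts}, 25, 300, 28, 28)
        mp = metagene_profile(store, "start", window_up=20, window_down=60, min_reads=1)
        assert np.allclose(mp.density, 1.0)
        assert mp.positions[0] == -20 and mp.positions[-1] == 60

    def test_equal_weight_across_coverage(self):
        low = np.full((1, 400), 2, dtype=np.int64)
        high = np.full((1, 400), 20, dtype=np.int64)
        store = make_store({"lo": low, "hi": high}, 25, 300, 28, 28)
        mp = metagene_profile(store, "start", 20, 60, min_reads=1)
        assert np.allclose(mp.density, 1.0)
        assert mp.n_genes == 2

    def test_matches_hand_normalisation(self):
        rng = np.random.default_rng(3)
        c1 = rng.integers(0, 50, size=(1, 400))
        c2 = rng.integers(0, 50, size=(1, 400))
        store = make_store({"a": c1, "b": c2}, 25, 300, 28, 28)
        mp = metagene_profile(store, "start", 10, 30, min_reads=1)
        expected = np.zeros(41)
        for c in (c1, c2):
            window = c[0, 15:56].astype(float)
            expected += window / window.mean()
        assert np.allclose(mp.density, expected / 2)

    def test_stop_anchor_window(self):
        counts = np.zeros((1, 400), dtype=np.int64)
        counts[0, 322] = 90   # stop codon first base
        counts[0, 300:322] = 1
        store = make_store({"g": counts}, 25, 300, 28, 28)
        mp = metagene_profile(store, "stop", 20, 20, min_reads=1)
        assert mp.positions[np.argmax(mp.density)] == 0

    def test_zero_eligible_genes_error_names_threshold(self):
        store = make_store({"g": np.zeros((1, 400), dtype=np.int64)}, 25, 300, 28, 28)
        with pytest.raises(DataError, match="min_reads=64"):
            metagene_profile(store, "start", 20, 60)

    def test_simulated_initiation_peak_at_minus_offset(self, footprint_run, sim_cfg):
        mp = metagene_profile(footprint_run["store"], "start", 20, 60, min_reads=64)
        peak_pos = mp.positions[np.argmax(mp.density)]
        assert peak_pos == -sim_cfg.asite_offset


class TestStartPeakRecovery:
    def test_peak_factor_recovered_from_pooled_profile(self, footprint_run, sim_cfg):
        """Pooled 5'-end counts: start-codon peak / interior in-frame mean
        estimates the generator's start_peak_factor; 4 delta-method SEs."""
        pooled = start_anchored_profile(footprint_run["store"], 20, 100)
        x = float(pooled.loc[-sim_cfg.asite_offset])
        interior = np.array(
            [pooled.loc[-sim_cfg.asite_offset + 3 * k] for k in range(10, 35)]
        )
        s, m = interior.sum(), len(interior)
        est = x / (s / m)
        se = (m / s) * np.sqrt(x + x**2 / s)
        assert abs(est - sim_cfg.start_peak_factor) < 4 * se


class TestDistributions:
    def test_length_hist_conservation(self, footprint_run):
        store = footprint_run["store"]
        hist = read_length_hist(store)
        assert hist.sum() == store.reads_total
        gid = store.gene_ids[0]
        assert read_length_hist(store, gene=gid).sum() == store[gid].reads_total

    def test_length_hist_multinomial_recovery(self, footprint_run, sim_cfg):
        truth = footprint_run["truth"]
        n = len(truth)
        hist = truth["true_length"].value_counts()
        for L, p in sim_cfg.length_distribution.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(hist.get(L, 0) / n - p) < 4 * se

    def test_length_hist_unknown_gene_error(self, footprint_run):
        with pytest.raises(DataError):
            read_length_hist(footprint_run["store"], gene="NOPE")

    def test_positional_all_reads_at_start(self):
        counts = np.zeros((1, 400), dtype=np.int64)
        counts[0, 25] = 100
        store = make_store({"g": counts}, 25, 300, 28, 28)
        dist = positional_distribution(store, n_bins=50, min_reads=1)
        assert dist[0] == 1.0 and dist[1:].sum() == 0.0

    def test_positional_exact_uniform(self):
        counts = np.zeros((1, 950), dtype=np.int64)
        counts[0, 25:925] = 4  # uniform over a 900-nt ORF; 18 positions/bin
        store = make_store({"g": counts}, 25, 900, 28, 28)
        dist = positional_distribution(store, n_bins=50, min_reads=1)
        assert np.allclose(dist, 1 / 50)

    def test_positional_multinomial_bound(self):
        rng = np.random.default_rng(29)
        n, n_bins = 30_000, 50
        positions = rng.integers(25, 925, size=n)
        counts = np.zeros((1, 950), dtype=np.int64)
        np.add.at(counts[0], positions, 1)
        store = make_store({"g": counts}, 25, 900, 28, 28)
        dist = positional_distribution(store, n_bins=n_bins, min_reads=1)
        se = np.sqrt((1 / n_bins) * (1 - 1 / n_bins) / n)
        assert np.all(np.abs(dist - 1 / n_bins) < 4 * se)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)


class TestNucleotideFreqs:
    def test_all_a_reads(self):
        reads = [SequencedRead(f"r{i}", "A" * 28, "I" * 28) for i in range(5)]
        alignments = [Alignment(r.read_id, "g", 0, 28) for r in reads]
        nf = nucleotide_freqs(alignments, reads, 30)
        assert np.allclose(nf.loc[1:28, "A"], 1.0)
        assert nf.loc[29:30].isna().all().all()  # positions beyond all reads

    def test_rows_sum_to_one(self, footprint_run):
        nf = nucleotide_freqs(
            footprint_run["alignments"], footprint_run["kept"], 32
        )
        sums = nf.dropna().sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_position1_bias_recovered(self, annotation, sim_cfg):
        cfg = dataclasses.replace(
            sim_cfg, n_reads=20_000, seed=31, nuc_bias={1: {"G": 0.7}}
        )
        reads, truth = rp.simulate_footprints(annotation, cfg)
        # truth-backed alignments: the bias statistic must see all reads,
        # including those whose biased first base no longer matches the
        # transcript (an exact aligner would drop them)
        alignments = [
            Alignment(row.read_id, row.gene_id, row.true_pos_5p, row.true_length)
            for row in truth.itertuples()
        ]
        nf = nucleotide_freqs(alignments, reads, 32)
        se = np.sqrt(0.7 * 0.3 / len(reads))
        assert abs(nf.loc[1, "G"] - 0.7) < 4 * se


class TestGeneProfile:
    def test_full_range_equals_column_sums(self, footprint_run):
        store = footprint_run["store"]
        gid = store.gene_ids[0]
        prof = gene_profile(store, gid)
        assert np.array_equal(prof["count"].to_numpy(), store[gid].counts.sum(axis=0))
        start = store.fingerprint[gid].start_codon_pos
        assert prof["position"].iloc[0] == -start

    def test_single_length_equals_matrix_row(self, footprint_run):
        store = footprint_run["store"]
        gid = store.gene_ids[0]
        prof = gene_profile(store, gid, lengths=[28])
        assert np.array_equal(prof["count"].to_numpy(), store[gid].row(28))

    def test_slice_totals_match_alignment_filter(self, footprint_run):
        store = footprint_run["store"]
        gid = store.gene_ids[1]
        prof = gene_profile(store, gid, lengths=[29, 30])
        expected = sum(
            1 for a in footprint_run["alignments"]
            if a.gene_id == gid and a.read_length in (29, 30)
        )
        assert prof["count"].sum() == expected

    def test_errors(self, footprint_run):
        store = footprint_run["store"]
        with pytest.raises(DataError):
            gene_profile(store, "NOPE")
        with pytest.raises(DataError):
            gene_profile(store, store.gene_ids[0], lengths=[])


class TestPeriodicityContrast:
    """Footprint data shows period 3; RNA-seq-like data shows none."""

    def test_replicate_contrast(self, annotation, sim_cfg):
        fp_hits = rna_none = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = dataclasses.replace(sim_cfg, n_reads=8000, seed=100 + rep)
            for kind, sim in (("fp", rp.simulate_footprints), ("rna", rp.simulate_rnaseq)):
                reads, _ = sim(annotation, cfg)
                alignments, _ = rp.align_exact(reads, annotation)
                store = rp.build_count_matrices(alignments, annotation, 15, 50)
                res = dataset_periodicity(store)
                if kind == "fp" and res.dominant_period == 3:
                    fp_hits += 1
                if kind == "rna" and res.dominant_period is None:
                    rna_none += 1
        assert fp_hits >= int(0.95 * n_rep)
        assert rna_none >= int(0.95 * n_rep)

    def test_statistics_identical_after_h5_roundtrip(self, footprint_run, tmp_path):
        store = footprint_run["store"]
        rp.write_h5(store, tmp_path / "s.h5")
        loaded = rp.read_h5(tmp_path / "s.h5")
        a, b = frame_distribution(store), frame_distribution(loaded)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(orf_profile(store), orf_profile(loaded))
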