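import numpy as np
import pytest

import riboprof as rp


@pytest.fixture(scope="session")
def sim_cfg():
    return rp.SimConfig(n_genes=20, n_reads=5000, seed=11)


@pytest.fixture(scope="session")
def annotation_paths(tmp_path_factory, sim_cfg):
    d = tmp_path_factory.mktemp("annot")
    records = rp.generate_transcriptome(sim_cfg)
    fasta, gff = d / "t.fasta", d / "t.gff3"
    rp.write_transcriptome(records, fasta, gff)
    return records, fasta, gff


@pytest.fixture(scope="session")
def annotation(annotation_paths):
    _, fasta, gff = annotation_paths
    return rp.load_transcriptome(fasta, gff)


@pytest.fixture(scope="session")
def footprint_run(annotation, sim_cfg):
    """Simulated footprints pushed through prepare + count; plus truth."""
    reads, truth = rp.simulate_footprints(annotation, sim_cfg)
    alignments, stats, kept = rp.prepare_reads(reads, annotation)
    store = rp.build_count_matrices(
        alignments, annotation, 15, 50, dataset_id="fixture"
    )
    return {
        "reads": reads, "truth": truth, "alignments": alignments,
        "stats": stats, "kept": kept, "store": store,
    }
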