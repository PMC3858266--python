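import pytest

from srnaome.simulate import paired_embryo_config, simulate_pair


@pytest.fixture(scope="session")
def small_sim():
    """A 20k-read study-structured pair for pipeline-level tests."""
    return simulate_pair(paired_embryo_config(seed=11, n_reads=20_000))


@pytest.fixture(scope="session")
def small_sim_dir(small_sim, tmp_path_factory):
    """The small simulated pair written out as pipeline input files."""
    from srnaome.io import write_catalog_fasta, write_fasta, write_fastq

    out = tmp_path_factory.mktemp("sim")
    for lib in ("dormant", "germinated"):
        write_fastq(small_sim.reads[lib], out / f"{lib}.fastq")
    write_catalog_fasta(small_sim.catalog, out / "catalog.fa")
    write_fasta(small_sim.scaffolds, out / "scaffolds.fa")
    return out
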