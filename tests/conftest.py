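import pytest
from hypothesis import HealthCheck, settings

from strictlnc.annotation_io import GenomicInterval, TranscriptModel
from strictlnc.synthetic_data import SimulationConfig, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_tx(tid, chrom, strand, exons, gene=None, seq=None):
    """Build a transcript from (start, end) exon tuples."""
    return TranscriptModel.build(
        tid,
        gene or tid.rsplit(".", 1)[0],
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        seq,
    )


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        seed=11,
        n_coding_genes=60,
        chrom_length_bp=200_000,
        n_modules=1,
        module_size=20,
        lncrnas_per_module=3,
        n_lincrna=6,
        n_nat=3,
        n_sense_exonic=3,
        n_intronic=3,
        n_dual=1,
        n_coding_contaminants=6,
        n_rescuable=2,
        n_trna_rrna_mimics=2,
        samples_per_tissue=4,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One full pipeline run on the default study-scale configuration."""
    from strictlnc.pipeline import PipelineConfig, run_all
    from strictlnc.synthetic_data import simulate_dataset as sim

    outdir = tmp_path_factory.mktemp("full_run")
    cfg = PipelineConfig(outdir=str(outdir), seed=3, write_data=False)
    report = run_all(cfg)
    dataset = sim(cfg.sim)
    return {"report": report, "outdir": outdir, "dataset": dataset, "config": cfg}
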