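import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from utarscan.coverage import BinnedCoverage
from utarscan.pipeline import PipelineConfig, run_pipeline
from utarscan.simulate import SimConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_track(counts, contig="chr1", strand="+", bin_size=50):
    counts = np.asarray(counts, dtype=np.int64)
    return BinnedCoverage(
        contig=contig,
        strand=strand,
        bin_size=bin_size,
        counts=counts,
        contig_length=len(counts) * bin_size,
    )


@pytest.fixture(scope="session")
def small_sim_config():
    """A reduced simulation for fast unit tests (not the study defaults)."""
    return SimConfig(
        seed=7, n_contigs=2, contig_length=120_000, n_genes=8, n_lnc=4,
        n_spots=50,
    )


@pytest.fixture(scope="session")
def default_run():
    """One full default-configuration pipeline run, shared across tests."""
    cfg = PipelineConfig(outdir=None, make_plots=False)
    cfg.sim.seed = 11
    return run_pipeline(cfg)
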