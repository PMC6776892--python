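import numpy as np
import pandas as pd
import pytest

from polyswitch.annotate import GeneAnnotation
from polyswitch.config import RunConfig, SimConfig
from polyswitch.simulate import simulate_genome, write_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast, small study: one chromosome, few domains and genes."""
    return SimConfig(
        n_chroms=1, chrom_length_bp=2_000_000, n_genes=60,
        n_common_domains=4, n_state_specific_domains=3,
        n_sensitive_genes=8, n_switch_genes=(2, 1),
        library_size=40_000, seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default study conditions written to disk, with a third EZH2
    replicate for validation checks; shared across tests."""
    outdir = tmp_path_factory.mktemp("default_dataset")
    cfg = SimConfig(seed=0)
    manifest = write_dataset(cfg, outdir, extra_ezh2_replicates=1)
    return cfg, outdir, manifest


@pytest.fixture()
def toy_annotation() -> GeneAnnotation:
    return GeneAnnotation(pd.DataFrame([
        {"gene": "gA", "chrom": "chr1", "start": 10_000, "end": 12_000,
         "strand": "+", "tss": 10_000, "length_bp": 2_000},
        {"gene": "gB", "chrom": "chr1", "start": 20_000, "end": 22_000,
         "strand": "-", "tss": 21_999, "length_bp": 2_000},
        {"gene": "gC", "chrom": "chr2", "start": 5_000, "end": 8_000,
         "strand": "+", "tss": 5_000, "length_bp": 3_000},
    ]))
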