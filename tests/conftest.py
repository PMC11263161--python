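import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))

from hapsv.caller import run_call
from hapsv.svbench import bench
from hapsv.synthsv import SimConfig, simulate_dataset

#: study conditions for the clean end-to-end recovery check: 2 Mb single
#: chromosome, 10 SVs per type at 50% heterozygosity, 20x depth, exact
#: breakpoints, perfect tagging
CLEAN_CONFIG = dict(
    genome_length=2_000_000,
    n_chroms=1,
    n_del=10,
    n_ins=10,
    n_dup=10,
    n_inv=10,
    het_fraction=0.5,
    depth=20.0,
    read_length=10_000,
    pos_jitter_sd=0.0,
    len_jitter_sd=0.0,
    tag_rate=1.0,
    mistag_rate=0.0,
)

#: noisy variant of the same genome: breakpoint jitter, imperfect tagging
NOISY_CONFIG = dict(
    CLEAN_CONFIG,
    pos_jitter_sd=30.0,
    len_jitter_sd=15.0,
    tag_rate=0.85,
    mistag_rate=0.02,
)


def run_clean_pipeline(out_dir: str, seed: int) -> dict:
    """simulate -> call -> bench on the clean study conditions."""
    cfg = SimConfig(**CLEAN_CONFIG, seed=seed)
    paths = simulate_dataset(cfg, out_dir)
    calls_vcf = os.path.join(out_dir, "calls.vcf")
    run_call(paths["bam"], calls_vcf, reference=paths["reference"])
    return bench(calls_vcf, paths["truth"], dup_to_ins=True)


@pytest.fixture(scope="session")
def clean_report(tmp_path_factory):
    out = tmp_path_factory.mktemp("clean_e2e")
    return run_clean_pipeline(str(out), seed=20_250_920)
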