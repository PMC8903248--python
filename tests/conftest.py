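"""Shared fixtures.

The expensive simulated-genome pipeline runs once per session; unit tests
use small purpose-built inputs instead.
"""

from __future__ import annotations

import pytest

from packtype.pipeline import annotate
from packtype.synthetic_data import default_config, generate_genome

#: One fixed seed for the canonical benchmark genome used across the suite.
BENCH_SEED = 1


@pytest.fixture(scope="session")
def bench_sim():
    """Canonical 1 Mb benchmark genome: 60 members / 6 families, 20 outward
    decoys, 5 singletons, 5 N-rich elements."""
    config = default_config(BENCH_SEED)
    genome, truth, cds_db, transposase_db = generate_genome(config)
    return {
        "config": config,
        "genome": genome,
        "truth": truth,
        "cds_db": cds_db,
        "transposase_db": transposase_db,
    }


@pytest.fixture(scope="session")
def bench_annotation(bench_sim):
    """Full pipeline output (internal similarity backend) on the canonical
    benchmark genome."""
    return annotate(
        bench_sim["genome"],
        bench_sim["config"].queries(),
        transposase_db=bench_sim["transposase_db"],
        cds_db=bench_sim["cds_db"],
        genome_prefix="Sx",
    )
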