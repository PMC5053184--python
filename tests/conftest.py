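"""Shared fixtures: one small simulated study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from rrbskit import bsalign, filtering, simdata
from rrbskit.config import GenomeParams, SimulationConfig


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=3,
        samples=("A", "B", "C"),
        genome=GenomeParams(n_chromosomes=1, chromosome_bp=200_000),
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simdata.generate_genome(small_config)


@pytest.fixture(scope="session")
def small_landscape(small_config, small_genome):
    return simdata.sample_landscape(small_genome, small_config)


@pytest.fixture(scope="session")
def small_fragments(small_config, small_genome):
    return simdata.mspi_digest(small_genome, small_config.size_range)


@pytest.fixture(scope="session")
def small_index(small_config, small_genome):
    return bsalign.build_index(small_genome, small_config.read_length)


@pytest.fixture(scope="session")
def small_reads(small_config, small_genome, small_landscape, small_fragments):
    """Per-sample (reads, sidecar) for the three-sample toy study."""
    return {
        s: simdata.simulate_reads(
            small_fragments, small_landscape, small_config, s, small_genome)
        for s in small_config.samples
    }


@pytest.fixture(scope="session")
def small_reports(small_config, small_genome, small_index, small_reads):
    """Unfiltered per-cytosine reports per sample."""
    out = {}
    for s, (reads, _side) in small_reads.items():
        alns, _stats = bsalign.map_reads(reads, small_index)
        out[s] = bsalign.call_cytosines(alns, reads, small_genome)
    return out


@pytest.fixture(scope="session")
def filtered_reports(small_reports):
    return {s: filtering.filter_coverage(r, 8) for s, r in small_reports.items()}


def synthetic_report(positions, levels, coverage=100, chrom="chr1", strand="+",
                     context="CG"):
    """Build a valid report whose levels approximate ``levels`` at the given
    integer coverage (level is exactly count_meth / coverage)."""
    from rrbskit.types import make_report

    positions = np.asarray(positions)
    levels = np.asarray(levels, dtype=float)
    meth = np.rint(levels * coverage).astype(int)
    return make_report(pd.DataFrame({
        "chrom": chrom, "pos": positions, "strand": strand, "context": context,
        "count_meth": meth, "count_unmeth": coverage - meth,
    }))
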