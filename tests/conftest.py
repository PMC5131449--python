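import numpy as np
import pytest

import fourc as fc


@pytest.fixture(scope="session")
def toy_library():
    """100 kbp single-chromosome genome with its fragend library."""
    cfg = fc.SimConfig(seed=1, chromosome_length=100_000, gatc_density=4.0)
    genome = fc.generate_genome(cfg)
    return fc.build_fragend_library(genome)


@pytest.fixture(scope="session")
def recovery_library():
    """1 Mbp genome used by the planted-interaction recovery simulations."""
    cfg = fc.SimConfig(seed=7, chromosome_length=1_000_000, gatc_density=4.0)
    genome = fc.generate_genome(cfg)
    return fc.build_fragend_library(genome)


@pytest.fixture(scope="session")
def strong_study():
    """Strong-effect synthetic study: three viewpoints, one per chromosome,
    near-deterministic planted contacts, every locus active, every target
    expressed. The candidate set should equal the planted targets exactly."""
    cfg = fc.SimConfig(
        seed=11,
        n_chromosomes=3,
        chromosome_length=1_200_000,
        gatc_density=4.0,
        background_coverage=0.02,
        viewpoint_decay_halflife=20_000,
        n_viewpoints=3,
        n_cell_types=2,
    )
    return fc.simulate_study(cfg, contact_coverage=0.95)


def make_profile(status, spacing=125, chrom="chr1", vp_pos=None, snp_id="rsX"):
    """Coverage profile on an evenly spaced synthetic fragend grid."""
    status = np.asarray(status, dtype=np.int64)
    starts = np.arange(len(status), dtype=np.int64) * spacing
    ends = starts + 16
    if vp_pos is None:
        vp_pos = int(starts[len(status) // 2]) if len(status) else 0
    vp = fc.ViewpointSpec(snp_id, chrom, int(vp_pos), "ACGTACGTACGTACGTACGT")
    return fc.CoverageProfile(vp, "ct1", chrom, starts, ends, status)
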