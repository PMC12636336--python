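import numpy as np
import pytest

import funnelqtl as fq


@pytest.fixture(scope="session")
def small_panel():
    """Two-chromosome founder panel shared across the suite."""
    return fq.make_founders(
        chromosomes=[("chr01", 150_000), ("chr02", 150_000)], seed=101
    )


@pytest.fixture(scope="session")
def haps2000(small_panel):
    """2000-strain funnel-cross population on the small panel."""
    return fq.simulate_funnel_cross(small_panel, 2000, seed=102)


@pytest.fixture(scope="session")
def scaffold_idx(haps2000):
    return np.flatnonzero(haps2000.markers.scaffold)


def plant(haps, marker_index, pattern, effects, target_h2=None,
          noise_sd=1.0, seed=0):
    """Phenotype with one causal locus at a marker of ``haps``."""
    chrom = haps.markers.chrom[marker_index]
    pos = int(haps.markers.pos[marker_index])
    arch = fq.TraitArchitecture(
        [fq.CausalLocus(chrom, pos, pattern, effects)],
        strain_noise_sd=noise_sd, target_h2=target_h2,
    )
    return fq.phenotype_from_architecture(haps, arch, seed=seed)
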