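import numpy as np
import pytest

from kscreen import GenotypePanel, HaplotypePanelSpec, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """Block-LD panel small enough for per-test knockoff generation."""
    return simulate_genotypes(HaplotypePanelSpec(n=600, p=60, seed=7))


def make_panel(dosages, positions=None, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=float)
    p = dosages.shape[1]
    if positions is None:
        positions = np.arange(1, p + 1) * 100
    return GenotypePanel(
        dosages=dosages,
        positions=np.asarray(positions),
        chrom=np.repeat(chrom, p),
        variant_ids=np.array([f"v{j}" for j in range(p)], dtype=object),
    )
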