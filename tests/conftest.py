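import numpy as np
import pytest

from estuarscan.io import GenotypeMatrix


def make_gm(codes, positions=None, chrom="chr1", pops=None):
    """Build a GenotypeMatrix from a plain code list (variants x samples)."""
    codes = np.asarray(codes, dtype=np.int8)
    v, s = codes.shape
    if positions is None:
        positions = np.arange(v) * 10
    samples = [f"s{i}" for i in range(s)]
    if pops is None:
        pops = {smp: "P1" for smp in samples}
    else:
        pops = {smp: p for smp, p in zip(samples, pops)}
    return GenotypeMatrix(
        np.repeat(chrom, v), np.asarray(positions, dtype=np.int64),
        np.repeat("A", v), np.repeat("T", v), codes, samples, pops)


@pytest.fixture
def gm_factory():
    return make_gm


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
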