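import numpy as np
import pytest

from cforigin.atlas import CellTypeMethylome


def make_methylome(cell_type, sample_id, betas, positions=None, chrom="chr1", depth=30):
    """Build a one-chromosome methylome from a beta vector."""
    betas = np.asarray(betas, dtype=float)
    if positions is None:
        positions = np.arange(len(betas)) * 25
    return CellTypeMethylome.from_arrays(
        cell_type, sample_id,
        np.repeat(chrom, len(betas)), np.asarray(positions), betas,
        np.full(len(betas), depth),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_methylomes(rng):
    """3 cell types x 2 samples x 40 CpGs of random betas (tie-free noise)."""
    out = []
    for ct in ("MK", "erythroblast", "granulocyte"):
        for s in range(2):
            out.append(make_methylome(ct, f"{ct}_{s}", rng.uniform(0, 1, 40)))
    return out
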