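import numpy as np
import pytest

from bindshift.model import BindingModel
from bindshift.motifs import bundled_halfsite_pwm
from bindshift.reads import ReadDataset


@pytest.fixture(scope="session")
def halfsite_pwm():
    return bundled_halfsite_pwm()


@pytest.fixture
def triangular_model():
    """Symmetric triangular binding model on +-200 (mass ~ 200 - |x|)."""
    offs = np.arange(-200, 201)
    mass = (200 - np.abs(offs)).astype(float)
    return BindingModel(mass / mass.sum())


def make_reads(chrom_lengths, reads):
    """Build a ReadDataset from [(chrom, pos, strand_char), ...]."""
    pos: dict[str, list[int]] = {}
    strand: dict[str, list[int]] = {}
    for chrom, p, st in reads:
        pos.setdefault(chrom, []).append(p)
        strand.setdefault(chrom, []).append(1 if st == "+" else -1)
    return ReadDataset(
        dict(chrom_lengths),
        {c: np.array(v, dtype=np.int64) for c, v in pos.items()},
        {c: np.array(v, dtype=np.int8) for c, v in strand.items()},
    )
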