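import numpy as np
import pytest

from sweepmap.io import GenotypeMatrix


def make_genotypes(dosage, groups=None, chrom=None, pos=None, ref=None, alt=None):
    """Small GenotypeMatrix from a raw dosage array (samples x sites)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if groups is None:
        half = n // 2
        groups = ["A"] * half + ["B"] * (n - half)
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        group=np.asarray(groups, dtype=object),
        chrom=np.asarray(chrom),
        pos=np.asarray(pos),
        ref=np.asarray(ref if ref is not None else ["A"] * m, dtype=object),
        alt=np.asarray(alt if alt is not None else ["G"] * m, dtype=object),
        dosage=dosage,
    )


def random_genotypes(rng, n=20, m=50, missing=0.0, groups=None):
    p = rng.uniform(0.1, 0.9, size=m)
    dose = (rng.random((n, m)) < p).astype(float) + (rng.random((n, m)) < p)
    if missing:
        mask = rng.random((n, m)) < missing
        dose[mask] = np.nan
    return make_genotypes(dose, groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
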