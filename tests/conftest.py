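import numpy as np
import pytest

from wellmut.plate import PlateLayout
from wellmut.welldata import CandidateVariant


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_variant(rng, layout=None, p_covered=0.15, p_var=0.05,
                   mean_reads=4.0, chrom="chr1", pos=1000):
    """A random plate of well evidence, unrelated to the simulator."""
    layout = layout or PlateLayout()
    n = layout.n_wells
    covered = rng.random(n) < p_covered
    ref = np.where(covered, rng.poisson(mean_reads, n), 0)
    has_var = covered & (rng.random(n) < p_var / p_covered)
    var = np.where(has_var, rng.poisson(mean_reads / 2, n) + 1, 0)
    gt = np.full(n, -1, dtype=np.int8)
    both = (ref > 0) & (var > 0)
    gt[(ref > 0) & (var == 0)] = 0
    gt[both] = 1
    gt[(ref == 0) & (var > 0)] = 2
    # sprinkle genotype noise so genotype- and read-conditions diverge
    noisy = rng.random(n) < 0.05
    gt[noisy & (gt >= 0)] = rng.integers(0, 3, int((noisy & (gt >= 0)).sum()))
    bases = "ACGT"
    ctx = "".join(bases[i] for i in rng.integers(0, 4, 21))
    qf = {k: float(rng.uniform(0, 100)) for k in
          ("QUAL", "BRF", "FR", "HP", "HapScore", "MGOF", "MMLQ", "MQ",
           "QD", "SbPval", "NF", "NR", "TCF", "TCR")}
    return CandidateVariant(
        chrom=chrom, pos=pos, ref_allele=ctx[10], alt_allele="T" if ctx[10] != "T" else "A",
        qual_fields=qf, ref_reads=ref, var_reads=var, genotypes=gt,
        merged_ref_reads=int(ref.sum()), merged_var_reads=int(var.sum()),
        context21=ctx, layout=layout,
    )


@pytest.fixture
def variant_factory(rng):
    def make(**kw):
        return random_variant(rng, **kw)
    return make
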