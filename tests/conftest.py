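import numpy as np
import pytest

from introscan.simpop import SimConfig, simulate_cohort
from introscan.variantio import MISSING, VariantTable


def build_table(
    genotypes,
    pos=None,
    chrom="chr1",
    ref=None,
    alt=None,
    qual=None,
    fs=None,
    mq=None,
    gq=None,
    phased=None,
    sample_ids=None,
    chrom_lengths=None,
):
    """Hand-construct a VariantTable from a (sites x samples) genotype array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 10
    pos = np.asarray(pos, dtype=np.int64)
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n_samples)]

    def site_arr(x, default, dtype=float):
        if x is None:
            return np.full(n_sites, default, dtype=dtype)
        return np.asarray(x, dtype=dtype)

    ref_a = np.asarray(ref if ref is not None else ["A"] * n_sites, dtype=object)
    alt_a = np.asarray(alt if alt is not None else ["G"] * n_sites, dtype=object)
    return VariantTable(
        chrom=np.full(n_sites, chrom, dtype=object)
        if isinstance(chrom, str)
        else np.asarray(chrom, dtype=object),
        pos=pos,
        ref=ref_a,
        alt=alt_a,
        qual=site_arr(qual, 100.0),
        fs=site_arr(fs, 1.0),
        mq=site_arr(mq, 55.0),
        genotypes=g,
        gq=None if gq is None else np.asarray(gq, dtype=np.int16),
        phased_haplotypes=None if phased is None else np.asarray(phased, dtype=np.int8),
        sample_ids=list(sample_ids),
        chrom_lengths=chrom_lengths,
    )


def phased_table(haplotypes, pos=None, chrom="chr1", **kw):
    """Table from a (sites x haplotypes) 0/1 array (haplotypes paired)."""
    h = np.asarray(haplotypes, dtype=np.int8)
    assert h.shape[1] % 2 == 0
    g = h[:, 0::2] + h[:, 1::2]
    phased = np.stack([h[:, 0::2], h[:, 1::2]], axis=2)
    return build_table(g, pos=pos, chrom=chrom, phased=phased, **kw)


@pytest.fixture
def make_table():
    return build_table


@pytest.fixture
def make_phased_table():
    return phased_table


@pytest.fixture(scope="session")
def small_cohort():
    """A modest admixed cohort reused by read-only tests."""
    cfg = SimConfig(
        seq_length=5_000_000, n_oh=10, n_onl=12, n_onc=8, n_og=4, seed=11
    )
    table, truth = simulate_cohort(cfg)
    return cfg, table, truth
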