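import numpy as np
import pytest

from poolclover.datatypes import (
    AccessionMetadata,
    AlleleFrequencyMatrix,
    LocusInfo,
    ReadCountMatrix,
)


def make_loci(n, prefix="L"):
    return [LocusInfo(locus_id=f"{prefix}{j + 1:04d}", ref_allele="A", alt_allele="G")
            for j in range(n)]


def make_accessions(n, pool_n=10, **kw):
    return [AccessionMetadata(accession_id=f"a{i + 1:03d}",
                              pool_n_individuals=pool_n, **kw)
            for i in range(n)]


def make_afm(freq, pool_n=10, accessions=None):
    """AlleleFrequencyMatrix from a 2-D array (NaN = missing)."""
    freq = np.atleast_2d(np.asarray(freq, dtype=float))
    if accessions is None:
        accessions = make_accessions(freq.shape[0], pool_n=pool_n)
    return AlleleFrequencyMatrix(accessions=accessions,
                                 loci=make_loci(freq.shape[1]), freq=freq)


def make_rcm(counts, pool_n=10, accessions=None, loci=None):
    counts = np.asarray(counts)
    if accessions is None:
        accessions = make_accessions(counts.shape[0], pool_n=pool_n)
    if loci is None:
        loci = make_loci(counts.shape[1])
    return ReadCountMatrix(accessions=accessions, loci=loci, counts=counts)


def wc_theta(k, n):
    """Multilocus Weir-Cockerham theta from haploid allele counts.

    Independent oracle: the classic ANOVA estimator on per-pool allele
    counts ``k`` (pools x loci) with haploid sample sizes ``n``;
    multilocus value is the ratio of sums of the per-locus mean-square
    components.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    r = k.shape[0]
    p = k / n[:, None]
    nsum = n.sum()
    pbar = (n[:, None] * p).sum(axis=0) / nsum
    msg = (n[:, None] * p * (1 - p)).sum(axis=0) / (n - 1).sum()
    msp = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / (r - 1)
    nc = (nsum - (n ** 2).sum() / nsum) / (r - 1)
    return float((msp - msg).sum() / (msp + (nc - 1) * msg).sum())


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
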