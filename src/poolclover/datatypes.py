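"""Core in-memory containers for pooled allele-count data.

The raw observable is a matrix of reference/alternate read counts per
accession (one pool of individuals) and per bi-allelic locus.  All
downstream statistics operate on the derived alternate-allele frequency
matrix together with the haploid pool size (2 x number of individuals in
the pool; tetraploid pools are deliberately treated as diploid, so their
haploid size is also 2N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ORIGIN_GROUPS = frozenset(
    {"Denmark", "Finland", "Graminor", "Lantmannen", "Norway", "Sweden",
     "DLF", "LocalPopulation", "Russia", "Synthetic"}
)
TYPE_GROUPS = frozenset(
    {"BreedingPopulation", "Cultivar", "Diploid", "Graminor", "Landrace",
     "Tetraploid", "Unknown", "WildPopulation", "Synthetic"}
)

_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class LocusInfo:
    """Annotation of one SNP locus.

    ``n_alleles_observed`` counts the distinct alleles seen in the raw
    calls; loci with more than two are carried through parsing and
    excluded by :func:`poolclover.counts_io.filter_loci`.
    """

    locus_id: str
    ref_allele: str
    alt_allele: str
    origin_flag: str = "target"  # "target" or "de_novo"
    n_alleles_observed: int = 2

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"{self.locus_id}: ref and alt allele are both {self.ref_allele!r}"
            )
        for a in (self.ref_allele, self.alt_allele):
            if a.upper() not in _IUPAC:
                raise ValueError(f"{self.locus_id}: {a!r} is not an IUPAC base")
        if self.origin_flag not in ("target", "de_novo"):
            raise ValueError(f"origin_flag must be 'target' or 'de_novo', got {self.origin_flag!r}")
        if self.n_alleles_observed < 1:
            raise ValueError("n_alleles_observed must be >= 1")


@dataclass(frozen=True)
class AccessionMetadata:
    """Metadata for one accession (= one sequenced pool)."""

    accession_id: str
    origin_group: str = "Synthetic"
    type_group: str = "Synthetic"
    ploidy: int = 2
    pool_n_individuals: int = 10
    latitude: float = 0.0
    longitude: float = 0.0
    maturity: str | None = None

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValueError(f"ploidy must be 2 or 4, got {self.ploidy}")
        if self.pool_n_individuals <= 0:
            raise ValueError("pool_n_individuals must be > 0")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} out of [-180, 180]")

    @property
    def pool_haploid_size(self) -> int:
        # Diploidization: tetraploid pools are treated as diploid pools,
        # so the haploid size is 2N regardless of the recorded ploidy.
        return 2 * self.pool_n_individuals


@dataclass
class ReadCountMatrix:
    """Reference/alternate read counts, shape ``(n_accessions, n_loci, 2)``."""

    accessions: list[AccessionMetadata]
    loci: list[LocusInfo]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = (len(self.accessions), len(self.loci), 2)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if np.any(self.counts < 0):
            raise ValueError("read counts must be non-negative")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus_id in loci")

    @property
    def accession_ids(self) -> list[str]:
        return [a.accession_id for a in self.accessions]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def coverage(self) -> np.ndarray:
        """Total filtered read depth per cell, shape ``(n_accessions, n_loci)``."""
        return self.counts.sum(axis=2)

    def select_loci(self, keep: Sequence[int]) -> "ReadCountMatrix":
        keep = list(keep)
        return ReadCountMatrix(
            accessions=self.accessions,
            loci=[self.loci[i] for i in keep],
            counts=self.counts[:, keep, :].copy(),
        )


@dataclass
class AlleleFrequencyMatrix:
    """Alternate-allele frequencies per accession and locus.

    ``freq`` is NaN-free only where ``missing`` is False; a cell is
    missing exactly when its total filtered read count was zero.
    """

    accessions: list[AccessionMetadata]
    loci: list[LocusInfo]
    freq: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.missing is None:
            self.missing = np.isnan(self.freq)
        self.missing = np.asarray(self.missing, dtype=bool)
        expected = (len(self.accessions), len(self.loci))
        if self.freq.shape != expected or self.missing.shape != expected:
            raise ValueError("freq/missing shape inconsistent with accessions x loci")
        ok = self.freq[~self.missing]
        if ok.size and (np.any(ok < 0) or np.any(ok > 1)):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def accession_ids(self) -> list[str]:
        return [a.accession_id for a in self.accessions]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def pool_haploid_sizes(self) -> np.ndarray:
        return np.array([a.pool_haploid_size for a in self.accessions])

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.freq, mask=self.missing)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, index=self.accession_ids, columns=self.locus_ids)
        return df.mask(pd.DataFrame(self.missing, index=df.index, columns=df.columns))


@dataclass
class PairwiseStatMatrix:
    """Symmetric accession x accession statistic matrix.

    ``statistic`` is ``"nei_D"`` (diagonal 0, entries >= 0, ``inf``
    sentinel where no allele is shared) or ``"fst"`` (entries in [-1, 1];
    negative multilocus values are meaningful and preserved).
    """

    accession_ids: list[str]
    values: np.ndarray
    statistic: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape inconsistent with accession_ids")
        finite = np.isfinite(self.values)
        sym = self.values.copy()
        sym[~finite] = 0.0
        if not np.allclose(sym, sym.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if self.statistic not in ("nei_D", "fst"):
            raise ValueError(f"unknown statistic {self.statistic!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accession_ids,
                            columns=self.accession_ids)

    def lower_triangle(self) -> np.ndarray:
        iu = np.tril_indices(len(self.accession_ids), k=-1)
        return self.values[iu]


def subset_accessions(obj, keep: Sequence[int]):
    """Row-subset a ReadCountMatrix or AlleleFrequencyMatrix."""
    keep = list(keep)
    if isinstance(obj, ReadCountMatrix):
        return ReadCountMatrix(
            accessions=[obj.accessions[i] for i in keep],
            loci=obj.loci,
            counts=obj.counts[keep].copy(),
        )
    if isinstance(obj, AlleleFrequencyMatrix):
        return AlleleFrequencyMatrix(
            accessions=[obj.accessions[i] for i in keep],
            loci=obj.loci,
            freq=obj.freq[keep].copy(),
            missing=obj.missing[keep].copy(),
        )
    raise TypeError(type(obj))


__all__ = [
    "LocusInfo", "AccessionMetadata", "ReadCountMatrix",
    "AlleleFrequencyMatrix", "PairwiseStatMatrix", "subset_accessions",
    "ORIGIN_GROUPS", "TYPE_GROUPS",
]
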