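"""Diversity and differentiation statistics for pooled samples.

All statistics start from filtered read counts or the derived
alternate-allele frequencies:

* expected heterozygosity H_S = mean over loci of 2p(1-p);
* Nei's (1972) standard genetic distance between pools;
* a pool-aware pairwise F_ST built on identity probabilities, which
  corrects both for reads re-sampling the same chromosome and for the
  finite number of chromosomes in the pool;
* Tajima's D per accession from the assayed locus set, with the
  standard Tajima (1989) normalising constants for the haploid pool
  size;
* a Mantel permutation test of isolation by distance against
  great-circle geographic distance.

Missing cells are handled pairwise-complete everywhere; negative F_ST
estimates are preserved (they indicate absence of structure, not an
error).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    AccessionMetadata,
    AlleleFrequencyMatrix,
    PairwiseStatMatrix,
    ReadCountMatrix,
)

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Expected heterozygosity

def expected_heterozygosity(
    afm: AlleleFrequencyMatrix,
    finite_pool_correction: bool = False,
) -> pd.DataFrame:
    """Per-accession expected heterozygosity H_S.

    H_S is the mean over non-missing loci of ``2p(1-p)`` (bounded by 0.5
    for bi-allelic loci).  ``finite_pool_correction`` multiplies by
    ``n/(n-1)`` with n the haploid pool size, the unbiased version for a
    finite pool.  Accessions with no usable locus get NaN.
    """
    het = 2.0 * afm.freq * (1.0 - afm.freq)
    het = np.ma.MaskedArray(het, mask=afm.missing)
    n_used = (~afm.missing).sum(axis=1)
    hs = het.mean(axis=1).filled(np.nan)
    if finite_pool_correction:
        n = afm.pool_haploid_sizes.astype(float)
        hs = hs * n / (n - 1.0)
    if np.any(n_used == 0):
        warnings.warn("accessions with all loci missing: H_S absent")
    return pd.DataFrame({"H_S": hs, "n_loci": n_used}, index=afm.accession_ids)


# ---------------------------------------------------------------------------
# Nei's standard genetic distance

def nei_standard_distance(afm: AlleleFrequencyMatrix) -> PairwiseStatMatrix:
    """Nei's (1972) standard genetic distance between every pair of pools.

    Over the loci non-missing in both pools: J_X = mean_l sum_a x_la^2,
    J_XY = mean_l sum_a x_la y_la with x = (1-p, p), and
    D = -ln( J_XY / sqrt(J_X J_Y) ).  Pairs sharing no allele at any
    common locus (J_XY = 0) get an ``inf`` sentinel.
    """
    p = afm.freq
    miss = afm.missing
    n = p.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            if not ok.any():
                raise ValueError(
                    f"no shared non-missing locus for pair "
                    f"({afm.accession_ids[i]}, {afm.accession_ids[j]})"
                )
            pi, pj = p[i, ok], p[j, ok]
            jx = np.mean(pi ** 2 + (1 - pi) ** 2)
            jy = np.mean(pj ** 2 + (1 - pj) ** 2)
            jxy = np.mean(pi * pj + (1 - pi) * (1 - pj))
            if jxy == 0.0:
                warnings.warn(
                    f"pair ({afm.accession_ids[i]}, {afm.accession_ids[j]}) "
                    "fixed for opposite alleles at all shared loci; Nei D = inf"
                )
                D[i, j] = D[j, i] = np.inf
            else:
                D[i, j] = D[j, i] = max(0.0, -math.log(jxy / math.sqrt(jx * jy)))
    return PairwiseStatMatrix(accession_ids=afm.accession_ids, values=D,
                              statistic="nei_D")


# ---------------------------------------------------------------------------
# Pool-aware pairwise F_ST

@dataclass(frozen=True)
class PerLocusPairFst:
    locus_id: str
    accession_i: str
    accession_j: str
    fst: float


def _pool_q1(counts: np.ndarray, haploid_sizes: np.ndarray) -> np.ndarray:
    """Unbiased within-pool identity probability per accession x locus.

    For read counts c_a at coverage C from a pool of n chromosomes,
    the raw read identity sum_a c_a(c_a-1)/(C(C-1)) over-counts identity
    because two reads can sample the same chromosome; the correction
    ( n*raw - 1 )/( n - 1 ) is unbiased for the identity of two distinct
    chromosomes of the source population.  Cells with C < 2 are NaN.
    """
    C = counts.sum(axis=2).astype(float)
    num = (counts.astype(float) * (counts - 1.0)).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = num / (C * (C - 1.0))
    raw[C < 2] = np.nan
    n = haploid_sizes[:, None].astype(float)
    return (n * raw - 1.0) / (n - 1.0)


def pairwise_fst(
    rcm: ReadCountMatrix,
    pool_haploid_sizes: np.ndarray | None = None,
    keep_per_locus: bool = True,
) -> tuple[PairwiseStatMatrix, list[PerLocusPairFst]]:
    """Identity-based pool F_ST for every accession pair.

    Per locus, F_ST-hat = (Q1bar - Q2)/(1 - Q2) where Q1bar averages
    the two unbiased within-pool identities and Q2 is the between-pool
    read identity; the multilocus value is the ratio of sums
    sum_l (Q1bar_l - Q2_l) / sum_l (1 - Q2_l) over loci informative for
    the pair (coverage >= 2 in both pools and 1 - Q2 != 0).  Negative
    estimates are preserved.
    """
    if pool_haploid_sizes is None:
        pool_haploid_sizes = np.array([a.pool_haploid_size for a in rcm.accessions])
    pool_haploid_sizes = np.asarray(pool_haploid_sizes)

    C = rcm.counts.sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = rcm.counts[:, :, 1] / C
    q1 = _pool_q1(rcm.counts, pool_haploid_sizes)

    n = rcm.n_accessions
    fst = np.zeros((n, n))
    per_locus: list[PerLocusPairFst] = []
    locus_ids = rcm.locus_ids
    for i in range(n):
        for j in range(i + 1, n):
            usable = (C[i] >= 2) & (C[j] >= 2)
            if not usable.any():
                raise ValueError(
                    f"no usable locus for pair ({rcm.accession_ids[i]}, "
                    f"{rcm.accession_ids[j]})"
                )
            q2 = f[i] * f[j] + (1 - f[i]) * (1 - f[j])
            q1bar = 0.5 * (q1[i] + q1[j])
            denom = 1.0 - q2
            informative = usable & (denom != 0.0)
            if keep_per_locus:
                for l in np.flatnonzero(informative):
                    per_locus.append(PerLocusPairFst(
                        locus_id=locus_ids[l],
                        accession_i=rcm.accession_ids[i],
                        accession_j=rcm.accession_ids[j],
                        fst=float((q1bar[l] - q2[l]) / denom[l]),
                    ))
            if not informative.any():
                raise ValueError(
                    f"no informative locus for pair ({rcm.accession_ids[i]}, "
                    f"{rcm.accession_ids[j]})"
                )
            fst[i, j] = fst[j, i] = (
                (q1bar[informative] - q2[informative]).sum()
                / denom[informative].sum()
            )
    mat = PairwiseStatMatrix(accession_ids=rcm.accession_ids, values=fst,
                             statistic="fst")
    return mat, per_locus


def per_locus_fst_frame(records: list[PerLocusPairFst]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


# ---------------------------------------------------------------------------
# Tajima's D

@dataclass(frozen=True)
class TajimaConstants:
    """Tajima (1989) normalising constants for haploid sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 3:
        raise ValueError("Tajima constants need n >= 3")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return TajimaConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2,
                           e1=e1, e2=e2)


def tajimas_d(
    afm: AlleleFrequencyMatrix,
    pool_haploid_size: int | None = None,
    min_segregating: int = 3,
) -> pd.DataFrame:
    """Per-accession Tajima's D from the assayed locus set.

    Allele counts are recovered from pool frequencies as
    ``k = round(p * n)`` clamped to [0, n] with n the haploid pool size.
    pi-hat sums ``2(k/n)(1-k/n) * n/(n-1)`` over loci, theta_W = S/a1
    with S the number of segregating loci, and
    D = (pi - theta_W)/sqrt(e1*S + e2*S(S-1)).  Accessions with fewer
    than ``min_segregating`` segregating loci get NaN.
    """
    out_d, out_s = [], []
    for idx, acc in enumerate(afm.accessions):
        n = pool_haploid_size or acc.pool_haploid_size
        if n < 4:
            raise ValueError("tajimas_d needs haploid pool size >= 4")
        const = tajima_constants(n)
        p = afm.freq[idx][~afm.missing[idx]]
        k = np.clip(np.round(p * n), 0, n)
        seg = (k > 0) & (k < n)
        S = int(seg.sum())
        out_s.append(S)
        if S < min_segregating:
            warnings.warn(
                f"{acc.accession_id}: only {S} segregating loci; Tajima's D absent"
            )
            out_d.append(np.nan)
            continue
        kk = k[seg]
        pi = float(np.sum(2.0 * (kk / n) * (1.0 - kk / n) * n / (n - 1.0)))
        theta_w = S / const.a1
        var = const.e1 * S + const.e2 * S * (S - 1.0)
        out_d.append((pi - theta_w) / math.sqrt(var))
    return pd.DataFrame({"D": out_d, "S": out_s}, index=afm.accession_ids)


# ---------------------------------------------------------------------------
# Mantel isolation by distance

def haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Great-circle distances (km) between coordinate pairs (spherical Earth)."""
    la = np.radians(np.asarray(lat, dtype=float))
    lo = np.radians(np.asarray(lon, dtype=float))
    dla = la[:, None] - la[None, :]
    dlo = lo[:, None] - lo[None, :]
    h = np.sin(dla / 2) ** 2 + np.cos(la)[:, None] * np.cos(la)[None, :] * np.sin(dlo / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def mantel_ibd(
    gen: PairwiseStatMatrix,
    coords: np.ndarray | list[tuple[float, float]],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mantel test of genetic distance against great-circle distance.

    Returns (r, p) where r is the Pearson correlation of the lower
    triangles and p the one-sided permutation p-value
    ``(#{r_perm >= r_obs} + 1)/(n_perm + 1)`` under simultaneous
    row/column permutation of the genetic matrix.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != len(gen.accession_ids):
        raise ValueError("coords must match the accession set of the matrix")
    geo = haversine_matrix(coords[:, 0], coords[:, 1])
    G = gen.values
    if not np.isfinite(G).all():
        raise ValueError("genetic matrix has non-finite entries; exclude sentinels first")

    n = G.shape[0]
    iu = np.tril_indices(n, k=-1)
    x = G[iu]
    y = geo[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if np.corrcoef(G[np.ix_(perm, perm)][iu], y)[0, 1] >= r_obs:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Group summaries

def group_summary(
    hs: pd.DataFrame,
    tajima: pd.DataFrame,
    nei: PairwiseStatMatrix,
    fst: PairwiseStatMatrix,
    accessions: list[AccessionMetadata],
    group_by: str = "origin",
) -> pd.DataFrame:
    """Per-group diversity summary and cross-tabulation.

    For each group (by origin_group or type_group): sample count, mean
    H_S, mean within-group pairwise Nei distance, mean within-group
    pairwise F_ST, mean Tajima's D.  Singleton groups report the
    pairwise columns as NaN (no within-group pair exists).  Additional
    columns give the percentage composition of the *other* grouping
    within each group.  Infinite Nei sentinels are excluded from means.
    """
    attr = {"origin": "origin_group", "type": "type_group"}.get(group_by)
    if attr is None:
        raise ValueError("group_by must be 'origin' or 'type'")
    other = "type_group" if attr == "origin_group" else "origin_group"
    labels = [getattr(a, attr) for a in accessions]
    missing_lab = [a.accession_id for a, l in zip(accessions, labels) if not l]
    if missing_lab:
        raise ValueError(f"accessions without {group_by} label: {missing_lab}")
    ids = [a.accession_id for a in accessions]
    if nei.accession_ids != ids or fst.accession_ids != ids:
        raise ValueError("matrix accession order must match metadata order")

    lab_arr = np.array(labels)
    rows = []
    for g in sorted(set(labels)):
        sel = np.flatnonzero(lab_arr == g)
        row = {"group": g, "n": len(sel)}
        row["H_S"] = float(np.nanmean(hs.loc[[ids[i] for i in sel], "H_S"]))
        row["tajimas_D"] = float(np.nanmean(tajima.loc[[ids[i] for i in sel], "D"]))
        if len(sel) >= 2:
            sub_nei = nei.values[np.ix_(sel, sel)]
            sub_fst = fst.values[np.ix_(sel, sel)]
            tri = np.tril_indices(len(sel), k=-1)
            nv = sub_nei[tri]
            row["nei_D"] = float(np.mean(nv[np.isfinite(nv)])) if np.isfinite(nv).any() else np.nan
            row["fst"] = float(np.mean(sub_fst[tri]))
        else:
            row["nei_D"] = np.nan
            row["fst"] = np.nan
        other_labs = np.array([getattr(accessions[i], other) for i in sel])
        for ol in sorted(set(getattr(a, other) for a in accessions)):
            row[f"pct_{ol}"] = 100.0 * float(np.mean(other_labs == ol))
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


__all__ = [
    "expected_heterozygosity", "nei_standard_distance", "pairwise_fst",
    "PerLocusPairFst", "per_locus_fst_frame", "TajimaConstants",
    "tajima_constants", "tajimas_d", "haversine_matrix", "mantel_ibd",
    "group_summary", "EARTH_RADIUS_KM",
]
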