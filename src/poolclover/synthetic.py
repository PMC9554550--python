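"""Synthetic pooled-sequencing metapopulations with known truth.

The generator emulates a Nordic seed-bank panel assayed by targeted
pool-seq: each accession is a pool of ten diploid individuals sequenced
to a mean depth of ~500x at a few hundred unlinked bi-allelic loci.
Population structure is hierarchical: a wild and a cultivated gene pool
diverge from a common ancestor (Balding-Nichols with drift coefficient
``f_stratum``), and individual populations drift further within their
stratum (``f_wild`` / ``f_cultivated``; the cultivated pool is more
homogeneous).  A small fraction of loci carry allele-frequency clines in
the wild stratum: on top of the drifted frequency p the population's
value becomes inverse-logit(logit(p) + slope * z) where z is the
standardized value of a temperature-like environmental variable at the
collection site (a flat cline therefore leaves these loci exactly
neutral).  Environmental variables follow latitudinal gradients
with site-level noise, and a monthly snow-thickness curve (September to
June) scales with latitude.

Read generation is two-stage and matches the sampling model the pool
F_ST estimator corrects for: a pool of 2N chromosomes is drawn
binomially from the population frequency, then reads re-sample the
realized pool with replacement (binomial on k/2N) at Poisson coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AccessionMetadata, LocusInfo, ReadCountMatrix
from .envdata import SNOW_MONTHS, SnowSeries, snow_auc

#: latitudinal gradient models: variable -> (value at 55 degN, slope per
#: degree of latitude, site noise SD); units degC, mm, %, CV%.  Site
#: noise dominates the shared latitude trend: across Scandinavian
#: collection sites the bioclimatic variables are only weakly mutually
#: predictive (a climate-only linear model has LOOCV RMSE about equal
#: to the response SD), and the SD scales echo the real panel
#: (temperature ~2.4 degC, precipitation ~226 mm, isothermality ~2.3%,
#: seasonality ~6.1 CV%).
DEFAULT_ENV_MODEL: dict[str, tuple[float, float, float]] = {
    "annual_mean_temperature": (6.0, -0.15, 2.2),
    "annual_precipitation": (800.0, -8.0, 215.0),
    "isothermality": (25.0, 0.08, 2.2),
    "precipitation_seasonality": (20.0, 0.2, 5.8),
}

#: relative shape of the September..June snow-thickness curve
_SNOW_SHAPE = np.array([0.0, 0.1, 0.4, 0.7, 1.0, 1.0, 0.8, 0.5, 0.2, 0.0])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic metapopulation."""

    n_pops: int = 80
    n_loci: int = 661
    pool_n_individuals: int = 10
    depth_mean: float = 500.0
    wild_fraction: float = 0.5
    f_stratum: float = 0.03          # wild/cultivated divergence
    f_wild: float = 0.04             # drift within the wild stratum
    f_cultivated: float = 0.01       # drift within the cultivated stratum
    adaptive_fraction: float = 10.0 / 661.0
    cline_slope: float = 1.0         # logit units per SD of environment
    cline_variable: str = "annual_mean_temperature"
    maf_floor: float = 0.05
    lat_range: tuple[float, float] = (55.0, 70.0)
    lon_range: tuple[float, float] = (5.0, 30.0)
    env_model: dict = field(default_factory=lambda: dict(DEFAULT_ENV_MODEL))
    uneven_pool_weights: bool = False  # Dirichlet-weighted individual contribution
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_wild", "f_cultivated"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {f}")
        if not 0.0 <= self.f_stratum < 1.0:
            raise ValueError("f_stratum must lie in [0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        for name in ("wild_fraction", "adaptive_fraction", "maf_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth of one simulated metapopulation."""

    config: SimulationConfig
    accessions: list[AccessionMetadata]
    loci: list[LocusInfo]
    stratum: np.ndarray                  # "wild" / "cultivated" per pop
    ancestral_freq: np.ndarray           # global ancestral, per locus
    pop_freq: np.ndarray                 # n_pops x n_loci
    adaptive_loci: list[str]
    adaptive_slopes: dict[str, float]
    env: pd.DataFrame                    # site x variable (incl. snow_auc, latitude)
    snow: list[SnowSeries]
    expected_pairwise_fst: np.ndarray    # closed-form model expectation

    @property
    def wild_index(self) -> np.ndarray:
        return np.flatnonzero(self.stratum == "wild")


def _balding_nichols(rng, p_anc: np.ndarray, F: float) -> np.ndarray:
    if F == 0.0:
        return p_anc.copy()
    # guard against parent frequencies that have drifted to the boundary
    p = np.clip(p_anc, 1e-9, 1.0 - 1e-9)
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return np.clip(rng.beta(a, b), 0.0, 1.0)


def _logit(p):
    return np.log(p / (1.0 - p))


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_metapop(config: SimulationConfig, seed: int | None = None) -> TruthTable:
    """Draw true population frequencies, environments and truth labels."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L, P = config.n_loci, config.n_pops
    n_wild = int(round(config.wild_fraction * P))
    stratum = np.array(["wild"] * n_wild + ["cultivated"] * (P - n_wild))

    p_anc = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=L)
    p_strat = {s: _balding_nichols(rng, p_anc, config.f_stratum)
               for s in ("wild", "cultivated")}

    lat = rng.uniform(*config.lat_range, size=P)
    lon = rng.uniform(*config.lon_range, size=P)
    env_cols = {}
    for var, (v55, slope, noise_sd) in config.env_model.items():
        env_cols[var] = v55 + slope * (lat - 55.0) + rng.normal(0.0, noise_sd, size=P)

    peak = np.maximum(0.04 * (lat - 54.0) + rng.normal(0.0, 0.3, size=P), 0.0)
    snow = [SnowSeries(site_id=f"acc_{i + 1:03d}",
                       thickness=tuple(np.round(peak[i] * _SNOW_SHAPE, 6)))
            for i in range(P)]
    env = pd.DataFrame(env_cols, index=[s.site_id for s in snow])
    env["snow_auc"] = [snow_auc(s) for s in snow]
    env["latitude"] = lat

    zvar = env[config.cline_variable].to_numpy()
    z = (zvar - zvar.mean()) / zvar.std()

    pop_freq = np.empty((P, L))
    f_pop = {"wild": config.f_wild, "cultivated": config.f_cultivated}
    for i in range(P):
        pop_freq[i] = _balding_nichols(rng, p_strat[stratum[i]], f_pop[stratum[i]])

    n_adaptive = int(round(config.adaptive_fraction * L))
    adaptive_idx = rng.choice(L, size=n_adaptive, replace=False) if n_adaptive else np.array([], dtype=int)
    locus_ids = [f"L{j + 1:04d}" for j in range(L)]
    adaptive_loci = sorted(locus_ids[j] for j in adaptive_idx)
    slopes = {locus_ids[j]: config.cline_slope for j in adaptive_idx}
    # clines act on top of the population's drifted frequency, so a flat
    # cline (slope 0) leaves adaptive loci exactly neutral
    wild = stratum == "wild"
    for j in adaptive_idx:
        base = _logit(np.clip(pop_freq[wild, j], 1e-9, 1 - 1e-9))
        pop_freq[wild, j] = _inv_logit(base + config.cline_slope * z[wild])

    accessions = [AccessionMetadata(
        accession_id=f"acc_{i + 1:03d}",
        origin_group="Synthetic",
        type_group="WildPopulation" if stratum[i] == "wild" else "Cultivar",
        ploidy=2,
        pool_n_individuals=config.pool_n_individuals,
        latitude=float(lat[i]), longitude=float(lon[i]),
    ) for i in range(P)]
    loci = [LocusInfo(locus_id=lid, ref_allele="A", alt_allele="G",
                      origin_flag="target") for lid in locus_ids]

    return TruthTable(
        config=config, accessions=accessions, loci=loci, stratum=stratum,
        ancestral_freq=p_anc, pop_freq=pop_freq,
        adaptive_loci=adaptive_loci, adaptive_slopes=slopes,
        env=env, snow=snow,
        expected_pairwise_fst=_expected_fst_matrix(config, stratum),
    )


def _expected_fst_matrix(config: SimulationConfig, stratum: np.ndarray) -> np.ndarray:
    """Closed-form expected multilocus pairwise F_ST under the model.

    With total within-pop correlation F_tot = F_s + (1 - F_s) F_pop,
    a cross-stratum pair expects (F_tot_i + F_tot_j)/2 and a same-
    stratum pair (F_pop_i + F_pop_j)/2 (the shared stratum ancestry
    cancels in the ratio of sums).  Clines are ignored (they affect a
    small minority of loci).
    """
    f_pop = np.where(stratum == "wild", config.f_wild, config.f_cultivated)
    f_tot = config.f_stratum + (1.0 - config.f_stratum) * f_pop
    P = len(stratum)
    out = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            if stratum[i] == stratum[j]:
                v = 0.5 * (f_pop[i] + f_pop[j])
            else:
                v = 0.5 * (f_tot[i] + f_tot[j])
            out[i, j] = out[j, i] = v
    return out


def _reads_from_pool_freq(rng, pool_freq: np.ndarray, depth_mean: float) -> np.ndarray:
    """Poisson coverage, then binomial re-sampling of the realized pool."""
    C = rng.poisson(depth_mean, size=pool_freq.shape)
    alt = rng.binomial(C, pool_freq)
    return np.stack([C - alt, alt], axis=-1)


def simulate_pool_reads(
    truth: TruthTable,
    seed: int | None = None,
) -> ReadCountMatrix:
    """Draw pooled read counts for every accession and locus.

    The pool of 2N chromosomes is sampled binomially from the true
    population frequency; reads then re-sample the realized pool.  With
    ``uneven_pool_weights`` individuals contribute Dirichlet-weighted
    shares of the DNA instead of equal amounts.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n2 = 2 * cfg.pool_n_individuals
    k = rng.binomial(n2, truth.pop_freq)
    if cfg.uneven_pool_weights:
        pool_freq = _uneven_pool_freq(rng, truth, k)
    else:
        pool_freq = k / n2
    counts = _reads_from_pool_freq(rng, pool_freq, cfg.depth_mean)
    return ReadCountMatrix(accessions=truth.accessions, loci=truth.loci,
                           counts=counts)


def _uneven_pool_freq(rng, truth: TruthTable, k: np.ndarray) -> np.ndarray:
    """Dirichlet-weighted contribution of individuals to the pooled DNA."""
    cfg = truth.config
    P, L = k.shape
    N = cfg.pool_n_individuals
    # distribute the k alt chromosomes over individuals, then weight
    geno = _genotypes_from_pool(rng, k, N)
    w = rng.dirichlet(np.ones(N), size=P)                  # P x N
    return np.clip(np.einsum("pn,pnl->pl", w, geno) / 2.0, 0.0, 1.0)


def _genotypes_from_pool(rng, k: np.ndarray, N: int) -> np.ndarray:
    """Split k alt chromosomes among N diploids by hypergeometric draws."""
    P, L = k.shape
    geno = np.zeros((P, N, L), dtype=int)
    remaining_alt = k.copy()
    remaining_chrom = np.full((P, L), 2 * N)
    for ind in range(N):
        g = rng.hypergeometric(remaining_alt, remaining_chrom - remaining_alt, 2)
        geno[:, ind, :] = g
        remaining_alt -= g
        remaining_chrom -= 2
    return geno


@dataclass
class IndividualPoolExperiment:
    """Matched individual genotypes and pooled reads of the same pools."""

    genotypes: np.ndarray        # n_pops x N x n_loci, alt dosage 0/1/2
    genotype_freq: np.ndarray    # n_pops x n_loci, = sum(g)/2N
    pooled: ReadCountMatrix


def simulate_individuals(
    truth: TruthTable,
    seed: int | None = None,
) -> IndividualPoolExperiment:
    """Genotype the individuals of each pool and sequence the same pool.

    Each of the N diploids gets an alt dosage g ~ Binomial(2, p_pop);
    the realized pool count k = sum(g) is shared between the
    genotype-derived accession frequency k/2N and the pooled reads,
    which re-sample that same pool — enabling the pool-vs-individual
    validation experiment.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    P, L = truth.pop_freq.shape
    N = cfg.pool_n_individuals
    geno = rng.binomial(2, truth.pop_freq[:, None, :], size=(P, N, L))
    k = geno.sum(axis=1)
    pool_freq = k / (2.0 * N)
    counts = _reads_from_pool_freq(rng, pool_freq, cfg.depth_mean)
    pooled = ReadCountMatrix(accessions=truth.accessions, loci=truth.loci,
                             counts=counts)
    return IndividualPoolExperiment(genotypes=geno, genotype_freq=pool_freq,
                                    pooled=pooled)


@dataclass
class ClusterTruth:
    """Ground truth of a flat k-cluster simulation."""

    labels: np.ndarray           # cluster index per pool
    cluster_freq: np.ndarray     # n_clusters x n_loci
    pop_freq: np.ndarray         # n_pops x n_loci
    accessions: list[AccessionMetadata]
    loci: list[LocusInfo]


def simulate_clusters(
    n_clusters: int,
    pops_per_cluster: int,
    n_loci: int,
    f_between: float = 0.3,
    f_within: float = 0.01,
    pool_n_individuals: int = 10,
    depth_mean: float = 500.0,
    maf_floor: float = 0.05,
    seed: int = 0,
) -> tuple[ClusterTruth, ReadCountMatrix]:
    """Flat k-cluster metapopulation (no environment, no clines).

    Cluster centres drift from a common ancestral frequency with
    coefficient ``f_between``; pools drift from their centre with
    ``f_within`` (0 = pools identical to the centre).  ``n_clusters=1``
    gives a panmictic panel.  Useful for calibration and recovery tests
    where a known discrete partition is needed.
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(maf_floor, 1.0 - maf_floor, size=n_loci)
    centers = np.stack([_balding_nichols(rng, p_anc, f_between)
                        for _ in range(n_clusters)])
    labels = np.repeat(np.arange(n_clusters), pops_per_cluster)
    pop_freq = np.stack([_balding_nichols(rng, centers[c], f_within)
                         for c in labels])
    P = len(labels)
    n2 = 2 * pool_n_individuals
    k = rng.binomial(n2, pop_freq)
    counts = _reads_from_pool_freq(rng, k / n2, depth_mean)
    accessions = [AccessionMetadata(accession_id=f"acc_{i + 1:03d}",
                                    pool_n_individuals=pool_n_individuals)
                  for i in range(P)]
    loci = [LocusInfo(locus_id=f"L{j + 1:04d}", ref_allele="A", alt_allele="G")
            for j in range(n_loci)]
    truth = ClusterTruth(labels=labels, cluster_freq=centers, pop_freq=pop_freq,
                         accessions=accessions, loci=loci)
    return truth, ReadCountMatrix(accessions=accessions, loci=loci, counts=counts)


def pool_validity_correlations(exp: IndividualPoolExperiment) -> np.ndarray:
    """Per-accession Pearson r between pooled-read and genotype frequencies."""
    C = exp.pooled.counts.sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_reads = exp.pooled.counts[:, :, 1] / C
    out = np.empty(exp.genotype_freq.shape[0])
    for i in range(len(out)):
        ok = C[i] > 0
        out[i] = np.corrcoef(f_reads[i, ok], exp.genotype_freq[i, ok])[0, 1]
    return out


__all__ = [
    "SimulationConfig", "TruthTable", "simulate_metapop",
    "simulate_pool_reads", "IndividualPoolExperiment",
    "simulate_individuals", "pool_validity_correlations",
    "ClusterTruth", "simulate_clusters",
    "DEFAULT_ENV_MODEL",
]
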