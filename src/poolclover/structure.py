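"""Population-structure analyses.

* Classical principal coordinate analysis (PCoA) on a genetic distance
  matrix.
* A PCA-based outlier-SNP scan: each SNP is regressed on the leading
  principal-component scores of the accessions, the resulting z-vectors
  are screened by robust Mahalanobis distance, rescaled by a genomic
  inflation factor and tested against a chi-square distribution with
  Benjamini-Hochberg control of the false discovery rate.
* DAPC: k-means cluster search over PCA scores scored by BIC, linear
  discriminant axes on retained PCs, Gaussian membership probabilities,
  and a stratified cross-validation to pick the number of PCs.
* Neighbor-joining tree construction on the distance matrix with newick
  output.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.covariance import MinCovDet
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from skbio import TreeNode

from .datatypes import AlleleFrequencyMatrix, PairwiseStatMatrix


# ---------------------------------------------------------------------------
# PCoA

@dataclass
class PcoaResult:
    coordinates: np.ndarray          # accession x axis
    eigenvalues: np.ndarray          # all eigenvalues, descending
    explained_fraction: np.ndarray   # per retained (positive) axis
    accession_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.accession_ids, columns=cols)


def pcoa(dist: PairwiseStatMatrix) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Double-centers the squared distances, B = -1/2 * J D^2 J, and keeps
    the axes with positive eigenvalues; coordinates are eigenvectors
    scaled by sqrt(eigenvalue).  Explained fractions are shares of the
    sum of positive eigenvalues only.
    """
    D = np.asarray(dist.values, dtype=float)
    if not np.isfinite(D).all():
        raise ValueError("distance matrix must be finite (exclude inf sentinels)")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals[0])) if evals.size else evals > 0
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    explained = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return PcoaResult(coordinates=coords, eigenvalues=evals,
                      explained_fraction=explained,
                      accession_ids=list(dist.accession_ids))


# ---------------------------------------------------------------------------
# PCA outlier scan

@dataclass
class OutlierScanResult:
    locus_ids: list[str]             # loci actually scanned
    zscores: np.ndarray              # locus x K
    mahalanobis_d2: np.ndarray
    gif: float
    p_values: np.ndarray
    q_values: np.ndarray
    flagged: np.ndarray              # boolean, q < fdr
    excluded_loci: list[str]         # monomorphic loci left out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "D2": self.mahalanobis_d2, "p": self.p_values,
            "q": self.q_values, "flagged": self.flagged,
        }, index=self.locus_ids)


def outlier_scan(
    afm: AlleleFrequencyMatrix,
    K: int = 2,
    fdr: float = 0.05,
    scale: str = "binomial",
    seed: int | None = 0,
) -> OutlierScanResult:
    """Scan SNPs for excess association with the top-K PCA axes.

    Columns are centered and (by default) scaled by the binomial
    standard deviation sqrt(pbar(1-pbar)).  Each SNP's z-vector holds
    the t-like statistics of its regression on the K leading left
    singular vectors of the scaled matrix; a robust (minimum covariance
    determinant) Mahalanobis D^2 of the z-vectors, divided by the
    genomic inflation factor median(D^2)/median(chi2_K), is referred to
    a chi-square with K degrees of freedom and Benjamini-Hochberg
    adjusted.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = afm.freq.shape[0]
    if n <= K:
        raise ValueError("need more accessions than K")
    if scale not in ("binomial", "none"):
        raise ValueError("scale must be 'binomial' or 'none'")

    X = np.where(afm.missing, np.nan, afm.freq)
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X)  # mean-impute missing cells

    sd = np.sqrt(col_mean * (1.0 - col_mean)) if scale == "binomial" else X.std(axis=0)
    usable = sd > 0
    excluded = [afm.locus_ids[j] for j in np.flatnonzero(~usable)]
    if excluded:
        warnings.warn(f"{len(excluded)} monomorphic loci excluded from outlier scan")
    Xs = (X[:, usable] - col_mean[usable]) / sd[usable]

    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    scores = U[:, :K]                                   # orthonormal columns
    beta = scores.T @ Xs                                # K x m
    resid = Xs - scores @ beta
    dof = max(n - K - 1, 1)
    sigma = np.sqrt((resid ** 2).sum(axis=0) / dof)
    sigma[sigma == 0] = np.finfo(float).tiny
    z = (beta / sigma).T                                # m x K

    if K == 1:
        center = np.median(z[:, 0])
        # classical fallback: squared z scaled so the median matches chi2_1
        d2 = (z[:, 0] - center) ** 2
    else:
        mcd = MinCovDet(random_state=seed).fit(z)
        d2 = mcd.mahalanobis(z)
    gif = float(np.median(d2) / stats.chi2.ppf(0.5, df=K))
    if gif <= 0:
        raise ValueError("degenerate scan: non-positive inflation factor")
    p = stats.chi2.sf(d2 / gif, df=K)
    q = stats.false_discovery_control(p, method="bh")
    return OutlierScanResult(
        locus_ids=[afm.locus_ids[j] for j in np.flatnonzero(usable)],
        zscores=z, mahalanobis_d2=d2, gif=gif, p_values=p, q_values=q,
        flagged=q < fdr, excluded_loci=excluded,
    )


# ---------------------------------------------------------------------------
# DAPC

def _pca_scores(afm: AlleleFrequencyMatrix, n_pcs: int) -> np.ndarray:
    X = np.where(afm.missing, np.nan, afm.freq)
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X) - col_mean
    n_pcs = min(n_pcs, min(X.shape) - 1) if min(X.shape) > 1 else 1
    return PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)


def find_clusters(
    afm: AlleleFrequencyMatrix,
    n_pcs: int = 50,
    k_max: int = 6,
    seed: int | None = 0,
    n_restarts: int = 20,
) -> tuple[pd.Series, np.ndarray]:
    """K-means cluster search on PCA scores, scored by BIC.

    BIC(k) = n*ln(WSS_k/n) + k*ln(n); returns the BIC curve (indexed by
    k) and the assignment for the k minimising it.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    n = afm.freq.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of accessions")
    scores = _pca_scores(afm, n_pcs)
    rng = np.random.default_rng(seed)
    bic, assignments = {}, {}
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts,
                        random_state=int(rng.integers(2 ** 31))).fit(scores)
            wss = float(km.inertia_)
            labels = km.labels_
        bic[k] = n * np.log(max(wss, np.finfo(float).tiny) / n) + k * np.log(n)
        assignments[k] = labels
    bic_series = pd.Series(bic, name="BIC")
    best = int(bic_series.idxmin())
    return bic_series, assignments[best]


@dataclass
class DapcResult:
    chosen_k: int
    retained_pcs: int
    discriminant_coordinates: np.ndarray   # accession x n_da
    membership_probabilities: np.ndarray   # accession x k, rows sum to 1
    assignment: np.ndarray
    accession_ids: list[str]
    bic_by_k: pd.Series | None = None


def dapc_fit(
    afm: AlleleFrequencyMatrix,
    groups: np.ndarray,
    n_pcs: int,
    n_da: int | None = None,
) -> DapcResult:
    """Discriminant analysis of principal components.

    PCA scores are reduced to ``n_pcs`` axes, then linear discriminant
    axes maximise between-group over within-group variance (generalised
    eigenproblem); membership probabilities come from the
    equal-covariance Gaussian classifier of the discriminant model.
    """
    groups = np.asarray(groups)
    ids, counts = np.unique(groups, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 members")
    k = len(ids)
    n = afm.freq.shape[0]
    if n_pcs > n - k:
        raise ValueError("n_pcs must be <= n_accessions - k to keep the "
                         "within-group covariance nonsingular")
    n_da = n_da or (k - 1)
    scores = _pca_scores(afm, n_pcs)
    lda = LinearDiscriminantAnalysis(solver="eigen", n_components=min(n_da, k - 1))
    try:
        lda.fit(scores, groups)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular within-group covariance; retain fewer PCs") from exc
    coords = lda.transform(scores)
    proba = lda.predict_proba(scores)
    return DapcResult(
        chosen_k=k, retained_pcs=scores.shape[1],
        discriminant_coordinates=coords,
        membership_probabilities=proba,
        assignment=lda.predict(scores),
        accession_ids=afm.accession_ids,
    )


def dapc_xval(
    afm: AlleleFrequencyMatrix,
    groups: np.ndarray,
    pc_grid: list[int],
    train_fraction: float = 0.9,
    reps: int = 30,
    seed: int | None = 0,
) -> tuple[int, pd.DataFrame]:
    """Stratified cross-validation of the number of retained PCs.

    For each candidate, repeatedly hold out ``1 - train_fraction`` of
    each group, fit the discriminant model on the rest, and record the
    held-out assignment success rate.  Returns the candidate with the
    best mean success (ties go to fewer PCs) and the score table.
    """
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    ids, counts = np.unique(groups, return_counts=True)
    scorable = {g for g, c in zip(ids, counts) if c >= 2}
    if len(scorable) < len(ids):
        warnings.warn("groups with a single member are excluded from scoring")

    full_scores = _pca_scores(afm, max(pc_grid))
    results = {p: [] for p in pc_grid}
    for _ in range(reps):
        train_idx, test_idx = [], []
        for g in ids:
            members = np.flatnonzero(groups == g)
            if g not in scorable:
                train_idx.extend(members)
                continue
            perm = rng.permutation(members)
            n_train = max(int(round(train_fraction * len(members))), 1)
            n_train = min(n_train, len(members) - 1)
            train_idx.extend(perm[:n_train])
            test_idx.extend(perm[n_train:])
        train_idx, test_idx = np.array(train_idx), np.array(test_idx)
        for p in pc_grid:
            Xtr, Xte = full_scores[train_idx, :p], full_scores[test_idx, :p]
            lda = LinearDiscriminantAnalysis(solver="svd")
            lda.fit(Xtr, groups[train_idx])
            results[p].append(float(np.mean(lda.predict(Xte) == groups[test_idx])))
    table = pd.DataFrame({p: pd.Series(v).describe() for p, v in results.items()}).T
    means = {p: float(np.mean(v)) for p, v in results.items()}
    best = min(sorted(pc_grid), key=lambda p: (-means[p], p))
    return best, table


# ---------------------------------------------------------------------------
# Neighbor joining

@dataclass
class NjTree:
    tree: TreeNode
    newick: str

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}


def nj_tree(dist: PairwiseStatMatrix) -> NjTree:
    """Saitou-Nei neighbor joining with newick serialization.

    Negative branch lengths are set to zero and the deficit transferred
    to the adjacent branch of the same join (Kuhner-Felsenstein), so
    tip-to-tip path lengths through the join are preserved.
    """
    ids = list(dist.accession_ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 accessions")
    D = np.asarray(dist.values, dtype=float).copy()
    if not np.isfinite(D).all():
        raise ValueError("distance matrix must be finite")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        a, b = np.unravel_index(np.argmin(Q), Q.shape)
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        # Kuhner-Felsenstein: zero a negative branch, move its length to
        # the sibling so the path between the two joined nodes is kept.
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni, nj_ = nodes[i], nodes[j]
        ni.length = max(li, 0.0)
        nj_.length = max(lj, 0.0)
        parent = TreeNode(children=[ni, nj_])
        nodes.append(parent)
        # distances from the new node to the remaining ones
        new_row = np.zeros(D.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            new_row[c] = 0.5 * (D[i, c] + D[j, c] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        active = [c for c in active if c not in (i, j)] + [D.shape[0] - 1]

    i, j = active
    ni, nj_ = nodes[i], nodes[j]
    d = max(D[i, j], 0.0)
    # root the unrooted tree on the final edge
    if ni.is_tip():
        ni, nj_ = nj_, ni
    ni.length = 0.0
    nj_.length = d
    root = ni
    root.append(nj_)
    buf = io.StringIO()
    root.write(buf, format="newick")
    return NjTree(tree=root, newick=buf.getvalue().strip())


__all__ = [
    "PcoaResult", "pcoa", "OutlierScanResult", "outlier_scan",
    "find_clusters", "DapcResult", "dapc_fit", "dapc_xval",
    "NjTree", "nj_tree",
]
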