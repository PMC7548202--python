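"""Cluster discovery (PCA + k-means + BIC) and DAPC membership probabilities.

The workflow mirrors the find.clusters / dapc pair familiar from
microsatellite studies: genotypes are encoded as per-allele dosages,
reduced by PCA, the number of gene pools K is chosen by the Bayesian
information criterion over k-means solutions, and a linear discriminant
analysis on the retained principal components yields per-individual
membership probabilities.  Individuals whose highest membership goes to a
cluster other than their sampling site's modal ("home") cluster with
probability above 0.5 are flagged as mixed genotypes (putative migrants or
stocked fish).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, ward
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DosageMatrix:
    """Centered allele-dosage encoding of a genotype matrix.

    One column per locus x allele holding 0 / 0.5 / 1 (allele copies / 2),
    mean-imputed where the genotype is missing, then column-centered.
    """

    X: np.ndarray
    columns: list[tuple[str, int]]
    individuals: list[str]

    def frame(self) -> pd.DataFrame:
        cols = [f"{locus}.{allele}" for locus, allele in self.columns]
        return pd.DataFrame(self.X, index=self.individuals, columns=cols)


def encode_alleles(gm: GenotypeMatrix) -> DosageMatrix:
    """Encode genotypes as a centered individuals x (locus, allele) matrix.

    Homozygotes score 1.0 in their allele's column, heterozygotes 0.5 in
    each of two columns.  Missing genotypes are imputed with the column
    mean of the observed values; columns are then centered, so imputed
    cells carry no signal.  Individuals missing at every locus are dropped
    with a warning.
    """
    keep = [
        indiv
        for indiv in gm.individuals
        if any(gm.df.at[indiv, locus] is not None for locus in gm.loci)
    ]
    dropped = set(gm.individuals) - set(keep)
    if dropped:
        logger.warning(
            "dropping %d individuals with no called genotype: %s",
            len(dropped),
            sorted(dropped)[:5],
        )
    columns: list[tuple[str, int]] = []
    blocks: list[np.ndarray] = []
    for locus in gm.loci:
        alleles = sorted(
            {a for c in gm.df[locus] if c is not None for a in c}
        )
        if not alleles:
            continue
        col_idx = {a: j for j, a in enumerate(alleles)}
        block = np.full((len(keep), len(alleles)), np.nan)
        for i, indiv in enumerate(keep):
            call = gm.df.at[indiv, locus]
            if call is None:
                continue
            block[i, :] = 0.0
            for a in call:
                block[i, col_idx[a]] += 0.5
        mean = np.nanmean(block, axis=0)
        inds = np.where(np.isnan(block))
        block[inds] = np.take(mean, inds[1])
        block -= block.mean(axis=0)
        blocks.append(block)
        columns.extend((locus, a) for a in alleles)
    X = np.hstack(blocks) if blocks else np.empty((len(keep), 0))
    return DosageMatrix(X=X, columns=columns, individuals=keep)


def _default_n_pca(X: np.ndarray, min_explained: float = 0.90) -> int:
    pca = PCA().fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    return int(np.searchsorted(cum, min_explained) + 1)


@dataclass
class FindClustersResult:
    bic: dict[int, float]
    k_best: int
    assignments: pd.Series
    n_pca: int
    scores: np.ndarray


def _select_k(bic: dict[int, float], criterion: str) -> int:
    """Choose K from a BIC curve.

    ``"min"`` takes the arg-minimum.  ``"diffNgroup"`` (default upstream)
    Ward-clusters the successive BIC differences into two groups — the
    steep initial drops versus the flat tail — and selects the K reached by
    the last steep drop.  On genotype dosage data the curve typically keeps
    creeping down after the true K (k-means can always shave within-cluster
    variance off discrete genotype classes), so the elbow rule is the
    reliable default and the arg-minimum is kept as an option.
    """
    ks = sorted(bic)
    if len(ks) == 1:
        return ks[0]
    if criterion == "min":
        return min(bic, key=bic.get)
    if criterion != "diffNgroup":
        raise ValueError(f"unknown criterion {criterion!r}")
    diffs = np.diff([bic[k] for k in ks])
    if len(diffs) == 1:
        return ks[0] if diffs[0] >= 0 else ks[1]
    groups = fcluster(ward(pdist(diffs[:, None])), t=2, criterion="maxclust")
    means = {g: diffs[groups == g].mean() for g in set(groups)}
    steep = min(means, key=means.get)
    last_steep = int(np.max(np.nonzero(groups == steep)[0]))
    return ks[last_steep + 1]


def _bic_curve(
    scores: np.ndarray,
    k_max: int,
    n_start: int,
    rng: np.random.Generator,
) -> tuple[dict[int, float], dict[int, np.ndarray]]:
    n = scores.shape[0]
    bic: dict[int, float] = {}
    assign: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
            assign[k] = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k,
                n_init=n_start,
                random_state=int(rng.integers(2**31)),
            ).fit(scores)
            wss = float(km.inertia_)
            assign[k] = km.labels_
        wss = max(wss, 1e-12)
        bic[k] = n * np.log(wss / n) + k * np.log(n)
    return bic, assign


def _structure_pretest(
    dosage: DosageMatrix,
    observed_drop: float,
    n_pca: int,
    n_start: int,
    rng: np.random.Generator,
    n_null: int = 5,
) -> bool:
    """Is there any multilocus structure at all?

    Null reference: permute individuals independently within each locus
    block, which preserves every per-locus genotype distribution but
    destroys the cross-locus correlation that population structure creates.
    Returns True (structure present) when the observed BIC drop from K=1 to
    K=2 exceeds every null drop; otherwise the data are compatible with a
    single gene pool.  K-means always shaves some variance off discrete
    genotype classes, so the drop is never compared against zero.
    """
    n = dosage.X.shape[0]
    locus_slices: dict[str, list[int]] = {}
    for j, (locus, _allele) in enumerate(dosage.columns):
        locus_slices.setdefault(locus, []).append(j)
    null_drops = []
    for _ in range(n_null):
        Xp = dosage.X.copy()
        for cols in locus_slices.values():
            Xp[:, cols] = Xp[rng.permutation(n)][:, cols]
        scores = PCA(n_components=min(n_pca, min(Xp.shape))).fit_transform(Xp)
        bic, _ = _bic_curve(scores, 2, n_start, rng)
        null_drops.append(bic[1] - bic[2])
    return observed_drop > max(null_drops)


def find_clusters(
    dosage: DosageMatrix,
    k_max: int = 10,
    n_pca: int | None = None,
    seed: int | None = None,
    n_start: int = 20,
    criterion: str = "diffNgroup",
) -> FindClustersResult:
    """Select the number of gene pools by BIC over k-means solutions.

    PCA scores on ``n_pca`` components (default: the smallest number
    explaining >= 90% of variance) are clustered with k-means for each K in
    1..``k_max`` (``n_start`` restarts, best inertia kept) and scored with
    BIC(K) = n ln(WSS_K / n) + K ln(n), where WSS_K is the total
    within-cluster sum of squares.  ``criterion`` picks K from the curve:
    the Ward elbow rule ``"diffNgroup"`` (default) or the arg-minimum
    ``"min"``.  Under ``"diffNgroup"`` a permutation pre-test
    (:func:`_structure_pretest`) first asks whether any multilocus
    structure exists; if not, K = 1 is reported regardless of the curve.
    """
    X = dosage.X
    n = X.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of individuals")
    if n_pca is None:
        n_pca = _default_n_pca(X)
    n_pca = min(n_pca, min(X.shape))
    scores = PCA(n_components=n_pca).fit_transform(X)
    rng = np.random.default_rng(seed)
    bic, best_assign = _bic_curve(scores, k_max, n_start, rng)
    k_best = _select_k(bic, criterion)
    if (
        criterion == "diffNgroup"
        and k_best > 1
        and not _structure_pretest(dosage, bic[1] - bic[2], n_pca, n_start, rng)
    ):
        logger.info("no multilocus structure detected; reporting a single pool")
        k_best = 1
    assignments = pd.Series(best_assign[k_best], index=dosage.individuals, name="cluster")
    return FindClustersResult(
        bic=bic, k_best=k_best, assignments=assignments, n_pca=n_pca, scores=scores
    )


@dataclass
class DapcFit:
    memberships: pd.DataFrame
    coords: np.ndarray
    n_pca: int
    n_da: int


def dapc(
    dosage: DosageMatrix,
    groups: pd.Series,
    n_pca: int | None = None,
    n_da: int | None = None,
) -> DapcFit:
    """Membership probabilities from LDA on retained principal components.

    ``groups`` assigns each individual to a cluster or population; the
    posterior probabilities of the discriminant model are the memberships.
    A singular within-group covariance falls back to shrinkage LDA.
    """
    groups = groups.loc[dosage.individuals]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("dapc needs at least two groups")
    if n_pca is None:
        n_pca = _default_n_pca(dosage.X)
    n_pca = min(n_pca, min(dosage.X.shape))
    if n_da is None:
        n_da = len(levels) - 1
    n_da = min(n_da, len(levels) - 1)
    scores = PCA(n_components=n_pca).fit_transform(dosage.X)
    try:
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(scores, groups.to_numpy())
    except np.linalg.LinAlgError:
        logger.warning("singular within-group covariance; applying shrinkage LDA")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(scores, groups.to_numpy())
    memberships = pd.DataFrame(
        lda.predict_proba(scores), index=dosage.individuals, columns=lda.classes_
    )
    try:
        coords = lda.transform(scores)[:, :n_da]
    except (AttributeError, NotImplementedError):  # lsqr solver has no transform
        coords = np.empty((len(dosage.individuals), 0))
    return DapcFit(memberships=memberships, coords=coords, n_pca=n_pca, n_da=n_da)


def a_score(
    dosage: DosageMatrix,
    groups: pd.Series,
    n_pca_candidates: list[int],
    n_reps: int = 10,
    seed: int | None = None,
) -> dict[int, float]:
    """Randomization a-score over candidate numbers of retained PCs.

    For each candidate, the a-score is the mean over groups of (observed
    correct-reassignment rate - the rate obtained with permuted group
    labels), averaged over ``n_reps`` permutations.  Larger is better; use
    it to pick ``n_pca`` when overfitting is a concern.
    """
    rng = np.random.default_rng(seed)
    groups = groups.loc[dosage.individuals]
    out: dict[int, float] = {}
    for n_pca in n_pca_candidates:
        fit = dapc(dosage, groups, n_pca=n_pca)
        observed = float(
            (fit.memberships.idxmax(axis=1) == groups).mean()
        )
        random_rates = []
        for _ in range(n_reps):
            perm = pd.Series(
                rng.permutation(groups.to_numpy()), index=groups.index
            )
            pfit = dapc(dosage, perm, n_pca=n_pca)
            random_rates.append(float((pfit.memberships.idxmax(axis=1) == perm).mean()))
        out[n_pca] = observed - float(np.mean(random_rates))
    return out


def gene_pool_frequencies(
    assignments: pd.Series, sites: pd.Series
) -> pd.DataFrame:
    """Per-site cluster composition: fraction of individuals per cluster."""
    sites = sites.loc[assignments.index]
    table = (
        pd.crosstab(sites, assignments)
        .apply(lambda row: row / row.sum(), axis=1)
        .rename_axis(index="site", columns="cluster")
    )
    return table


def home_clusters(assignments: pd.Series, sites: pd.Series) -> dict[str, object]:
    """Modal cluster per site; ties broken toward the globally larger cluster."""
    sites = sites.loc[assignments.index]
    global_sizes = assignments.value_counts()
    home: dict[str, object] = {}
    for site in sites.unique():
        counts = assignments[sites == site].value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) > 1:
            top = sorted(top, key=lambda c: (-global_sizes.get(c, 0), str(c)))
            logger.info("site %s: home-cluster tie broken toward %s", site, top[0])
        home[site] = top[0]
    return home


def mixed_genotypes(
    memberships: pd.DataFrame,
    sites: pd.Series,
    threshold: float = 0.5,
) -> tuple[pd.Series, int]:
    """Flag individuals grouping with a foreign gene pool.

    An individual is flagged iff its maximum-membership cluster differs
    from its site's home (modal) cluster and that membership exceeds
    ``threshold``.  Returns the per-individual flags and their count.
    """
    sites = sites.loc[memberships.index]
    assignments = memberships.idxmax(axis=1)
    home = home_clusters(assignments, sites)
    max_prob = memberships.max(axis=1)
    flags = pd.Series(
        [
            (assignments[i] != home[sites[i]]) and (max_prob[i] > threshold)
            for i in memberships.index
        ],
        index=memberships.index,
        name="mixed",
    )
    return flags, int(flags.sum())
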