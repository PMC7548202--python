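"""Diversity indices, HWE tests, null-allele EM and Weir-Cockerham theta-ST.

Conventions follow the standard microsatellite toolkits: expected
heterozygosity is Nei's gene diversity He = 1 - sum p_i^2 (the unbiased
small-sample form is also emitted as ``uHe``), the fixation index is
Fi = (He - Ho) / He, and differentiation is the Weir & Cockerham (1984)
theta estimator of F_ST with variance components a (among populations),
b (among individuals within populations) and c (within individuals),
summed over alleles and loci:  theta = sum a / sum (a + b + c).
Missing genotypes are dropped per locus (pairwise-complete).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class FreqTable:
    """Allele frequencies of one population at one locus."""

    population: str
    locus: str
    freqs: dict[int, float]
    n_typed: int


def allele_freqs(
    gm: GenotypeMatrix, group_by: str = "region"
) -> dict[str, dict[str, FreqTable]]:
    """Per-population, per-locus allele frequencies.

    Each homozygote contributes two copies of its allele, each heterozygote
    one copy of each; missing calls are excluded from the denominator.
    Returns ``tables[population][locus]``.
    """
    labels = gm.labels(group_by)
    out: dict[str, dict[str, FreqTable]] = {}
    for pop in gm.populations(group_by):
        mask = labels == pop
        out[pop] = {}
        for locus in gm.loci:
            counts: dict[int, int] = {}
            n_typed = 0
            for call in gm.df.loc[mask, locus]:
                if call is None:
                    continue
                n_typed += 1
                for allele in call:
                    counts[allele] = counts.get(allele, 0) + 1
            total = 2 * n_typed
            freqs = (
                {a: c / total for a, c in sorted(counts.items())} if total else {}
            )
            out[pop][locus] = FreqTable(pop, locus, freqs, n_typed)
    return out


# -- diversity indices --------------------------------------------------


def _locus_indices(table: FreqTable, calls: list[tuple[int, int]]) -> dict:
    p = np.fromiter(table.freqs.values(), dtype=float) if table.freqs else np.array([])
    sum_p2 = float((p**2).sum()) if p.size else np.nan
    he = 1.0 - sum_p2 if p.size else np.nan
    n = table.n_typed
    ho = (
        sum(1 for a, b in calls if a != b) / n if n else np.nan
    )
    row = {
        "n_typed": n,
        "A": int((p > 0).sum()) if p.size else 0,
        "Ae": 1.0 / sum_p2 if p.size and sum_p2 > 0 else np.nan,
        "I": float(-(p[p > 0] * np.log(p[p > 0])).sum()) if p.size else np.nan,
        "Ho": ho,
        "He": he,
        "uHe": he * (2 * n) / (2 * n - 1) if n and n > 0 and 2 * n > 1 else np.nan,
        "Fi": (he - ho) / he if p.size and he > 0 else (0.0 if p.size else np.nan),
    }
    return row


def diversity(
    gm: GenotypeMatrix, group_by: str = "region"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diversity indices per population.

    Per locus: A (alleles observed), Ae = 1 / sum p^2 (effective alleles),
    I = -sum p ln p (Shannon), Ho (observed heterozygote fraction),
    He = 1 - sum p^2 (Nei), uHe (unbiased He), Fi = (He - Ho)/He.

    Returns ``(means, per_locus)``: one row per population of means across
    loci (N = individuals sampled; Fi averaged over polymorphic loci only,
    since it is undefined where He = 0), and the full per-locus table.
    """
    tables = allele_freqs(gm, group_by)
    labels = gm.labels(group_by)
    per_locus_rows = []
    mean_rows = []
    for pop in gm.populations(group_by):
        mask = labels == pop
        pop_rows = []
        for locus in gm.loci:
            calls = [c for c in gm.df.loc[mask, locus] if c is not None]
            row = {"population": pop, "locus": locus}
            row.update(_locus_indices(tables[pop][locus], calls))
            pop_rows.append(row)
        per_locus_rows.extend(pop_rows)
        sub = pd.DataFrame(pop_rows)
        polymorphic = sub["He"] > 0
        if not polymorphic.any():
            logger.warning("population %s: He = 0 at every locus; Fi reported 0", pop)
        mean_rows.append(
            {
                "population": pop,
                "N": int(mask.sum()),
                "A": sub["A"].mean(),
                "Ae": sub["Ae"].mean(),
                "I": sub["I"].mean(),
                "Ho": sub["Ho"].mean(),
                "He": sub["He"].mean(),
                "uHe": sub["uHe"].mean(),
                "Fi": sub.loc[polymorphic, "Fi"].mean() if polymorphic.any() else 0.0,
            }
        )
    return pd.DataFrame(mean_rows), pd.DataFrame(per_locus_rows)


def private_alleles(
    tables: dict[str, dict[str, FreqTable]],
) -> list[tuple[str, str, int, float]]:
    """Alleles present (freq > 0) in exactly one population.

    Returns ``(population, locus, allele, frequency)`` tuples, frequency
    taken in the single population carrying the allele.
    """
    pops = list(tables)
    if len(pops) < 2:
        raise ValueError("private alleles need at least two populations")
    loci = list(tables[pops[0]])
    out = []
    for locus in loci:
        presence: dict[int, list[str]] = {}
        for pop in pops:
            for allele, freq in tables[pop][locus].freqs.items():
                if freq > 0:
                    presence.setdefault(allele, []).append(pop)
        for allele, carriers in sorted(presence.items()):
            if len(carriers) == 1:
                pop = carriers[0]
                out.append((pop, locus, allele, tables[pop][locus].freqs[allele]))
    return out


# -- Hardy-Weinberg -----------------------------------------------------


@dataclass
class HweResult:
    population: str
    locus: str
    chi2: float
    df: int
    p_value: float
    n_typed: int
    tested: bool


def hwe_test(
    gm: GenotypeMatrix, population: str, locus: str, group_by: str = "region"
) -> HweResult:
    """Chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Expected genotype counts come from the observed allele frequencies
    (n p_i^2 for homozygotes, 2 n p_i p_j for heterozygotes) over all
    k(k+1)/2 genotype cells without pooling; df = k(k-1)/2.  Monomorphic
    loci are flagged untested.
    """
    calls = gm.pop_calls(population, locus, group_by)
    n = len(calls)
    allele_counts: dict[int, int] = {}
    geno_counts: dict[tuple[int, int], int] = {}
    for a, b in calls:
        geno_counts[(a, b)] = geno_counts.get((a, b), 0) + 1
        allele_counts[a] = allele_counts.get(a, 0) + 1
        allele_counts[b] = allele_counts.get(b, 0) + 1
    alleles = sorted(allele_counts)
    k = len(alleles)
    if k < 2 or n < 5:
        return HweResult(population, locus, np.nan, 0, np.nan, n, tested=False)
    p = {a: allele_counts[a] / (2 * n) for a in alleles}
    chi2 = 0.0
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            expected = n * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
            observed = geno_counts.get((a, b), 0)
            if expected > 0:
                chi2 += (observed - expected) ** 2 / expected
    df = k * (k - 1) // 2
    p_value = float(stats.chi2.sf(chi2, df))
    return HweResult(population, locus, float(chi2), df, p_value, n, tested=True)


def hwe_all(gm: GenotypeMatrix, group_by: str = "region") -> pd.DataFrame:
    rows = []
    for pop in gm.populations(group_by):
        for locus in gm.loci:
            r = hwe_test(gm, pop, locus, group_by)
            rows.append(vars(r))
    return pd.DataFrame(rows)


# -- null-allele EM -----------------------------------------------------


@dataclass
class NullAlleleResult:
    null_freq: float
    visible_freqs: dict[int, float]
    log_likelihood: float
    n_iter: int
    converged: bool


def null_allele_em(
    genotype_counts: dict[tuple[int, int], int],
    n_missing: int = 0,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> NullAlleleResult:
    """EM estimate of the null-allele frequency at one population x locus.

    Model: one unobservable (null) allele segregates alongside the visible
    alleles under random mating.  Null heterozygotes present as apparent
    homozygotes for their visible allele; null homozygotes present as
    missing calls (``n_missing``, optional).  The E step splits apparent
    homozygote counts between true homozygotes and null heterozygotes by
    their conditional probabilities; the M step re-estimates allele
    frequencies from expected allele counts; iteration stops when the
    observed-data log-likelihood improves by less than ``tol``.
    """
    visible = sorted({a for pair in genotype_counts for a in pair})
    if not visible:
        raise ValueError("no genotypes supplied")
    k = len(visible)
    idx = {a: i for i, a in enumerate(visible)}
    het_counts = np.zeros((k, k))
    hom_counts = np.zeros(k)
    for (a, b), c in genotype_counts.items():
        if a == b:
            hom_counts[idx[a]] += c
        else:
            het_counts[idx[a], idx[b]] += c
            het_counts[idx[b], idx[a]] += c
    n_total = sum(genotype_counts.values()) + n_missing

    # init: equal shares including the null
    p = np.full(k + 1, 1.0 / (k + 1))  # p[:k] visible, p[k] null

    def loglik(p: np.ndarray) -> float:
        pv, p0 = p[:k], p[k]
        ll = 0.0
        hom_prob = pv**2 + 2 * pv * p0
        for i in range(k):
            if hom_counts[i]:
                ll += hom_counts[i] * np.log(max(hom_prob[i], 1e-300))
            for j in range(i + 1, k):
                if het_counts[i, j]:
                    ll += het_counts[i, j] * np.log(max(2 * pv[i] * pv[j], 1e-300))
        if n_missing:
            ll += n_missing * np.log(max(p0**2, 1e-300))
        return float(ll)

    prev_ll = loglik(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pv, p0 = p[:k], p[k]
        # expected allele copy counts
        copies = np.zeros(k + 1)
        # visible heterozygote (i,j): one copy of each allele
        copies[:k] += het_counts.sum(axis=1)
        # apparent homozygote i: true hom (2 copies of i) vs null het (1 + null)
        denom = pv + 2 * p0
        w_hom = np.where(denom > 0, pv / np.where(denom > 0, denom, 1.0), 0.0)
        copies[:k] += hom_counts * (2 * w_hom + (1 - w_hom))
        copies[k] += float((hom_counts * (1 - w_hom)).sum())
        copies[k] += 2.0 * n_missing
        p = copies / (2.0 * n_total)
        ll = loglik(p)
        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    if not converged:
        logger.warning("null-allele EM did not converge in %d iterations", max_iter)
    return NullAlleleResult(
        null_freq=float(p[k]),
        visible_freqs={a: float(p[idx[a]]) for a in visible},
        log_likelihood=prev_ll,
        n_iter=it,
        converged=converged,
    )


def null_allele_table(gm: GenotypeMatrix, group_by: str = "region") -> pd.DataFrame:
    """Null-allele EM estimates for every population x locus."""
    labels = gm.labels(group_by)
    rows = []
    for pop in gm.populations(group_by):
        mask = labels == pop
        for locus in gm.loci:
            col = gm.df.loc[mask, locus]
            counts: dict[tuple[int, int], int] = {}
            n_missing = 0
            for call in col:
                if call is None:
                    n_missing += 1
                else:
                    counts[call] = counts.get(call, 0) + 1
            if not counts:
                continue
            res = null_allele_em(counts)
            rows.append(
                {
                    "population": pop,
                    "locus": locus,
                    "null_freq": res.null_freq,
                    "converged": res.converged,
                    "n_typed": int(sum(counts.values())),
                    "n_missing": n_missing,
                }
            )
    return pd.DataFrame(rows)


# -- Weir-Cockerham theta -----------------------------------------------


def _wc_components_locus(
    g1: np.ndarray, g2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-allele variance components (a, b, c) for one locus, two samples.

    ``g1``/``g2`` are (n_i, 2) integer arrays of allele codes with missing
    rows already removed.
    """
    n1, n2 = len(g1), len(g2)
    r = 2
    nbar = (n1 + n2) / r
    if n1 == 0 or n2 == 0 or nbar <= 1:
        return np.array([]), np.array([]), np.array([])
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    alleles = np.union1d(g1.ravel(), g2.ravel())
    a_list, b_list, c_list = [], [], []
    for allele in alleles:
        p1 = (g1 == allele).sum() / (2 * n1)
        p2 = (g2 == allele).sum() / (2 * n2)
        h1 = (((g1 == allele).sum(axis=1) == 1)).sum() / n1
        h2 = (((g2 == allele).sum(axis=1) == 1)).sum() / n2
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_list.append(a)
        b_list.append(b)
        c_list.append(c)
    return np.array(a_list), np.array(b_list), np.array(c_list)


def _theta_from_arrays(per_locus: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Multilocus theta from per-locus (genotypes_pop1, genotypes_pop2)."""
    num = 0.0
    den = 0.0
    for g1, g2 in per_locus:
        a, b, c = _wc_components_locus(g1, g2)
        num += a.sum()
        den += (a + b + c).sum()
    if den == 0.0:
        return np.nan
    return num / den


@dataclass
class PairwiseTheta:
    pop_a: str
    pop_b: str
    theta: float
    p_value: float
    n_perm: int
    defined: bool = True


def theta_st(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    group_by: str = "region",
    n_perm: int = 999,
    seed: int | None = None,
) -> PairwiseTheta:
    """Pairwise multilocus Weir-Cockerham theta with a permutation test.

    The p-value is the add-one-corrected fraction of ``n_perm`` random
    reassignments of individuals to the two populations whose theta is at
    least the observed value.  ``n_perm = 0`` skips the test (p = NaN).
    """
    labels = gm.labels(group_by)
    idx_a = np.flatnonzero((labels == pop_a).to_numpy())
    idx_b = np.flatnonzero((labels == pop_b).to_numpy())
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"empty population among {pop_a!r}, {pop_b!r}")
    pooled = np.concatenate([idx_a, idx_b])
    n_a = len(idx_a)

    # pre-code genotypes per locus over the pooled individuals
    per_locus_all = [gm.allele_array(locus)[pooled] for locus in gm.loci]

    def theta_for(order: np.ndarray) -> float:
        per_locus = []
        for arr in per_locus_all:
            g = arr[order]
            g1 = g[:n_a]
            g2 = g[n_a:]
            g1 = g1[g1[:, 0] >= 0]
            g2 = g2[g2[:, 0] >= 0]
            per_locus.append((g1, g2))
        return _theta_from_arrays(per_locus)

    identity = np.arange(len(pooled))
    observed = theta_for(identity)
    if np.isnan(observed):
        logger.warning("theta undefined for %s vs %s (no variance)", pop_a, pop_b)
        return PairwiseTheta(pop_a, pop_b, np.nan, np.nan, n_perm, defined=False)
    if n_perm <= 0:
        return PairwiseTheta(pop_a, pop_b, float(observed), np.nan, 0)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        t = theta_for(perm)
        if not np.isnan(t) and t >= observed:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return PairwiseTheta(pop_a, pop_b, float(observed), float(p), n_perm)


def pairwise_theta(
    gm: GenotypeMatrix,
    group_by: str = "region",
    n_perm: int = 999,
    seed: int | None = None,
    floor_zero: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise thetas; returns (theta matrix, p-value matrix).

    ``floor_zero`` truncates negative estimates to 0 in the returned matrix
    (the raw values are what the permutation test used either way).
    """
    pops = gm.populations(group_by)
    theta = pd.DataFrame(np.nan, index=pops, columns=pops)
    pvals = pd.DataFrame(np.nan, index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    for i, a in enumerate(pops):
        theta.loc[a, a] = 0.0
        for b in pops[i + 1 :]:
            res = theta_st(
                gm, a, b, group_by, n_perm=n_perm, seed=int(rng.integers(2**31))
            )
            t = res.theta
            if floor_zero and not np.isnan(t):
                t = max(t, 0.0)
            theta.loc[a, b] = theta.loc[b, a] = t
            pvals.loc[a, b] = pvals.loc[b, a] = res.p_value
    return theta, pvals
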