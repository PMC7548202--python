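import numpy as np
import pytest
from scipy import stats

from msatpop.popgen import (
    allele_freqs,
    diversity,
    hwe_test,
    null_allele_em,
    pairwise_theta,
    private_alleles,
    theta_st,
)
from msatpop.simulate import diverged_populations, sample_genotypes

from conftest import draw_pop_calls, make_gm


# -- allele frequencies and diversity ------------------------------------


def test_allele_counting_conventions():
    gm = make_gm({"P": [{"L": (21, 21)}, {"L": (21, 24)}]})
    tables = allele_freqs(gm, "site")
    assert tables["P"]["L"].freqs == {21: 0.75, 24: 0.25}
    assert tables["P"]["L"].n_typed == 2
    gm2 = make_gm({"P": [{"L": (21, 21)}, {"L": None}]})
    t2 = allele_freqs(gm2, "site")["P"]["L"]
    assert t2.freqs == {21: 1.0} and t2.n_typed == 1


def test_diversity_closed_forms():
    # two alleles at 0.5/0.5: He=0.5, Ae=2, I=ln 2
    gm = make_gm({"P": [{"L": (21, 24)}] * 10})
    _, per_locus = diversity(gm, "site")
    row = per_locus.iloc[0]
    assert row.He == pytest.approx(0.5)
    assert row.Ae == pytest.approx(2.0)
    assert row.I == pytest.approx(np.log(2))
    assert row.Ho == 1.0 and row.A == 2
    # monomorphic locus
    gm2 = make_gm({"P": [{"L": (21, 21)}] * 10})
    _, pl2 = diversity(gm2, "site")
    row2 = pl2.iloc[0]
    assert (row2.A, row2.Ae, row2.I, row2.He) == (1, 1.0, 0.0, 0.0)


def test_fixation_index_recovered_from_inbred_simulation(panel, ancestral):
    """fis = 0.30 at n = 500 is recovered within +/-0.05 as mean Fi."""
    pops = diverged_populations(ancestral, ["P"], fst=0.0, n_individuals=500, fis=0.30, seed=5)
    gm = sample_genotypes(pops, panel, seed=6).genotypes
    means, _ = diversity(gm, "site")
    assert abs(means.Fi.iloc[0] - 0.30) < 0.05
    expected_he = np.mean(
        [1 - sum(p**2 for p in ancestral[locus].values()) for locus in ancestral]
    )
    assert means.He.iloc[0] == pytest.approx(expected_he, abs=0.03)


def test_bounds_invariants_on_random_data(panel, ancestral):
    pops = diverged_populations(ancestral, ["A", "B"], fst=0.2, n_individuals=40, seed=7)
    gm = sample_genotypes(pops, panel, seed=8).genotypes
    _, per_locus = diversity(gm)
    assert per_locus.He.between(0, 1).all()
    assert per_locus.Ho.between(0, 1).all()
    assert (per_locus.Ae <= per_locus.A + 1e-9).all()
    assert (per_locus.I >= 0).all()


def test_private_alleles_match_brute_force(panel, ancestral):
    pops = diverged_populations(ancestral, ["A", "B", "C", "D"], fst=0.3, n_individuals=30, seed=9)
    gm = sample_genotypes(pops, panel, seed=10).genotypes
    tables = allele_freqs(gm)
    got = {(p, l, a) for p, l, a, _f in private_alleles(tables)}
    # brute-force scan of presence sets
    want = set()
    for locus in gm.loci:
        for pop in tables:
            for allele, freq in tables[pop][locus].freqs.items():
                if freq > 0 and all(
                    other == pop or tables[other][locus].freqs.get(allele, 0) == 0
                    for other in tables
                ):
                    want.add((pop, locus, allele))
    assert got == want
    shared = make_gm(
        {"A": [{"L": (21, 24)}] * 3, "B": [{"L": (21, 21)}] * 3}
    )
    priv = private_alleles(allele_freqs(shared, "site"))
    assert priv == [("A", "L", 24, pytest.approx(0.5))]


# -- Hardy-Weinberg ------------------------------------------------------


def test_hwe_exact_proportions_give_zero_statistic():
    # p = q = 0.5, n = 100: 25 hom / 50 het / 25 hom exactly
    rows = [{"L": (21, 21)}] * 25 + [{"L": (21, 24)}] * 50 + [{"L": (24, 24)}] * 25
    gm = make_gm({"P": rows})
    res = hwe_test(gm, "P", "L", "site")
    assert res.chi2 == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_hwe_all_heterozygotes_statistic():
    # 100 heterozygotes only: chi2 = 50^2/50 + 25 + 25 = 100, df = 1
    gm = make_gm({"P": [{"L": (21, 24)}] * 100})
    res = hwe_test(gm, "P", "L", "site")
    assert res.chi2 == pytest.approx(100.0)
    assert res.df == 1


def test_hwe_monomorphic_flagged_untested():
    gm = make_gm({"P": [{"L": (21, 21)}] * 20})
    assert not hwe_test(gm, "P", "L", "site").tested


def test_inbred_populations_mostly_reject_hwe(panel, ancestral):
    """fis = 0.35 drives widespread HWE rejection across loci."""
    pops = diverged_populations(ancestral, ["P"], fst=0.0, n_individuals=150, fis=0.35, seed=11)
    gm = sample_genotypes(pops, panel, seed=12).genotypes
    results = [hwe_test(gm, "P", locus, "site") for locus in gm.loci]
    rejected = [r for r in results if r.tested and r.p_value < 0.05]
    assert len(rejected) / len(results) > 0.6


# -- null-allele EM ------------------------------------------------------


def test_em_reports_no_null_at_hardy_weinberg_counts():
    res = null_allele_em({(1, 1): 36, (1, 2): 48, (2, 2): 16})
    assert res.converged
    assert res.null_freq < 1e-3


def test_em_matches_likelihood_grid_when_all_homozygous():
    counts = {(1, 1): 60, (2, 2): 40}
    res = null_allele_em(counts)

    def loglik(p0, f):
        p1, p2 = (1 - p0) * f, (1 - p0) * (1 - f)
        return 60 * np.log(p1**2 + 2 * p1 * p0) + 40 * np.log(p2**2 + 2 * p2 * p0)

    # coarse-to-fine grid maximum-likelihood oracle
    best = max(
        ((loglik(p0, f), p0) for p0 in np.linspace(0.01, 0.99, 99)
         for f in np.linspace(0.01, 0.99, 99)),
    )
    lo, hi = max(best[1] - 0.02, 1e-4), min(best[1] + 0.02, 1 - 1e-4)
    best = max(
        ((loglik(p0, f), p0) for p0 in np.linspace(lo, hi, 400)
         for f in np.linspace(0.3, 0.7, 400)),
    )
    assert res.null_freq == pytest.approx(best[1], abs=1e-4)


def test_em_recovers_planted_null_allele():
    """True null frequency 0.1 at n = 500 estimated within +/-0.05."""
    rng = np.random.default_rng(13)
    p = [0.4, 0.3, 0.2, 0.1]  # last allele is the null
    counts, miss = {}, 0
    for _ in range(500):
        a, b = rng.choice(4, 2, p=p)
        if a == 3 and b == 3:
            miss += 1
        elif 3 in (a, b):
            v = int(min(a, b)) + 1
            counts[(v, v)] = counts.get((v, v), 0) + 1
        else:
            key = tuple(sorted((int(a) + 1, int(b) + 1)))
            counts[key] = counts.get(key, 0) + 1
    res = null_allele_em(counts, n_missing=miss)
    assert res.null_freq == pytest.approx(0.1, abs=0.05)


# -- Weir-Cockerham theta ------------------------------------------------


def wc_theta_oracle(gm, pop_a, pop_b, group_by="site"):
    """Independently coded textbook estimator: plain loops per allele."""
    num = den = 0.0
    labels = gm.labels(group_by)
    for locus in gm.loci:
        ga = [c for c in gm.df.loc[labels == pop_a, locus] if c is not None]
        gb = [c for c in gm.df.loc[labels == pop_b, locus] if c is not None]
        n1, n2 = len(ga), len(gb)
        if n1 == 0 or n2 == 0 or n1 + n2 <= 2:
            continue
        r = 2
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
        for allele in sorted({a for g in ga + gb for a in g}):
            p1 = sum(g.count(allele) for g in ga) / (2 * n1)
            p2 = sum(g.count(allele) for g in gb) / (2 * n2)
            h1 = sum(1 for g in ga if (g[0] == allele) != (g[1] == allele)) / n1
            h2 = sum(1 for g in gb if (g[0] == allele) != (g[1] == allele)) / n2
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


def toy_two_pop_gm(seed=7, n=10):
    rng = np.random.default_rng(seed)
    f1 = {"L1": ([3, 6, 9], [0.5, 0.3, 0.2]), "L2": ([4, 8], [0.7, 0.3])}
    f2 = {"L1": ([3, 6, 9], [0.2, 0.3, 0.5]), "L2": ([4, 8], [0.4, 0.6])}
    return make_gm({"A": draw_pop_calls(rng, n, f1), "B": draw_pop_calls(rng, n, f2)})


def test_theta_equals_independent_oracle():
    gm = toy_two_pop_gm()
    res = theta_st(gm, "A", "B", "site", n_perm=0)
    assert res.theta == pytest.approx(wc_theta_oracle(gm, "A", "B"), abs=1e-10)


def test_theta_with_missing_calls_equals_oracle():
    gm = toy_two_pop_gm(seed=8, n=12)
    gm.df.iloc[0, gm.df.columns.get_loc("L1")] = None
    gm.df.iloc[15, gm.df.columns.get_loc("L2")] = None
    res = theta_st(gm, "A", "B", "site", n_perm=0)
    assert res.theta == pytest.approx(wc_theta_oracle(gm, "A", "B"), abs=1e-10)


def test_theta_near_zero_for_identical_populations():
    rng = np.random.default_rng(9)
    f = {"L1": ([3, 6], [0.5, 0.5]), "L2": ([3, 6, 9], [0.4, 0.4, 0.2])}
    gm = make_gm({"A": draw_pop_calls(rng, 500, f), "B": draw_pop_calls(rng, 500, f)})
    assert abs(theta_st(gm, "A", "B", "site", n_perm=0).theta) < 0.01


def test_theta_one_for_fixed_differences():
    gm = make_gm({"A": [{"L": (3, 3)}] * 20, "B": [{"L": (6, 6)}] * 20})
    assert theta_st(gm, "A", "B", "site", n_perm=0).theta == pytest.approx(1.0)


def test_theta_invariant_under_label_swap():
    gm = toy_two_pop_gm()
    t_ab = theta_st(gm, "A", "B", "site", n_perm=0).theta
    t_ba = theta_st(gm, "B", "A", "site", n_perm=0).theta
    assert t_ab == pytest.approx(t_ba, abs=1e-12)


def test_permutation_p_values_uniform_under_null():
    """QQ check: 200 null datasets, n_perm = 199 each; KS against U(0,1)."""
    rng = np.random.default_rng(42)
    f = {"L1": ([3, 6, 9], [0.5, 0.3, 0.2]), "L2": ([4, 8], [0.6, 0.4])}
    ps = []
    for rep in range(200):
        gm = make_gm(
            {"A": draw_pop_calls(rng, 10, f), "B": draw_pop_calls(rng, 10, f)}
        )
        ps.append(theta_st(gm, "A", "B", "site", n_perm=199, seed=rep).p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_regional_pooling_precondition(panel, ancestral):
    """Sites sharing a gene pool show intraregional theta < 0.05."""
    pops = diverged_populations(
        ancestral, ["R1a", "R1b", "R2a"], fst=0.0, n_individuals=60, seed=14
    )
    # R1a/R1b same pool; R2a diverged
    pops2 = diverged_populations(ancestral, ["R2a"], fst=0.2, n_individuals=60, seed=15)
    pops[2] = pops2[0]
    gm = sample_genotypes(
        pops, panel, seed=16, site_to_region={"R1a": "R1", "R1b": "R1", "R2a": "R2"}
    ).genotypes
    intra = theta_st(gm, "R1a", "R1b", "site", n_perm=0).theta
    assert intra < 0.05
    theta, _ = pairwise_theta(gm, "region", n_perm=0)
    assert theta.loc["R1", "R2"] > 0.05
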