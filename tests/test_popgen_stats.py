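"""Diversity statistics, Weir–Cockerham θ and the Mantel test against
independently coded oracles."""

import math
from itertools import combinations

import numpy as np
import pytest

from karstdemog import GenotypeMatrix, LocusRecord, PopulationMap
from karstdemog.popgen_stats import (
    allelic_richness,
    diversity_table,
    expected_heterozygosity,
    geographic_distance,
    inbreeding_coefficient,
    mantel_test,
    nei_distance,
    nucleotide_diversity,
    observed_heterozygosity,
    private_alleles,
    wc_fst,
)


def test_heterozygosity_hand_counts(tiny_matrix):
    gm, popmap = tiny_matrix
    samples = gm.samples
    ho, ho_mean, _ = observed_heterozygosity(gm, samples)
    # column het fractions: [2/5, 3/5, 2/5, 5/5]
    assert np.allclose(ho, [0.4, 0.6, 0.4, 1.0])
    assert ho_mean == pytest.approx(0.6)
    he, he_mean, _ = expected_heterozygosity(gm, samples)
    # alt freqs: 4/10, 5/10, 4/10, 5/10 -> 2pq = .48, .5, .48, .5
    assert np.allclose(he, [0.48, 0.5, 0.48, 0.5])
    assert he_mean == pytest.approx(0.49)
    fis = inbreeding_coefficient(gm, samples)
    expect = np.mean([(h - o) / h for h, o in zip([0.48, 0.5, 0.48, 0.5],
                                                  [0.4, 0.6, 0.4, 1.0])])
    assert fis == pytest.approx(expect)


def test_fis_analytic_extremes():
    # single locus with H_E = 0.5 and every call heterozygous -> F = -1
    calls = np.ones((6, 1), dtype=np.int8)
    gm = GenotypeMatrix(samples=[f"s{i}" for i in range(6)],
                        loci=[LocusRecord("l", 0)], calls=calls)
    assert inbreeding_coefficient(gm, gm.samples) == pytest.approx(-1.0)


def test_private_alleles_bruteforce(toy_filter):
    gm, popmap = toy_filter
    got = private_alleles(gm, popmap, level="population")
    # oracle: explicit per-allele presence scan
    from karstdemog.genotype_io import MISSING

    pops = popmap.populations
    expect = {p: 0 for p in pops}
    for j in range(gm.n_loci):
        present = {}
        for p in pops:
            idx = [gm.samples.index(s) for s in popmap.samples_in_pop(p)]
            obs = [gm.calls[i, j] for i in idx if gm.calls[i, j] != MISSING]
            genes = sum(obs)
            tot = 2 * len(obs)
            present[p] = (genes < tot, genes > 0)  # (ref seen, alt seen)
        for a in (0, 1):
            holders = [p for p in pops if present[p][a]]
            if len(holders) == 1:
                expect[holders[0]] += 1
    assert got == expect


def test_allelic_richness_exact_hypergeometric():
    # monomorphic locus: 1 for any g
    mono = GenotypeMatrix(samples=[f"s{i}" for i in range(10)],
                          loci=[LocusRecord("m", 0)],
                          calls=np.zeros((10, 1), dtype=np.int8))
    assert allelic_richness(mono, mono.samples, g=10) == pytest.approx(1.0)
    # singleton with g = 2n is always sampled: contribution exactly 2
    calls = np.zeros((5, 1), dtype=np.int8)
    calls[0, 0] = 1
    single = GenotypeMatrix(samples=[f"s{i}" for i in range(5)],
                            loci=[LocusRecord("s", 0)], calls=calls)
    assert allelic_richness(single, single.samples, g=10) == pytest.approx(2.0)
    # 2n = 20, allele counts {18, 2}, g = 10: direct combinatorial sum
    calls = np.zeros((10, 1), dtype=np.int8)
    calls[0, 0] = 2  # 2 alt copies
    gm = GenotypeMatrix(samples=[f"s{i}" for i in range(10)],
                        loci=[LocusRecord("x", 0)], calls=calls)
    expect = (1 - math.comb(2, 10) / math.comb(20, 10)  # ref (18 copies)
              + 1 - math.comb(18, 10) / math.comb(20, 10))  # alt (2 copies)
    assert allelic_richness(gm, gm.samples, g=10) == pytest.approx(expect)


def test_allelic_richness_monotone_in_g(tiny_matrix):
    gm, _ = tiny_matrix
    vals = [allelic_richness(gm, gm.samples, g=g) for g in (2, 4, 6, 8, 10)]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


def test_nucleotide_diversity_pairwise_oracle(tiny_matrix):
    gm, _ = tiny_matrix
    got = nucleotide_diversity(gm, gm.samples)
    # oracle: average pairwise difference over gene copies per site
    pis = []
    for j in range(gm.n_loci):
        genes = []
        for c in gm.calls[:, j]:
            genes.extend([1] * c + [0] * (2 - c))
        diffs = [a != b for a, b in combinations(genes, 2)]
        pis.append(np.mean(diffs))
    assert got == pytest.approx(np.mean(pis))
    # n = 2 gene copies, one of each allele -> pi = 1
    pair = GenotypeMatrix(samples=["s0"], loci=[LocusRecord("p", 0)],
                          calls=np.array([[1]], dtype=np.int8))
    assert nucleotide_diversity(pair, ["s0"]) == pytest.approx(1.0)


def _wc_theta_anova(n_i, p_i, h_i):
    """Weir–Cockerham θ via the mean-squares (ANOVA) formulation —
    an algebraically equivalent but independently coded route."""
    r = len(n_i)
    n_i = np.asarray(n_i, float)
    p_i = np.asarray(p_i, float)
    h_i = np.asarray(h_i, float)
    nbar = n_i.mean()
    nc = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
    pbar = (n_i * p_i).sum() / n_i.sum()
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / n_i.sum()
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar)
                                            - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_wc_fst_two_pop_toy_counts():
    # pop1: genotypes [0,0,1,2,2]; pop2: [1,1,2,2,2,2]
    calls = np.array([[0], [0], [1], [2], [2], [1], [1], [2], [2], [2], [2]],
                     dtype=np.int8)
    samples = [f"s{i}" for i in range(11)]
    gm = GenotypeMatrix(samples=samples, loci=[LocusRecord("l", 0)],
                        calls=calls)
    popmap = PopulationMap(
        {s: ("P1" if i < 5 else "P2") for i, s in enumerate(samples)},
        {"P1": "I", "P2": "II"},
    )
    res = wc_fst(gm, popmap, pairwise=False)
    n_i = [5, 6]
    p_i = [5 / 10, 10 / 12]
    h_i = [1 / 5, 2 / 6]
    a, b, c = _wc_theta_anova(n_i, p_i, h_i)
    assert res.overall == pytest.approx(a / (a + b + c), rel=1e-9)


def test_wc_fst_limits():
    rng = np.random.default_rng(1)
    # two populations fixed for alternative alleles -> theta -> 1
    calls = np.vstack([np.zeros((30, 20)), np.full((30, 20), 2)]).astype(np.int8)
    samples = [f"s{i}" for i in range(60)]
    gm = GenotypeMatrix(
        samples=samples,
        loci=[LocusRecord(f"l{j}", 0) for j in range(20)],
        calls=calls,
    )
    popmap = PopulationMap(
        {s: ("A" if i < 30 else "B") for i, s in enumerate(samples)},
        {"A": "I", "B": "II"},
    )
    res = wc_fst(gm, popmap, pairwise=False)
    assert res.overall > 0.98
    # single population -> error
    pm1 = PopulationMap({s: "A" for s in samples}, {"A": "I"})
    with pytest.raises(ValueError):
        wc_fst(gm, pm1)


def test_multilocus_theta_within_per_locus_range(island):
    gm, popmap, _ = island
    res = wc_fst(gm, popmap, pairwise=False)
    per = res.per_locus[~np.isnan(res.per_locus)]
    assert per.min() - 1e-9 <= res.overall <= per.max() + 1e-9


def test_expected_het_bound(toy_filter):
    gm, popmap = toy_filter
    from karstdemog.genotype_io import MISSING

    for pop in popmap.populations:
        samples = popmap.samples_in_pop(pop)
        he, _, _ = expected_heterozygosity(gm, samples)
        idx = [gm.samples.index(s) for s in samples]
        n = (gm.calls[idx, :] != MISSING).sum(axis=0)
        ok = n > 0
        assert np.all(he[ok] <= 1 - 1 / (2 * n[ok]) + 1e-12)


def test_nei_distance_zero_for_identical_populations(tiny_matrix):
    gm, _ = tiny_matrix
    # both "populations" are the same set of genotypes duplicated
    calls = np.vstack([gm.calls, gm.calls])
    samples = [f"x{i}" for i in range(10)]
    dup = GenotypeMatrix(samples=samples, loci=gm.loci, calls=calls)
    popmap = PopulationMap(
        {s: ("A" if i < 5 else "B") for i, s in enumerate(samples)},
        {"A": "I", "B": "II"},
    )
    D = nei_distance(dup, popmap)
    assert D.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)
    assert D.values.diagonal().sum() == 0


def test_mantel_identity_and_exact_enumeration():
    rng = np.random.default_rng(7)
    M = rng.random((4, 4))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    res = mantel_test(M, M, exact=True)
    assert res.r_squared == pytest.approx(1.0)

    Y = rng.random((4, 4))
    Y = (Y + Y.T) / 2
    np.fill_diagonal(Y, 0)
    exact = mantel_test(M, Y, exact=True)
    # permutation p within binomial error of exhaustive enumeration
    perm = mantel_test(M, Y, n_perm=999, seed=11)
    se = math.sqrt(exact.p_value * (1 - exact.p_value) / 999)
    assert abs(perm.p_value - exact.p_value) <= 4 * se + 2 / 999
    with pytest.raises(ValueError):
        mantel_test(np.zeros((4, 4)), Y)


def test_geographic_distance_and_table(toy_filter):
    gm, popmap = toy_filter
    popmap.coords.update(
        {"P1": (37.1, 128.4), "P2": (37.0, 128.35), "P3": (36.9, 128.3)}
    )
    D = geographic_distance(popmap)
    assert D.loc["P1", "P3"] > D.loc["P1", "P2"] > 0
    table = diversity_table(gm, popmap)
    assert set(table.index) >= {"P1", "P2", "P3", "cluster_I", "cluster_II"}
    assert ((table["H_O"] >= 0) & (table["H_O"] <= 1)).all()
    assert ((table["N_A"] >= 1) & (table["N_A"] <= 2)).all()
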