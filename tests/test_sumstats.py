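"""Diversity statistics against hand arithmetic and enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strassign import (
    allelic_richness,
    effective_alleles,
    expected_heterozygosity,
    hwe_exact_test,
    inbreeding_coefficient,
    observed_heterozygosity,
    private_alleles,
    unbiased_heterozygosity,
)
from strassign.genotype_db import AlleleCountTable
from strassign.sumstats import locus_stats, population_summary


# ---------------------------------------------------------------------------
# heterozygosity / effective alleles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts,expected",
    [
        ({1: 5, 2: 5}, 2.0),
        ({1: 7}, 1.0),
        ({1: 70, 2: 20, 3: 10}, 1 / 0.54),
    ],
)
def test_effective_alleles(counts, expected):
    assert effective_alleles(counts) == pytest.approx(expected)


@pytest.mark.parametrize(
    "counts,expected",
    [
        ({1: 5, 2: 5}, 0.5),
        ({1: 7}, 0.0),
        ({1: 70, 2: 20, 3: 10}, 0.46),
    ],
)
def test_expected_heterozygosity(counts, expected):
    assert expected_heterozygosity(counts) == pytest.approx(expected)


def test_unbiased_heterozygosity_small_sample_correction():
    counts = {1: 5, 2: 5}  # He = 0.5, N = 5 -> 10/9 * 0.5
    assert unbiased_heterozygosity(counts, 5) == pytest.approx(5 / 9)
    assert unbiased_heterozygosity({1: 4}, 2) == 0.0
    # correction vanishes for large N
    assert unbiased_heterozygosity(counts, 10_000) == pytest.approx(0.5, abs=1e-4)


def test_observed_heterozygosity():
    assert observed_heterozygosity([(1, 2), (1, 2)]) == 1.0
    assert observed_heterozygosity([(1, 1), (2, 2)]) == 0.0
    assert observed_heterozygosity([(1, 1), (1, 2), (2, 2), (1, 2)]) == 0.5


def test_private_alleles_counting():
    pops = [
        AlleleCountTable("p1", {"L1": {1: 2, 2: 2}, "L2": {9: 4}}),
        AlleleCountTable("p2", {"L1": {2: 4}, "L2": {9: 2, 8: 2}}),
    ]
    assert private_alleles(pops, "p1") == 1     # allele 1 at L1
    assert private_alleles(pops, "p2") == 1     # allele 8 at L2
    with pytest.raises(ValueError):
        private_alleles(pops[:1], "p1")


def test_private_alleles_sum_identity():
    rng = np.random.default_rng(3)
    pops = []
    for p in range(4):
        counts = {
            f"L{l}": {
                int(a): int(rng.integers(0, 4))
                for a in rng.choice(12, size=5, replace=False)
            }
            for l in range(3)
        }
        pops.append(AlleleCountTable(f"p{p}", counts))
    total = sum(private_alleles(pops, t.population_id) for t in pops)
    singly_carried = 0
    for l in range(3):
        alleles = {
            a for t in pops for a, c in t.counts[f"L{l}"].items() if c > 0
        }
        for a in alleles:
            carriers = sum(
                1 for t in pops if t.counts[f"L{l}"].get(a, 0) > 0
            )
            singly_carried += carriers == 1
    assert total == singly_carried


# ---------------------------------------------------------------------------
# allelic richness (rarefaction)
# ---------------------------------------------------------------------------

def _ar_oracle(counts, n_standard):
    """Expected number of distinct alleles over all C(2N, 2n) draws."""
    genes = [a for a, c in counts.items() for _ in range(c)]
    draws = list(itertools.combinations(range(len(genes)), 2 * n_standard))
    return sum(len({genes[i] for i in draw}) for draw in draws) / len(draws)


def test_allelic_richness_hand_example():
    # {A:3, B:1}, 2N=4, n=1: [1 - C(1,2)/C(4,2)] + [1 - C(3,2)/C(4,2)] = 1.5
    assert allelic_richness({1: 3, 2: 1}, 1) == pytest.approx(1.5)


def test_allelic_richness_monomorphic_and_full_sample():
    assert allelic_richness({1: 8}, 2) == pytest.approx(1.0)
    counts = {1: 3, 2: 2, 3: 1}
    assert allelic_richness(counts, 3) == pytest.approx(3.0)   # n = N -> Na


def test_allelic_richness_exceeding_sample_is_error():
    with pytest.raises(ValueError):
        allelic_richness({1: 4}, 3)


def test_allelic_richness_matches_enumeration_oracle_small_tables():
    """AR equals the expected-distinct-alleles enumeration on every
    composition of at most 8 gene copies (even totals, >=1 draw)."""
    for total in (2, 4, 6, 8):
        for k in range(1, 5):
            for cut in itertools.combinations(range(1, total), k - 1):
                parts = [b - a for a, b in zip((0,) + cut, cut + (total,))]
                counts = {i: c for i, c in enumerate(parts)}
                for n in range(1, total // 2 + 1):
                    assert allelic_richness(counts, n) == pytest.approx(
                        _ar_oracle(counts, n)
                    ), (counts, n)


def test_allelic_richness_nondecreasing_in_n():
    counts = {1: 5, 2: 3, 3: 2, 4: 2}
    values = [allelic_richness(counts, n) for n in range(1, 7)]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


# ---------------------------------------------------------------------------
# FIS
# ---------------------------------------------------------------------------

def test_fis_zero_when_observed_matches_expected():
    # Ho = 0.5, and construct so uHe == Ho is not generally exact; use the
    # degenerate checks instead plus the all-het negative case.
    genos = [(1, 1), (1, 2), (1, 2), (2, 2)]
    counts = {1: 4, 2: 4}
    uhe = unbiased_heterozygosity(counts, 4)
    expected = (uhe - 0.5) / uhe
    assert inbreeding_coefficient(genos) == pytest.approx(expected)


def test_fis_complete_heterozygote_deficit_is_one():
    assert inbreeding_coefficient([(1, 1), (2, 2)]) == pytest.approx(1.0)


def test_fis_all_heterozygotes_negative():
    genos = [(1, 2)] * 6
    # He = 0.5, uHe = 12/11 * 0.5, Ho = 1 -> FIS = 1 - Ho/uHe
    uhe = 12 / 11 * 0.5
    assert inbreeding_coefficient(genos) == pytest.approx((uhe - 1) / uhe)
    assert inbreeding_coefficient(genos) < 0


def test_fis_nei_variant():
    genos = [(1, 2)] * 6
    assert inbreeding_coefficient(genos, estimator="nei") == pytest.approx(
        (0.5 - 1.0) / 0.5
    )


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def _levene_prob(table, allele_counts):
    n = sum(table.values())
    h = sum(c for (a, b), c in table.items() if a != b)
    num = (
        math.factorial(n)
        * math.prod(math.factorial(c) for c in allele_counts.values())
        * 2 ** h
    )
    den = math.factorial(2 * n) * math.prod(
        math.factorial(c) for c in table.values()
    )
    return num / den


def _hwe_oracle_two_alleles(n_aa, n_ab, n_bb):
    """Independent enumeration over heterozygote counts for 2 alleles."""
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    obs = _levene_prob({(1, 1): n_aa, (1, 2): n_ab, (2, 2): n_bb},
                       {1: na, 2: nb})
    p = 0.0
    for h in range(min(na, nb) % 2, min(na, nb) + 1, 2):
        aa, bb = (na - h) // 2, (nb - h) // 2
        prob = _levene_prob({(1, 1): aa, (1, 2): h, (2, 2): bb},
                            {1: na, 2: nb})
        if prob <= obs + 1e-12:
            p += prob
    return p


def test_hwe_modal_table_p_is_one():
    res = hwe_exact_test({(1, 1): 1, (1, 2): 2, (2, 2): 1})
    assert res.method == "enumeration"
    assert res.p_value == pytest.approx(1.0)
    assert res.p_value == pytest.approx(_hwe_oracle_two_alleles(1, 2, 1))


def test_hwe_extreme_heterozygote_deficit():
    res = hwe_exact_test({(1, 1): 10, (2, 2): 10})
    assert res.method == "enumeration"
    assert res.p_value < 0.001
    assert res.p_value == pytest.approx(_hwe_oracle_two_alleles(10, 0, 10))


def test_hwe_monomorphic_p_is_one():
    assert hwe_exact_test({(1, 1): 5}).p_value == 1.0


@pytest.mark.parametrize(
    "table",
    [
        {(1, 1): 4, (1, 2): 3, (2, 2): 5},
        {(1, 1): 8, (1, 2): 1, (2, 2): 2},
        {(1, 1): 2, (1, 2): 9, (2, 2): 1},
    ],
)
def test_hwe_enumeration_matches_independent_oracle(table):
    res = hwe_exact_test(table)
    n_aa = table.get((1, 1), 0)
    n_ab = table.get((1, 2), 0)
    n_bb = table.get((2, 2), 0)
    assert res.p_value == pytest.approx(_hwe_oracle_two_alleles(n_aa, n_ab, n_bb))


def test_hwe_monte_carlo_agrees_with_enumeration():
    table = {(1, 1): 6, (1, 2): 2, (2, 2): 6}
    exact = hwe_exact_test(table).p_value
    mc = hwe_exact_test(table, chain_length=20_000, seed=5, enumeration_cap=0)
    assert mc.method == "monte-carlo"
    assert abs(mc.p_value - exact) <= 3 * mc.se


def test_hwe_null_pvalues_are_sub_uniform():
    """p-values of HW-simulated genotypes must be conservative: the
    empirical CDF may not exceed the uniform beyond a Kolmogorov band."""
    rng = np.random.default_rng(9)
    n_rep, n_ind = 200, 25
    pvals = []
    for _ in range(n_rep):
        p = rng.dirichlet([2.0, 2.0, 2.0])
        genos = {}
        for _i in range(n_ind):
            pair = tuple(sorted(rng.choice(3, 2, p=p)))
            genos[pair] = genos.get(pair, 0) + 1
        pvals.append(hwe_exact_test(genos).p_value)
    pvals = np.sort(pvals)
    ecdf = np.arange(1, n_rep + 1) / n_rep
    band = 1.63 / np.sqrt(n_rep)  # ~1% Kolmogorov
    assert np.all(ecdf - pvals <= band)


# ---------------------------------------------------------------------------
# assembled tables
# ---------------------------------------------------------------------------

def test_locus_stats_and_population_summary(tiny_db):
    per_locus = locus_stats(tiny_db)
    assert set(per_locus["population"]) == {"north", "south"}
    north = per_locus[per_locus["population"] == "north"]
    assert (north["Ne"] <= north["Na"] + 1e-9).all()
    assert (north["uHe"] >= north["He"] - 1e-12).all()
    summary = population_summary(per_locus)
    row = summary[summary["population"] == "north"].iloc[0]
    assert row["He_mean"] == pytest.approx(
        north["He"].mean()
    )


def test_locus_stats_invariants_on_simulated_data(sim_small):
    db, _ = sim_small
    df = locus_stats(db)
    assert (df["Ne"] >= 1 - 1e-12).all()
    assert (df["Ne"] <= df["Na"] + 1e-9).all()
    assert (df["He"] >= 0).all() and (df["He"] < 1).all()
    assert (df["uHe"] >= df["He"] - 1e-12).all()
    ok = df["AR"].notna()
    assert (df.loc[ok, "AR"] <= df.loc[ok, "Na"] + 1e-9).all()


def test_fis_near_zero_under_hardy_weinberg(sim_default):
    """Genotypes are drawn in HW proportions, so the across-locus mean FIS
    per population should scatter around zero."""
    db, _ = sim_default
    df = locus_stats(db)
    mean_fis = df.groupby("population")["FIS"].mean()
    assert abs(mean_fis.mean()) < 0.05
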