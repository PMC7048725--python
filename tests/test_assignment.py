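"""Rannala-Mountain likelihoods, scores, leave-one-out, exclusion p-values."""

import itertools
import math

import numpy as np
import pytest

from strassign import (
    MultilocusGenotype,
    alleles_per_locus,
    assign_batch,
    assignment_scores,
    classify,
    exclusion_pvalue,
    leave_one_out_validation,
    reference_units,
    rm_likelihood,
    simulate_queries,
    simulate_reference,
    SimulationConfig,
)
from strassign.assignment import ReferenceUnit, rm_locus_probability
from strassign.genotype_db import AlleleCountTable


def _unit(counts, locus="L1"):
    return ReferenceUnit("u", AlleleCountTable("u", {locus: counts}))


# ---------------------------------------------------------------------------
# per-locus posterior-predictive probability
# ---------------------------------------------------------------------------

def test_empty_unit_heterozygote_prior_probability():
    # n = 0, K = 2: E[2 p_a p_b] under Dirichlet(1/2, 1/2) = 0.25
    assert rm_locus_probability((1, 2), {}, 2) == pytest.approx(0.25)


def test_hand_worked_heterozygote_probability():
    # counts {A:3, B:1}, K = 2: 2 * 3.5 * 1.5 / (5 * 6) = 0.35
    assert rm_locus_probability((1, 2), {1: 3, 2: 1}, 2) == pytest.approx(0.35)


def test_prior_probability_matches_dirichlet_mc_oracle():
    """E[2 p_a p_b] and E[p_a^2] under the Dirichlet posterior, estimated
    by direct Monte Carlo over frequencies, must match the closed form."""
    rng = np.random.default_rng(17)
    n_mc = 200_000
    for counts, k in [({}, 2), ({1: 3, 2: 1}, 2), ({1: 2, 2: 2, 3: 6}, 4)]:
        alpha = np.full(k, 1.0 / k)
        for a, c in counts.items():
            alpha[a - 1] += c
        p = rng.dirichlet(alpha, size=n_mc)
        for pair in [(1, 1), (1, 2)]:
            a, b = pair
            if a == b:
                draws = p[:, a - 1] ** 2
            else:
                draws = 2 * p[:, a - 1] * p[:, b - 1]
            # posterior-predictive of a genotype = E over Dirichlet, but the
            # homozygote form has the extra +1 polya term: compare against
            # E[p_a p_b] with the exchangeable correction via direct pairs
            mc = draws.mean()
            se = draws.std() / math.sqrt(n_mc)
            if a == b:
                # closed form E[p^2] = (n_a+t)(n_a+t+1)/((n+1)(n+2)), t=1/K
                t, n = 1.0 / k, sum(counts.values())
                na = counts.get(a, 0)
                closed = (na + t) * (na + t + 1) / ((n + 1) * (n + 2))
            else:
                closed = rm_locus_probability(pair, counts, k)
            assert abs(mc - closed) <= 3 * se


@pytest.mark.parametrize("k", [2, 3, 4, 6])
def test_locus_probabilities_sum_to_one(k):
    rng = np.random.default_rng(k)
    counts = {a + 1: int(rng.integers(0, 6)) for a in range(k)}
    total = sum(
        rm_locus_probability((a, b), counts, k)
        for a, b in itertools.combinations_with_replacement(range(1, k + 1), 2)
    )
    assert total == pytest.approx(1.0, abs=1e-12)


def test_rm_likelihood_skips_missing_loci():
    g = MultilocusGenotype("q", {"L1": (1, 2), "L2": None})
    unit = AlleleCountTable("u", {"L1": {1: 3, 2: 1}, "L2": {1: 4}})
    ll = rm_likelihood(g, unit, {"L1": 2, "L2": 1})
    assert ll == pytest.approx(math.log(0.35))


def test_monotonicity_in_matching_alleles():
    """Adding copies of the query's own alleles to a unit never lowers the
    query's likelihood there."""
    g = MultilocusGenotype("q", {"L1": (1, 2)})
    k = {"L1": 4}
    base = rm_likelihood(g, AlleleCountTable("u", {"L1": {1: 2, 2: 1, 3: 5}}), k)
    more = rm_likelihood(g, AlleleCountTable("u", {"L1": {1: 3, 2: 2, 3: 5}}), k)
    assert more >= base


# ---------------------------------------------------------------------------
# scores and threshold
# ---------------------------------------------------------------------------

def test_identical_units_split_scores_equally():
    g = MultilocusGenotype("q", {"L1": (1, 2)})
    counts = {"L1": {1: 3, 2: 3}}
    units = [
        ReferenceUnit("a", AlleleCountTable("a", counts)),
        ReferenceUnit("b", AlleleCountTable("b", counts)),
    ]
    res = assignment_scores(g, units, {"L1": 2})
    assert res.scores == pytest.approx([50.0, 50.0])
    assert res.scores.sum() == pytest.approx(100.0)


def test_single_unit_scores_100():
    g = MultilocusGenotype("q", {"L1": (1, 1)})
    res = assignment_scores(g, [_unit({1: 4})], {"L1": 1})
    assert res.best_score == pytest.approx(100.0)


def test_scores_invariant_to_unit_order_and_locus_order(tiny_db):
    g = MultilocusGenotype("q", {"L1": (100, 102), "L2": (200, 202)})
    k = alleles_per_locus(tiny_db, [g])
    units = reference_units(tiny_db)
    fwd = assignment_scores(g, units, k)
    rev = assignment_scores(g, units[::-1], k)
    for uid in fwd.unit_ids:
        assert fwd.scores[fwd.unit_ids.index(uid)] == pytest.approx(
            rev.scores[rev.unit_ids.index(uid)]
        )


class FakeResult:
    def __init__(self, best):
        self.best_score = best

    def assigned(self, t=70.0):
        return self.best_score > t


@pytest.mark.parametrize(
    "score,decision",
    [(70.05, "assigned"), (69.54, "unassigned"), (70.0, "unassigned")],
)
def test_threshold_is_strict(score, decision):
    assert classify(FakeResult(score)) == decision


# ---------------------------------------------------------------------------
# leave-one-out validation
# ---------------------------------------------------------------------------

def test_loo_perfect_on_disjoint_units():
    rng = np.random.default_rng(1)
    from strassign import Locality, ReferenceDatabase

    loci = [f"L{i}" for i in range(6)]
    inds = []
    for pop, offset in [("a", 100), ("b", 200)]:
        for i in range(15):
            calls = {
                l: tuple(sorted(rng.integers(offset, offset + 6, 2).tolist()))
                for l in loci
            }
            inds.append(MultilocusGenotype(f"{pop}{i}", calls, pop))
    db = ReferenceDatabase(loci, [Locality("a"), Locality("b")], inds)
    rep = leave_one_out_validation(db)
    assert rep.percent_correct == 100.0
    assert rep.quality_index > 99.0
    assert rep.confusion.loc["a", "a"] == 15


def test_loo_symmetric_identical_units_near_chance():
    """Two units simulated from the same frequencies: correct
    re-assignment hovers around 50%."""
    rates = []
    for seed in range(5):
        cfg = SimulationConfig(
            n_clusters=1, localities_per_cluster=(2,),
            individuals_per_locality=15, n_loci=6, alleles_per_locus=5,
            cluster_drift=0.2, locality_drift=0.001, seed=seed + 40,
        )
        db, _ = simulate_reference(cfg)
        rep = leave_one_out_validation(db)
        rates.append(rep.percent_correct)
    assert 30 < np.mean(rates) < 70


def test_loo_quality_index_in_range(sim_small):
    db, _ = sim_small
    rep = leave_one_out_validation(db, "cluster")
    assert 0 <= rep.quality_index <= 100
    assert rep.n_reference == len(db.individuals)
    assert rep.confusion.to_numpy().sum() == rep.n_reference


def test_loo_singleton_unit_skipped():
    from strassign import Locality, ReferenceDatabase

    inds = [
        MultilocusGenotype("a1", {"L1": (1, 2)}, "a"),
        MultilocusGenotype("b1", {"L1": (3, 4)}, "b"),
        MultilocusGenotype("b2", {"L1": (3, 3)}, "b"),
    ]
    db = ReferenceDatabase(["L1"], [Locality("a"), Locality("b")], inds)
    rep = leave_one_out_validation(db)
    skipped = rep.per_individual[rep.per_individual["skipped"].notna()]
    assert list(skipped["individual_id"]) == ["a1"]
    assert rep.n_reference == 2


# ---------------------------------------------------------------------------
# exclusion p-values
# ---------------------------------------------------------------------------

def test_exclusion_p_uniform_under_null():
    """Queries drawn from the unit itself get p-values spread over (0, 1]."""
    rng = np.random.default_rng(23)
    counts = {f"L{l}": {a: int(c) for a, c in
                        enumerate(rng.multinomial(40, rng.dirichlet(np.ones(5))))}
              for l in range(5)}
    unit = ReferenceUnit("u", AlleleCountTable("u", counts))
    k = {f"L{l}": 5 for l in range(5)}
    pvals = []
    for i in range(60):
        calls = {}
        for l in range(5):
            freqs = np.array([counts[f"L{l}"].get(a, 0) for a in range(5)],
                             dtype=float)
            freqs /= freqs.sum()
            a, b = rng.choice(5, 2, p=freqs)
            calls[f"L{l}"] = tuple(sorted((int(a), int(b))))
        q = MultilocusGenotype(f"q{i}", calls)
        pvals.append(exclusion_pvalue(q, unit, k, n_sim=400, seed=i))
    pvals = np.array(pvals)
    assert 0.25 < pvals.mean() < 0.75
    assert (pvals < 0.05).mean() < 0.2


def test_exclusion_p_small_for_foreign_alleles():
    unit = _unit({1: 20, 2: 20})
    k = {"L1": 30}
    q = MultilocusGenotype("q", {"L1": (25, 26)})  # alleles absent from unit
    p = exclusion_pvalue(q, unit, k, n_sim=2_000, seed=0)
    assert p < 0.05


def test_exclusion_p_never_zero():
    unit = _unit({1: 50})
    q = MultilocusGenotype("q", {"L1": (9, 9)})
    p = exclusion_pvalue(q, unit, {"L1": 60}, n_sim=500, seed=1)
    assert p >= 1 / 501


# ---------------------------------------------------------------------------
# batch assignment
# ---------------------------------------------------------------------------

def test_batch_recovers_cluster_origins(sim_small):
    db, truth = sim_small
    queries, origins = simulate_queries(truth, n_per_locality=2, seed=99)
    table = assign_batch(queries, db, grouping_levels=("cluster",))
    correct = sum(
        row.best_cluster == truth.locality_cluster[origins[row.individual_id]]
        for row in table.itertuples()
    )
    assert len(table) == len(queries)
    assert correct / len(queries) > 0.9


def test_batch_query_identical_to_reference_individual(sim_small):
    db, _ = sim_small
    ref = db.individuals[0]
    q = MultilocusGenotype("copycat", dict(ref.calls), None)
    table = assign_batch([q], db, grouping_levels=("locality",))
    assert table.iloc[0]["best_locality"] == ref.origin_label


def test_batch_locus_mismatch_is_error(sim_small):
    db, _ = sim_small
    q = MultilocusGenotype("q", {"NOT_A_LOCUS": (1, 2)})
    with pytest.raises(ValueError, match="NOT_A_LOCUS"):
        assign_batch([q], db)
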