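"""Per-population, per-locus diversity statistics and the HWE exact test.

Implements the classical microsatellite summary panel: number of alleles
(Na), effective number of alleles (Ne = 1/sum p_i^2), observed and expected
heterozygosity (Ho, He = 1 - sum p_i^2), Nei's sample-size-unbiased
heterozygosity (uHe = 2N/(2N-1) * He), private alleles (PA), rarefied
allelic richness (AR), and the inbreeding coefficient FIS.

The Hardy-Weinberg exact test uses Levene's conditional distribution of
genotype arrays given allele counts: complete enumeration when the array
space is small, otherwise Monte Carlo (random re-pairing of gene copies,
which samples the Levene distribution exactly).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "effective_alleles",
    "expected_heterozygosity",
    "unbiased_heterozygosity",
    "observed_heterozygosity",
    "private_alleles",
    "allelic_richness",
    "inbreeding_coefficient",
    "hwe_exact_test",
    "HWETestResult",
    "locus_stats",
    "population_summary",
    "summary_table",
]


def _freqs(counts_at_locus):
    total = sum(counts_at_locus.values())
    if total == 0:
        return None
    return np.array([c / total for c in counts_at_locus.values() if c > 0])


def effective_alleles(counts_at_locus):
    """Ne = 1 / sum(p_i^2); the number of equifrequent alleles giving the
    same homozygosity.  Returns None when no gene copies were sampled."""
    p = _freqs(counts_at_locus)
    if p is None:
        return None
    return 1.0 / float(np.sum(p ** 2))


def expected_heterozygosity(counts_at_locus):
    """He = 1 - sum(p_i^2) (Nei's gene diversity, no sample-size correction)."""
    p = _freqs(counts_at_locus)
    if p is None:
        return None
    return 1.0 - float(np.sum(p ** 2))


def unbiased_heterozygosity(counts_at_locus, n_typed):
    """uHe = (2N / (2N - 1)) * He with N the number of typed individuals."""
    if n_typed == 0:
        return None
    he = expected_heterozygosity(counts_at_locus)
    if he is None:
        return None
    return 2 * n_typed / (2 * n_typed - 1) * he


def observed_heterozygosity(genotypes_at_locus):
    """Fraction of typed individuals carrying two distinct alleles.

    ``genotypes_at_locus``: iterable of (a, b) pairs (missing excluded)."""
    pairs = [p for p in genotypes_at_locus if p is not None]
    if not pairs:
        return None
    return sum(a != b for a, b in pairs) / len(pairs)


def private_alleles(all_population_counts, population_id):
    """Number of (locus, allele) combinations found only in this population."""
    if len(all_population_counts) < 2:
        raise ValueError("private alleles undefined with a single population")
    target = next(
        t for t in all_population_counts if t.population_id == population_id
    )
    others = [t for t in all_population_counts if t is not target]
    count = 0
    for locus, alleles in target.counts.items():
        for allele, c in alleles.items():
            if c == 0:
                continue
            if all(o.counts.get(locus, {}).get(allele, 0) == 0 for o in others):
                count += 1
    return count


def allelic_richness(counts_at_locus, n_standard):
    """Rarefied allelic richness: expected distinct alleles among 2n genes.

    AR = sum_i [1 - C(2N - N_i, 2n) / C(2N, 2n)] where N_i is the gene-copy
    count of allele i among the 2N sampled genes and n the standardized
    number of individuals.  Each term is the probability that allele i
    appears at least once in a random draw of 2n of the 2N genes.
    """
    genes = sum(counts_at_locus.values())
    draw = 2 * n_standard
    if draw > genes:
        raise ValueError(
            f"rarefaction size 2*{n_standard} exceeds {genes} sampled genes"
        )
    denom = math.comb(genes, draw)
    total = 0.0
    for ni in counts_at_locus.values():
        if ni > 0:
            total += 1.0 - math.comb(genes - ni, draw) / denom
    return total


def inbreeding_coefficient(genotypes_at_locus, estimator="unbiased"):
    """Per-locus FIS: heterozygote deficit relative to expectation.

    ``estimator="unbiased"`` uses (uHe - Ho)/uHe; ``"nei"`` uses
    (He - Ho)/He.  Returns None for monomorphic data (denominator zero).
    """
    pairs = [p for p in genotypes_at_locus if p is not None]
    if not pairs:
        return None
    counts: dict = {}
    for a, b in pairs:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    ho = observed_heterozygosity(pairs)
    if estimator == "unbiased":
        denom = unbiased_heterozygosity(counts, len(pairs))
    elif estimator == "nei":
        denom = expected_heterozygosity(counts)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if not denom:
        return None
    return (denom - ho) / denom


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@dataclass
class HWETestResult:
    p_value: float
    method: str            # "enumeration" | "monte-carlo"
    se: float | None = None


def _genotype_matrix(genotype_counts):
    """Normalize {(a,b): count} to a canonical dict with a <= b keys."""
    table: dict = {}
    for (a, b), c in genotype_counts.items():
        key = (a, b) if a <= b else (b, a)
        table[key] = table.get(key, 0) + c
    return table


def _allele_counts_from_table(table):
    counts: dict = {}
    for (a, b), c in table.items():
        counts[a] = counts.get(a, 0) + c
        counts[b] = counts.get(b, 0) + c
    return counts


def _log_levene(table, n_ind, allele_counts):
    """log P(genotype array | allele counts) under random pairing (Levene)."""
    h = sum(c for (a, b), c in table.items() if a != b)
    lp = (
        gammaln(n_ind + 1)
        + sum(gammaln(c + 1) for c in allele_counts.values())
        + h * math.log(2)
        - gammaln(2 * n_ind + 1)
        - sum(gammaln(c + 1) for c in table.values())
    )
    return float(lp)


def _enumerate_tables(alleles, allele_counts):
    """Yield every genotype array consistent with the given allele counts."""
    k = len(alleles)
    cells = [(i, j) for i in range(k) for j in range(i, k)]

    def rec(idx, remaining, current):
        if idx == len(cells):
            if all(r == 0 for r in remaining):
                yield dict(current)
            return
        i, j = cells[idx]
        a, b = alleles[i], alleles[j]
        if i == j:
            cap = remaining[i] // 2
        else:
            cap = min(remaining[i], remaining[j])
        for c in range(cap + 1):
            rem = list(remaining)
            if i == j:
                rem[i] -= 2 * c
            else:
                rem[i] -= c
                rem[j] -= c
            current[(a, b)] = c
            yield from rec(idx + 1, rem, current)
            del current[(a, b)]

    remaining = [allele_counts[a] for a in alleles]
    yield from rec(0, remaining, {})


def _count_table_space(allele_counts, cap):
    """Cheap upper bound on the enumeration size; stops early past ``cap``."""
    est = 1
    for c in sorted(allele_counts.values(), reverse=True)[1:]:
        est *= c + 1
        if est > cap:
            return est
    return est


def hwe_exact_test(genotype_counts, chain_length=200_000, seed=0,
                   enumeration_cap=50_000):
    """Exact test of Hardy-Weinberg proportions on one locus.

    ``genotype_counts``: mapping (allele_a, allele_b) -> number of
    individuals.  The p-value is the probability, under Levene's
    distribution conditional on the observed allele counts, of genotype
    arrays no more probable than the observed one.  Complete enumeration is
    used when the array space is small; otherwise a Monte Carlo scheme that
    randomly re-pairs the 2N gene copies (an exact draw from the Levene
    distribution per iteration) estimates p with a binomial standard error.
    """
    table = _genotype_matrix(genotype_counts)
    n_ind = sum(table.values())
    if n_ind < 3:
        raise ValueError("need at least 3 typed individuals")
    allele_counts = _allele_counts_from_table(table)
    alleles = sorted(allele_counts)
    if len(alleles) < 2:
        return HWETestResult(1.0, "enumeration")

    lp_obs = _log_levene(table, n_ind, allele_counts)
    tol = 1e-12

    if _count_table_space(allele_counts, enumeration_cap) <= enumeration_cap:
        p = 0.0
        for cand in _enumerate_tables(alleles, allele_counts):
            lp = _log_levene(cand, n_ind, allele_counts)
            if lp <= lp_obs + tol:
                p += math.exp(lp)
        return HWETestResult(min(p, 1.0), "enumeration")

    rng = np.random.default_rng(seed)
    genes = np.array(
        [a for a, c in allele_counts.items() for _ in range(c)]
    )
    hits = 0
    for _ in range(chain_length):
        rng.shuffle(genes)
        pairs = genes.reshape(-1, 2)
        cand: dict = {}
        for a, b in pairs:
            key = (a, b) if a <= b else (b, a)
            cand[key] = cand.get(key, 0) + 1
        if _log_levene(cand, n_ind, allele_counts) <= lp_obs + tol:
            hits += 1
    p = hits / chain_length
    se = math.sqrt(max(p * (1 - p), 1 / chain_length) / chain_length)
    return HWETestResult(p, "monte-carlo", se)


# ---------------------------------------------------------------------------
# Assembled per-locus / per-population tables
# ---------------------------------------------------------------------------

def locus_stats(db, counts_tables=None, ar_n_standard=None,
                fis_estimator="unbiased"):
    """Long-format per-population, per-locus statistics DataFrame.

    ``ar_n_standard``: individuals in the rarefaction sample; defaults per
    locus to the minimum across populations of individuals typed there
    (so every population supports the draw).
    """
    from .genotype_db import allele_counts as _allele_counts

    tables = counts_tables or _allele_counts(db, "locality")
    by_pop = {t.population_id: t for t in tables}

    if ar_n_standard is None:
        ar_std = {}
        for locus in db.loci:
            typed = [
                t.n_typed(locus) for t in tables if t.genes_sampled.get(locus)
            ]
            ar_std[locus] = min(typed) if typed else 0
    else:
        ar_std = {locus: ar_n_standard for locus in db.loci}

    rows = []
    for pop_id, table in by_pop.items():
        members = {
            g.individual_id for g in db.individuals
            if g.origin_label in _members_of(db, pop_id)
        }
        for locus in db.loci:
            counts = table.counts.get(locus, {})
            genes = table.genes_sampled.get(locus, 0)
            genos = [
                g.calls.get(locus) for g in db.individuals
                if g.individual_id in members and g.calls.get(locus) is not None
            ]
            if genes == 0:
                continue
            n_typed = genes // 2
            na = sum(1 for c in counts.values() if c > 0)
            row = dict(
                population=pop_id,
                locus=locus,
                N_typed=n_typed,
                Na=na,
                Ne=effective_alleles(counts),
                Ho=observed_heterozygosity(genos),
                He=expected_heterozygosity(counts),
                uHe=unbiased_heterozygosity(counts, n_typed),
                AR=(
                    allelic_richness(counts, ar_std[locus])
                    if 0 < 2 * ar_std[locus] <= genes else None
                ),
                FIS=inbreeding_coefficient(genos, fis_estimator),
            )
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        pa = {
            t.population_id: private_alleles(tables, t.population_id)
            for t in tables
        } if len(tables) > 1 else {t.population_id: None for t in tables}
        df["PA_population"] = df["population"].map(pa)
    return df


def _members_of(db, pop_id):
    # locality grouping: pop_id is a locality name
    if pop_id in db.locality_names:
        return {pop_id}
    cmap = db.cluster_map()
    return {name for name, cid in cmap.items() if str(cid) == str(pop_id)}


def population_summary(per_locus_df):
    """Mean and SD across loci for each statistic, per population."""
    stats = ["Na", "Ne", "Ho", "He", "uHe", "AR", "FIS"]
    out = []
    for pop, sub in per_locus_df.groupby("population", sort=False):
        row = {"population": pop, "N": int(sub["N_typed"].max())}
        for s in stats:
            vals = sub[s].dropna()
            row[f"{s}_mean"] = vals.mean() if len(vals) else None
            row[f"{s}_sd"] = vals.std(ddof=1) if len(vals) > 1 else None
        if "PA_population" in sub:
            row["PA"] = sub["PA_population"].iloc[0]
        out.append(row)
    return pd.DataFrame(out)


def summary_table(db, **kwargs):
    """Convenience: per-locus long table plus per-population mean/SD table."""
    per_locus = locus_stats(db, **kwargs)
    return per_locus, population_summary(per_locus)


def hwe_matrix(db, chain_length=100_000, seed=0):
    """Population x locus matrix of HWE exact-test p-values."""
    rows = {}
    for name in db.locality_names:
        inds = db.individuals_of(name)
        rows[name] = {}
        for locus in db.loci:
            genos: dict = {}
            for g in inds:
                pair = g.calls.get(locus)
                if pair is not None:
                    genos[pair] = genos.get(pair, 0) + 1
            if sum(genos.values()) < 3:
                rows[name][locus] = None
                continue
            res = hwe_exact_test(genos, chain_length=chain_length, seed=seed)
            rows[name][locus] = res.p_value
    return pd.DataFrame(rows).T[db.loci]
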