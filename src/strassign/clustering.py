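"""Admixture-model Bayesian clustering, run alignment, and Evanno's ΔK.

The sampler implements the standard admixture model for unlinked,
codominant loci: each gene copy carries a latent cluster label Z, each
cluster k has allele frequencies P_k per locus, and each individual i has
an admixture vector Q_i on the K-simplex.  Gibbs updates:

* ``P_k,l | Z`` — Dirichlet posterior.  Independent-frequency mode uses a
  flat Dirichlet(1) prior; correlated mode uses an F-model prior
  Dirichlet(p_anc * (1-F_k)/F_k) around ancestral frequencies, with one
  drift parameter F_k per cluster updated by a Metropolis step.
* ``Q_i | Z`` — Dirichlet(alpha + copy counts); alpha is shared across
  clusters and updated by a Metropolis random walk on log(alpha).
* ``Z | P, Q`` — per-copy multinomial.

With ``locprior`` enabled, the prior on Q_i mixes a symmetric component
with the sampling location's current mean membership (weight ``r``), a
simplified form of location-informed priors.

The data log-probability reported per run is mean(lnL) - var(lnL)/2 over
post-burn-in samples, and ΔK is the absolute second difference of the mean
data log-probability across K, divided by its between-run SD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ClusterRun",
    "EvannoTable",
    "encode_genotypes",
    "admixture_gibbs",
    "align_runs",
    "evanno_delta_k",
    "localities_to_clusters",
    "membership_barplot",
]


@dataclass
class ClusterRun:
    """One MCMC run: posterior-mean Q and P plus the lnP(data) estimate."""

    K: int
    Q: np.ndarray                 # individuals x K
    P: list                       # per locus: K x n_alleles
    lnP_data: float
    seed: int
    iterations: int
    burnin: int
    individual_ids: list = None
    allele_labels: list = None    # per locus, label order of P columns


@dataclass
class EvannoTable:
    """Mean/SD of lnP(data) per K and the ΔK statistic (interior K only)."""

    table: pd.DataFrame

    @property
    def best_k(self):
        dk = self.table["delta_k"].dropna()
        if dk.empty:
            raise ValueError("no interior K with defined delta K")
        return int(self.table.loc[dk.idxmax(), "K"])


def encode_genotypes(db):
    """Integer-code the database's allele matrix for the sampler.

    Returns (alleles, missing_mask, labels): ``alleles`` is an
    (N, L, 2) int array of per-locus allele codes (0-based; -1 = missing),
    ``labels`` the per-locus label lists defining the coding.
    """
    n, loci = len(db.individuals), db.loci
    labels = []
    for locus in loci:
        seen = sorted({
            a for g in db.individuals
            for a in (g.calls.get(locus) or ())
        })
        labels.append(seen)
    code = [{a: i for i, a in enumerate(lab)} for lab in labels]
    alleles = np.full((n, len(loci), 2), -1, dtype=np.int64)
    for i, g in enumerate(db.individuals):
        for l, locus in enumerate(loci):
            pair = g.calls.get(locus)
            if pair is not None:
                alleles[i, l, 0] = code[l][pair[0]]
                alleles[i, l, 1] = code[l][pair[1]]
    return alleles, alleles[..., 0] >= 0, labels


def _sample_rows(prob, rng):
    """Sample one category per row of a row-stochastic matrix."""
    cum = np.cumsum(prob, axis=1)
    u = rng.random(prob.shape[0])[:, None] * cum[:, -1:]
    return (u >= cum).sum(axis=1)


def _dirichlet_rows(alpha_matrix, rng):
    g = rng.gamma(np.maximum(alpha_matrix, 1e-12))
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=1, keepdims=True)


def _log_dirichlet_pdf(x, alpha):
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum()
        + ((alpha - 1) * np.log(np.maximum(x, 1e-300))).sum()
    )


def admixture_gibbs(db, K, iterations=10_000, burnin=1_000, seed=0,
                    correlated_freqs=True, locprior=False, locprior_r=0.7,
                    alpha0=1.0, thin=10):
    """Run the admixture-model Gibbs sampler on a reference database.

    Parameters mirror common practice: ``iterations`` are post-burn-in
    sweeps, ``burnin`` sweeps are discarded, ``thin`` controls how often
    posterior samples are recorded.  Returns posterior means and the
    lnP(data) estimate used by model choice across K.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if iterations <= 0 or burnin < 0:
        raise ValueError("iterations must be positive and burnin >= 0")
    rng = np.random.default_rng(seed)
    alleles, typed, labels = encode_genotypes(db)
    n, L, _ = alleles.shape
    n_alleles = [len(lab) for lab in labels]

    loc_names = db.locality_names
    loc_index = {name: i for i, name in enumerate(loc_names)}
    loc_of = np.array([loc_index[g.origin_label] for g in db.individuals])
    n_loc = len(loc_names)

    # ancestral frequencies for the F-model: overall empirical frequencies
    p_anc = []
    for l in range(L):
        counts = np.zeros(n_alleles[l])
        for c in range(2):
            m = typed[:, l]
            counts += np.bincount(alleles[m, l, c], minlength=n_alleles[l])
        p_anc.append((counts + 0.5) / (counts + 0.5).sum())

    # state
    Q = np.full((n, K), 1.0 / K)
    P = [
        _dirichlet_rows(np.ones((K, n_alleles[l])), rng) for l in range(L)
    ]
    Z = [rng.integers(0, K, size=(n, 2)) for _ in range(L)]
    # start the drift parameters diffuse: a small initial F makes the
    # F-model prior overwhelm the data before clusters can separate
    F = np.full(K, 0.3)
    alpha = alpha0

    q_sum = np.zeros_like(Q)
    p_sum = [np.zeros_like(P[l]) for l in range(L)]
    lnl_samples = []
    n_rec = 0

    total = burnin + iterations
    for sweep in range(total):
        # --- Z | P, Q ------------------------------------------------------
        copy_counts = np.zeros((n, K))
        for l in range(L):
            m = typed[:, l]
            for c in range(2):
                a = alleles[m, l, c]
                w = Q[m] * P[l][:, a].T           # (n_typed, K)
                z = _sample_rows(w, rng)
                Z[l][m, c] = z
                copy_counts[np.where(m)[0], z] += 1

        # --- P | Z ---------------------------------------------------------
        for l in range(L):
            m = typed[:, l]
            counts = np.zeros((K, n_alleles[l]))
            for c in range(2):
                a = alleles[m, l, c]
                z = Z[l][m, c]
                np.add.at(counts, (z, a), 1.0)
            if correlated_freqs:
                prior = np.outer((1.0 - F) / F, p_anc[l])
            else:
                prior = np.ones((K, n_alleles[l]))
            P[l] = _dirichlet_rows(prior + counts, rng)

        # --- F_k (correlated mode): random-walk Metropolis on logit --------
        if correlated_freqs and K > 1:
            for k in range(K):
                f_new = F[k] * np.exp(rng.normal(0.0, 0.3))
                if not (1e-4 < f_new < 0.99):
                    continue
                lp_old = sum(
                    _log_dirichlet_pdf(
                        P[l][k], p_anc[l] * (1 - F[k]) / F[k]
                    ) for l in range(L)
                )
                lp_new = sum(
                    _log_dirichlet_pdf(
                        P[l][k], p_anc[l] * (1 - f_new) / f_new
                    ) for l in range(L)
                )
                # log-scale proposal is symmetric in log(F): Jacobian f_new/F[k]
                if np.log(rng.random()) < lp_new - lp_old + np.log(f_new / F[k]):
                    F[k] = f_new

        # --- Q | Z ---------------------------------------------------------
        if K == 1:
            Q = np.ones((n, 1))
        else:
            if locprior:
                # location mean membership from current copy counts
                eta = np.ones((n_loc, K))
                np.add.at(eta, loc_of, copy_counts)
                eta /= eta.sum(axis=1, keepdims=True)
                prior_q = alpha * (
                    (1 - locprior_r) / K + locprior_r * eta[loc_of]
                ) * K
            else:
                prior_q = np.full((n, K), alpha)
            Q = _dirichlet_rows(prior_q + copy_counts, rng)

        # --- alpha | Q -----------------------------------------------------
        if K > 1 and not locprior:
            a_new = alpha * np.exp(rng.normal(0.0, 0.3))
            if 1e-3 < a_new < 10.0:
                lq = np.log(np.maximum(Q, 1e-300)).sum()
                lp_old = n * (gammaln(K * alpha) - K * gammaln(alpha)) \
                    + (alpha - 1) * lq
                lp_new = n * (gammaln(K * a_new) - K * gammaln(a_new)) \
                    + (a_new - 1) * lq
                if np.log(rng.random()) < lp_new - lp_old + np.log(a_new / alpha):
                    alpha = a_new

        # --- record --------------------------------------------------------
        if sweep >= burnin and (sweep - burnin) % thin == 0:
            lnl = 0.0
            for l in range(L):
                m = typed[:, l]
                for c in range(2):
                    a = alleles[m, l, c]
                    mix = (Q[m] * P[l][:, a].T).sum(axis=1)
                    lnl += np.log(np.maximum(mix, 1e-300)).sum()
            lnl_samples.append(lnl)
            q_sum += Q
            for l in range(L):
                p_sum[l] += P[l]
            n_rec += 1

    lnl_samples = np.array(lnl_samples)
    ln_p_data = float(lnl_samples.mean() - lnl_samples.var() / 2.0)
    return ClusterRun(
        K=K,
        Q=q_sum / n_rec,
        P=[p / n_rec for p in p_sum],
        lnP_data=ln_p_data,
        seed=seed,
        iterations=iterations,
        burnin=burnin,
        individual_ids=[g.individual_id for g in db.individuals],
        allele_labels=labels,
    )


# ---------------------------------------------------------------------------
# Label-switching alignment across runs (CLUMPP-style greedy)
# ---------------------------------------------------------------------------

def _similarity(q1, q2):
    return float((q1 * q2).sum())


def _best_permutation(q_ref, q, exhaustive_max=6):
    K = q.shape[1]
    if K <= exhaustive_max:
        best, best_s = None, -np.inf
        for perm in itertools.permutations(range(K)):
            s = _similarity(q_ref, q[:, perm])
            if s > best_s:
                best, best_s = perm, s
        return list(best)
    # greedy column matching for large K
    sim = q_ref.T @ q                      # K x K
    perm = [-1] * K
    used = set()
    for _ in range(K):
        i, j = np.unravel_index(
            np.argmax(np.where(
                np.isneginf(sim), -np.inf, sim
            )), sim.shape
        )
        perm[i] = j
        sim[i, :] = -np.inf
        sim[:, j] = -np.inf
        used.add(j)
    return perm


def align_runs(runs):
    """Permute cluster columns of each run to match the first run.

    All runs must share K and individual order.  Returns (aligned_runs,
    mean_pairwise_similarity); similarity is the normalized sum of
    per-individual Q dot products against the reference run.
    """
    runs = list(runs)
    if len(runs) < 2:
        raise ValueError("need at least two runs to align")
    K = runs[0].K
    if any(r.K != K for r in runs):
        raise ValueError("runs disagree on K")
    ref = runs[0]
    aligned = [ref]
    sims = []
    norm = np.sqrt((ref.Q ** 2).sum())
    for r in runs[1:]:
        perm = _best_permutation(ref.Q, r.Q)
        q = r.Q[:, perm]
        p = [pl[perm, :] for pl in r.P]
        aligned.append(ClusterRun(
            K=K, Q=q, P=p, lnP_data=r.lnP_data, seed=r.seed,
            iterations=r.iterations, burnin=r.burnin,
            individual_ids=r.individual_ids, allele_labels=r.allele_labels,
        ))
        other = np.sqrt((q ** 2).sum())
        sims.append(_similarity(ref.Q, q) / (norm * other))
    return aligned, float(np.mean(sims))


# ---------------------------------------------------------------------------
# Evanno's ΔK
# ---------------------------------------------------------------------------

def evanno_delta_k(runs_by_k):
    """ΔK over a contiguous range of K from replicate runs.

    ``runs_by_k``: mapping K -> list of ClusterRun (>=2 each).  ΔK(K) =
    |mean lnP(K+1) - 2 mean lnP(K) + mean lnP(K-1)| / SD(lnP(K)); endpoints
    get no ΔK.  A zero between-run SD yields an infinite ΔK with a warning
    in the table.
    """
    ks = sorted(runs_by_k)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    if any(len(runs_by_k[k]) < 2 for k in ks):
        raise ValueError("need >=2 runs per K")
    mean = {k: np.mean([r.lnP_data for r in runs_by_k[k]]) for k in ks}
    sd = {k: np.std([r.lnP_data for r in runs_by_k[k]], ddof=1) for k in ks}
    rows = []
    for k in ks:
        row = dict(K=k, mean_lnP=mean[k], sd_lnP=sd[k], n_runs=len(runs_by_k[k]))
        if k == ks[0] or k == ks[-1]:
            row["delta_k"] = np.nan
        else:
            second = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            row["delta_k"] = second / sd[k] if sd[k] > 0 else np.inf
        rows.append(row)
    return EvannoTable(pd.DataFrame(rows))


def localities_to_clusters(run, db):
    """Assign each locality the cluster maximizing its mean membership.

    Ties go to the lowest cluster index.  Returns {locality name ->
    1-based cluster id}.
    """
    q = run.Q
    out = {}
    ids = {g.individual_id: i for i, g in enumerate(db.individuals)}
    for name in db.locality_names:
        rows = [ids[g.individual_id] for g in db.individuals_of(name)]
        mean_q = q[rows].mean(axis=0)
        out[name] = int(np.argmax(mean_q)) + 1
    return out


def membership_barplot(run, db, path=None, ax=None):
    """Stacked-bar membership plot (individuals grouped by locality)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    order = []
    boundaries = []
    for name in db.locality_names:
        members = [
            i for i, g in enumerate(db.individuals)
            if g.origin_label == name
        ]
        order.extend(members)
        boundaries.append(len(order))
    q = run.Q[order]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(order) / 8), 2.5))
    bottom = np.zeros(len(order))
    x = np.arange(len(order))
    for k in range(run.K):
        ax.bar(x, q[:, k], bottom=bottom, width=1.0)
        bottom += q[:, k]
    for b in boundaries[:-1]:
        ax.axvline(b - 0.5, color="black", linewidth=0.8)
    ax.set_xlim(-0.5, len(order) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("membership")
    ax.set_xticks([])
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
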