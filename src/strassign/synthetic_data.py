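"""Simulate structured microsatellite reference databases and noisy replicates.

Populations follow a hierarchical F-model: ancestral allele frequencies per
locus are drawn from a flat Dirichlet; each cluster's frequencies drift
around the ancestral vector with strength ``F_c`` (Dirichlet with
concentration p_anc * (1-F_c)/F_c, so E[freq] = p_anc and the drift
parameter approximates the cluster-level FST); localities drift around
their cluster the same way with ``F_l``.  Genotypes are drawn under
Hardy-Weinberg proportions within localities.

The replicate/consensus machinery emulates a genotyping protocol for
low-template DNA: each allele of a true genotype independently drops out
per amplification, heterozygotes are replicated twice and homozygote calls
four times, and an allele is only recorded once observed in at least two
amplifications of the same extract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .genotype_db import Locality, MultilocusGenotype, ReferenceDatabase

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_reference",
    "simulate_queries",
    "simulate_replicates",
    "consensus_genotype",
    "NEEDS_MORE_REPLICATES",
    "UNRESOLVED",
]

#: sentinel results of :func:`consensus_genotype`
NEEDS_MORE_REPLICATES = "needs-more-replicates"
UNRESOLVED = "unresolved"


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 3 clusters of differing size holding 15
    localities, 10 loci, 12 individuals per locality (180 reference
    individuals), moderate cluster differentiation and weak locality-level
    drift within clusters."""

    n_clusters: int = 3
    localities_per_cluster: tuple = (2, 4, 9)
    individuals_per_locality: int = 12
    n_loci: int = 10
    alleles_per_locus: int = 8
    cluster_drift: float | tuple = 0.15
    locality_drift: float = 0.03
    dropout_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.localities_per_cluster, int):
            self.localities_per_cluster = (
                (self.localities_per_cluster,) * self.n_clusters
            )
        self.localities_per_cluster = tuple(self.localities_per_cluster)
        if isinstance(self.cluster_drift, (int, float)):
            self.cluster_drift = (float(self.cluster_drift),) * self.n_clusters
        self.cluster_drift = tuple(float(f) for f in self.cluster_drift)
        problems = []
        if self.n_clusters < 1:
            problems.append("n_clusters must be >= 1")
        if len(self.localities_per_cluster) != self.n_clusters:
            problems.append("localities_per_cluster length != n_clusters")
        if any(m < 1 for m in self.localities_per_cluster):
            problems.append("each cluster needs >= 1 locality")
        if self.individuals_per_locality < 1:
            problems.append("individuals_per_locality must be >= 1")
        if self.n_loci < 1 or self.alleles_per_locus < 1:
            problems.append("need >= 1 locus with >= 1 allele")
        if any(not 0 < f < 1 for f in self.cluster_drift):
            problems.append("cluster_drift must lie in (0, 1)")
        if not 0 < self.locality_drift < 1:
            problems.append("locality_drift must lie in (0, 1)")
        if not 0 <= self.dropout_rate < 1:
            problems.append("dropout_rate must lie in [0, 1)")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("localities_per_cluster", "cluster_drift"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulatedTruth:
    """Ground truth of one simulation: frequencies and origins."""

    config: SimulationConfig
    loci: list
    allele_labels: list                  # per locus
    ancestral_freqs: list                # per locus, simplex vector
    cluster_freqs: dict                  # cluster id -> per-locus vectors
    locality_freqs: dict                 # locality name -> per-locus vectors
    locality_cluster: dict               # locality name -> cluster id
    origins: dict = field(default_factory=dict)  # individual id -> locality


def _drifted(base, f, rng):
    conc = base * (1.0 - f) / f
    draw = rng.gamma(np.maximum(conc, 1e-9))
    draw = np.maximum(draw, 1e-300)
    return draw / draw.sum()


def _draw_individual(ind_id, origin, truth, rng):
    calls = {}
    freqs = truth.locality_freqs[origin]
    for l, locus in enumerate(truth.loci):
        p = freqs[l]
        a, b = rng.choice(len(p), size=2, p=p)
        labels = truth.allele_labels[l]
        calls[locus] = (labels[a], labels[b])
    return MultilocusGenotype(ind_id, calls, origin)


def simulate_reference(config):
    """Generate a reference database plus its ground truth.

    Deterministic given ``config.seed``.  Allele labels mimic fragment
    sizes (150, 152, ... base pairs).
    """
    rng = np.random.default_rng(config.seed)
    loci = [f"L{j + 1:02d}" for j in range(config.n_loci)]
    allele_labels = [
        [150 + 2 * a for a in range(config.alleles_per_locus)]
        for _ in loci
    ]

    anc = []
    for _ in loci:
        draw = rng.gamma(np.ones(config.alleles_per_locus))
        anc.append(draw / draw.sum())

    cluster_ids = [f"C{c + 1}" for c in range(config.n_clusters)]
    cluster_freqs = {
        cid: [
            _drifted(anc[l], config.cluster_drift[c], rng)
            for l in range(config.n_loci)
        ]
        for c, cid in enumerate(cluster_ids)
    }

    localities = []
    locality_freqs = {}
    locality_cluster = {}
    idx = 0
    for c, cid in enumerate(cluster_ids):
        for _ in range(config.localities_per_cluster[c]):
            idx += 1
            name = f"Loc {idx}"
            localities.append(Locality(name, cluster_id=cid))
            locality_freqs[name] = [
                _drifted(cluster_freqs[cid][l], config.locality_drift, rng)
                for l in range(config.n_loci)
            ]
            locality_cluster[name] = cid

    truth = SimulatedTruth(
        config=config,
        loci=loci,
        allele_labels=allele_labels,
        ancestral_freqs=anc,
        cluster_freqs=cluster_freqs,
        locality_freqs=locality_freqs,
        locality_cluster=locality_cluster,
    )

    individuals = []
    counter = 0
    for loc in localities:
        for _ in range(config.individuals_per_locality):
            counter += 1
            ind_id = f"ind{counter:04d}"
            individuals.append(_draw_individual(ind_id, loc.name, truth, rng))
            truth.origins[ind_id] = loc.name

    db = ReferenceDatabase(loci, localities, individuals)
    return db, truth


def simulate_queries(truth, n_per_locality=1, seed=0):
    """Draw fresh individuals of known (but withheld) origin.

    ``n_per_locality``: int, or mapping locality name -> count.  Returns
    (queries, hidden_origins); queries carry no origin label.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_per_locality, int):
        plan = {name: n_per_locality for name in truth.locality_freqs}
    else:
        plan = dict(n_per_locality)
    queries, origins = [], {}
    counter = 0
    for name in truth.locality_freqs:
        for _ in range(plan.get(name, 0)):
            counter += 1
            qid = f"query{counter:04d}"
            g = _draw_individual(qid, name, truth, rng)
            queries.append(MultilocusGenotype(qid, g.calls, None))
            origins[qid] = name
    return queries, origins


# ---------------------------------------------------------------------------
# Genotyping-error replicates and the two-observation consensus rule
# ---------------------------------------------------------------------------

def _amplify_call(pair, dropout_rate, rng):
    """One amplification of one locus: allele-wise dropout."""
    observed = [a for a in pair if rng.random() >= dropout_rate]
    if not observed:
        return None
    if len(observed) == 1:
        return (observed[0], observed[0])   # dropout makes a false homozygote
    return tuple(sorted(observed))


def simulate_replicates(genotype, dropout_rate, n_het_reps=2, n_hom_reps=4,
                        seed=0):
    """Replicate amplifications of one individual under allelic dropout.

    Heterozygous loci are amplified ``n_het_reps`` times and homozygous
    loci ``n_hom_reps`` times (the schedule depends on the *true* state,
    mirroring a protocol where apparent homozygotes get extra replicates).
    Returns {locus: [replicate calls]}; a replicate is a pair or None when
    both alleles dropped.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for locus, pair in genotype.calls.items():
        if pair is None:
            out[locus] = []
            continue
        n_reps = n_het_reps if pair[0] != pair[1] else n_hom_reps
        out[locus] = [
            _amplify_call(pair, dropout_rate, rng) for _ in range(n_reps)
        ]
    return out


def consensus_genotype(replicates, n_hom_reps=4):
    """Apply the two-observation consensus rule to one locus's replicates.

    An allele is confirmed once seen in >= 2 replicates.  Two confirmed
    alleles -> heterozygote call; one confirmed allele after at least
    ``n_hom_reps`` replicates -> homozygote call; one confirmed allele on
    fewer replicates -> ``NEEDS_MORE_REPLICATES``; zero or more than two
    confirmed -> ``UNRESOLVED``.
    """
    reps = list(replicates)
    if not reps:
        raise ValueError("need at least one replicate")
    seen: dict = {}
    for call in reps:
        if call is None:
            continue
        for allele in set(call):
            seen[allele] = seen.get(allele, 0) + 1
    confirmed = sorted(a for a, c in seen.items() if c >= 2)
    if len(confirmed) == 2:
        return (confirmed[0], confirmed[1])
    if len(confirmed) == 1:
        if len(reps) >= n_hom_reps:
            return (confirmed[0], confirmed[0])
        return NEEDS_MORE_REPLICATES
    return UNRESOLVED


def consensus_protocol(genotype, dropout_rate, seed=0, n_het_reps=2,
                       n_hom_reps=4, max_extra_rounds=2):
    """Full per-locus protocol: replicate, call consensus, extend if needed.

    When a locus returns ``NEEDS_MORE_REPLICATES`` the replicate set is
    topped up to ``n_hom_reps`` (then by one extra round at a time, up to
    ``max_extra_rounds``); loci still unresolved become missing.  Returns
    {locus: call or None}.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for locus, pair in genotype.calls.items():
        if pair is None:
            out[locus] = None
            continue
        n_reps = n_het_reps if pair[0] != pair[1] else n_hom_reps
        reps = [_amplify_call(pair, dropout_rate, rng) for _ in range(n_reps)]
        extra = 0
        while True:
            call = consensus_genotype(reps, n_hom_reps=n_hom_reps)
            if call == NEEDS_MORE_REPLICATES and extra <= max_extra_rounds:
                want = max(n_hom_reps - len(reps), 1)
                reps += [
                    _amplify_call(pair, dropout_rate, rng)
                    for _ in range(want)
                ]
                extra += 1
                continue
            break
        out[locus] = call if isinstance(call, tuple) else None
    return out
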