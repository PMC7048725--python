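"""Infer the number of genetic clusters with the admixture model + ΔK.

Runs the admixture-model Gibbs sampler at K = 2..6 (several seeds each) on
a strongly structured 3-cluster simulation, computes Evanno's ΔK from the
per-K data log-probabilities, aligns the runs at the chosen K, and maps
each locality to its dominant cluster.
"""

from strassign import (
    SimulationConfig,
    admixture_gibbs,
    align_runs,
    evanno_delta_k,
    localities_to_clusters,
    simulate_reference,
)

cfg = SimulationConfig(
    n_clusters=3, localities_per_cluster=(2, 2, 2),
    individuals_per_locality=10, n_loci=8, alleles_per_locus=6,
    cluster_drift=0.25, locality_drift=0.02, seed=5,
)
db, truth = simulate_reference(cfg)

runs = {
    k: [
        admixture_gibbs(db, k, iterations=800, burnin=250, seed=k * 10 + r)
        for r in range(4)
    ]
    for k in range(2, 7)
}
table = evanno_delta_k(runs)
print(table.table.round(2).to_string(index=False))
print(f"\nselected K = {table.best_k} (planted: 3)")

aligned, similarity = align_runs(runs[table.best_k])
print(f"runs aligned with mean similarity {similarity:.3f}")
print("locality -> cluster:", localities_to_clusters(aligned[0], db))
print("\nΔK peaks at the true K because lnP(data) gains flatten once extra")
print("clusters stop explaining real structure.")
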