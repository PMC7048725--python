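"""Replicate amplification and the two-observation consensus rule.

Fecal-sample genotyping suffers allelic dropout: one allele of a
heterozygote randomly fails to amplify, producing a false homozygote.
The protocol modeled here amplifies heterozygous calls twice and apparent
homozygotes four times, and records an allele only after two independent
observations.  This script measures how much the rule cuts the false-
homozygote rate compared with trusting a single amplification.
"""

import numpy as np

from strassign import MultilocusGenotype, consensus_protocol, simulate_replicates

dropout = 0.2
n_loci = 3000
truth = MultilocusGenotype("demo", {f"L{i}": (1, 2) for i in range(n_loci)})

single = simulate_replicates(truth, dropout, n_het_reps=1, seed=1)
single_rate = np.mean(
    [r[0][0] == r[0][1] for r in single.values() if r[0] is not None]
)

calls = consensus_protocol(truth, dropout, seed=2)
resolved = [c for c in calls.values() if c is not None]
consensus_rate = np.mean([c[0] == c[1] for c in resolved])

print(f"dropout rate per allele per amplification: {dropout}")
print(f"false-homozygote rate, single amplification: {single_rate:.3f}")
print(f"false-homozygote rate, consensus protocol:  {consensus_rate:.4f}")
print(f"loci resolved by the protocol: {len(resolved)}/{n_loci}")
print("\nThe consensus rule trades a few unresolved loci for a much lower")
print("genotyping error rate, protecting downstream assignment.")
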