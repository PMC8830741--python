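"""Sketch the clonal lineage from inferred subclone genotypes.

After clustering, the subclones' genotypes are related by a minimum
spanning tree over Hamming distances, rooted at the unmutated (normal)
genotype; under infinite-sites-like evolution this recovers the ancestry
chain of nested mutation sets.
"""

import numpy as np

import clonemix as cm
from clonemix.lineage import to_newick, total_weight

truth = cm.simulate_dataset(cm.SimConfig(N=120, M=30, K=4, seed=11))
fit = cm.fit_em(truth.gtm(), 4, cm.EMConfig(), np.random.default_rng(11))

tree = cm.build_mst(fit.params.C, include_root=True)
sizes = np.bincount(fit.assignments, minlength=fit.params.K)

print("lineage edges (node 0 = unmutated root):")
for u, v, w in tree.edges:
    print(f"  {u} -- {v}  ({w} mutations apart)")
print(f"total tree weight: {total_weight(tree)} mutations")
print("newick:", to_newick(tree, sizes=sizes))
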