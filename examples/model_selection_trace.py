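"""Watch the subclone-number search decide where to stop.

The pipeline fits K = 1, 2, 3, ... and scores each model by how well the
expected between-cluster distances (given the fitted genotypes and error
rates) match the observed mean distances between the clusters' cells.  The
search stops once the best score has not improved for kappa consecutive K.
"""

import clonemix as cm

truth = cm.simulate_dataset(cm.SimConfig(N=200, M=60, K=4, seed=1))
fit = cm.select_k(truth.gtm(), cm.EMConfig(), kappa=10, seed=1)

print(f"simulated K = 4; selected K = {fit.params.K}\n")
print(f"{'K':>3} {'score s_K':>10} {'log-likelihood':>15}")
for K, s, ll in fit.score_trace:
    marker = "  <-- selected" if K == fit.params.K else ""
    print(f"{K:3d} {s:10.4f} {ll:15.1f}{marker}")
print("\ns_K is the mean over cluster pairs of exp(-(d - d_hat)^2); "
      "1.0 means the fitted model exactly explains the observed separation.")
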