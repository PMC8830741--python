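"""Estimate sequencing error rates jointly with the subclones.

Simulates matrices whose false-positive rate (alpha) and false-negative
rate (beta) are drawn at random, fits the mixture with both rates free, and
compares estimates with the simulated truth.  Over many matrices the
estimated alpha tends to run slightly high because doublet cells merge two
genotypes and present extra mutations the error model can only explain as
false positives.
"""

import numpy as np

import clonemix as cm

rng = np.random.default_rng(42)
em = cm.EMConfig(estimate_alpha=True)

print(f"{'true a':>8} {'est a':>8} {'true b':>8} {'est b':>8}")
true_a, est_a, true_b, est_b = [], [], [], []
for _ in range(10):
    seed = int(rng.integers(2 ** 31))
    config = cm.preset_config("D7", seed=seed)  # 100x100, K=5, drawn rates
    truth = cm.simulate_dataset(config)
    fit = cm.fit_em(truth.gtm(), config.K, em, np.random.default_rng(seed))
    true_a.append(config.alpha)
    est_a.append(fit.params.alpha)
    true_b.append(config.beta)
    est_b.append(fit.params.beta)
    print(f"{config.alpha:8.4f} {fit.params.alpha:8.4f} "
          f"{config.beta:8.4f} {fit.params.beta:8.4f}")

print(f"\ncorrelation(true, est) alpha: {np.corrcoef(true_a, est_a)[0, 1]:.3f}")
print(f"correlation(true, est) beta : {np.corrcoef(true_b, est_b)[0, 1]:.3f}")
print(f"mean alpha bias (doublets)  : {np.mean(np.array(est_a) - np.array(true_a)):+.4f}")
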