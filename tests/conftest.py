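import numpy as np
import pytest

import clonemix as cm


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_gtm():
    """3 cells x 4 loci with one missing entry."""
    return cm.GenotypeMatrix(np.array([
        [0, 1, 1, 0],
        [1, 1, 0, 0],
        [0, cm.MISSING, 1, 1],
    ]))


def random_gtm(rng, n, m, p_missing=0.1):
    vals = rng.choice(
        [0, 1, cm.MISSING], size=(n, m),
        p=[(1 - p_missing) / 2, (1 - p_missing) / 2, p_missing],
    ).astype(np.int8)
    return cm.GenotypeMatrix(vals)


def naive_total_loglik(gtm, params):
    """Literal double-loop evaluation of the mixture log-likelihood."""
    import math
    total = 0.0
    for i in range(gtm.n_cells):
        mix = 0.0
        for k in range(params.K):
            term = math.log(params.pi[k])
            for j in range(gtm.n_loci):
                d = int(gtm.values[i, j])
                c = int(params.C[k, j])
                if d == cm.MISSING:
                    continue
                if c == 1:
                    p = 1 - params.beta if d == 1 else params.beta
                else:
                    p = params.alpha if d == 1 else 1 - params.alpha
                term += math.log(p)
            mix += math.exp(term)
        total += math.log(mix)
    return total


def assert_monotone_trace(fit, tol=1e-8):
    """Log-likelihood never drops outside documented re-seed iterations."""
    trace = fit.ll_trace
    skip = {r + 1 for r in fit.reseed_iters}
    for i in range(1, len(trace)):
        if i in skip:
            continue
        assert trace[i] >= trace[i - 1] - tol, (
            f"log-likelihood dropped at iteration {i}: "
            f"{trace[i - 1]} -> {trace[i]}"
        )
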