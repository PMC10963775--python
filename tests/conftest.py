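import numpy as np
import pytest

from surpass import (
    SyntheticSpec,
    decompose,
    estimate_noise_sigma,
    compute_amplitude_thresholds,
    count_significant_processes,
    generate_dataset,
    log_transform,
)

# pseudocount for generated cohorts: exp(ln X) has no zeros, and a tiny
# pseudocount keeps the planted log-linear structure intact
SYNTH_PSEUDOCOUNT = 1e-6


@pytest.fixture(scope="session")
def default_cohort():
    """Planted 1000x120 cohort at the package's default study conditions."""
    spec = SyntheticSpec(seed=0)
    matrix, meta, truth = generate_dataset(spec)
    return spec, matrix, meta, truth


@pytest.fixture(scope="session")
def default_decomposition(default_cohort):
    """Surprisal decomposition of the default cohort with thresholds."""
    spec, matrix, meta, truth = default_cohort
    L = log_transform(matrix, pseudocount=SYNTH_PSEUDOCOUNT)
    d = decompose(L)
    noise = estimate_noise_sigma(L, fraction=spec.stable_fraction)
    compute_amplitude_thresholds(d, noise, n_surrogates=50, seed=0)
    count_significant_processes(d, noise, L=L)
    return L, d, noise


def planted_correlations(d, truth):
    """|r| between each planted process amplitude and its best-matching
    recovered component."""
    p = truth.planted_lambda.shape[1] - 1
    out = []
    for a in range(1, p + 1):
        best = max(
            abs(np.corrcoef(d.lam[:, j], truth.planted_lambda[:, a])[0, 1])
            for j in range(1, p + 1)
        )
        out.append(best)
    return out
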