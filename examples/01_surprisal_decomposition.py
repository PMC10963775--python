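"""Surprisal analysis of a planted cohort.

Generates a synthetic normal/AML expression matrix, decomposes its log
expression into a steady state plus unbalanced processes, and shows that
the steady state is invariant across samples while the process amplitudes
carry the disease signal.
"""

import numpy as np

import surpass as sp

spec = sp.SyntheticSpec(seed=0)
matrix, meta, truth = sp.generate_dataset(spec)
L = sp.log_transform(matrix, pseudocount=1e-6)

d = sp.decompose(L)
noise = sp.estimate_noise_sigma(L, fraction=spec.stable_fraction)
sp.compute_amplitude_thresholds(d, noise, n_surrogates=100, seed=0)
n_sig = sp.count_significant_processes(d, noise, L=L)

lam0 = d.lam[:, 0]
print(f"cohort: {spec.n_genes} genes x {spec.n_samples} samples, "
      f"{spec.n_processes} planted processes")
print(f"noise floor sigma (stable transcripts): {noise.sigma:.3f} "
      f"(generator used {spec.noise_sd})")
print(f"significant processes: {n_sig}")
print(f"steady-state amplitude: mean {lam0.mean():.1f}, "
      f"CV {100 * lam0.std() / lam0.mean():.2f}% across samples")
print(f"largest process amplitude: {np.abs(d.lam[:, 1:]).max():.1f}")
for a in range(1, n_sig + 1):
    r = max(
        abs(np.corrcoef(d.lam[:, j], truth.planted_lambda[:, a])[0, 1])
        for j in range(1, n_sig + 1)
    )
    print(f"planted process {a}: best |r| with a recovered component = {r:.4f}")

# The steady state barely moves between normal and AML samples (CV < 1%)
# and dwarfs every unbalanced process; the per-sample process amplitudes,
# not the baseline, are what distinguishes patients.
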