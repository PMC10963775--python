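"""Surprisal analysis of log-expression matrices.

Surprisal analysis decomposes the natural-log expression matrix into a
maximal-entropy steady state (component alpha = 0) plus "unbalanced
processes" (alpha >= 1), coordinated deviations from that steady state:

    ln X_i(k) = G_i0 lambda_0(k) - sum_{alpha>=1} G_ia lambda_a(k)

up to the sign convention on each component. Computationally this is the
singular value decomposition of the log matrix, applied directly (no mean
centering): G holds the gene weights (left singular vectors) and
lambda = V * Sigma the per-sample process amplitudes. The equivalent
covariance-matrix diagonalization route yields the same subspaces; the
direct SVD is the numerically safer single code path.

Process significance is judged against the measurement-noise floor,
estimated from the most stable transcripts, via surrogate decompositions
of pure-noise matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import LogMatrix
from .synthetic import generate_noise_matrix

__all__ = [
    "SurprisalDecomposition",
    "NoiseEstimate",
    "decompose",
    "estimate_noise_sigma",
    "compute_amplitude_thresholds",
    "count_significant_processes",
    "reconstruct",
    "deviation_terms",
]

THRESHOLD_FLOOR = 1e-12


@dataclass
class SurprisalDecomposition:
    """SVD-based surprisal decomposition of a log-expression matrix.

    ``G`` (genes x r) has orthonormal columns of gene weights G_ia;
    ``lam`` (samples x r) holds amplitudes lambda_a(k) scaled so that
    ``G @ lam.T`` reproduces the log matrix. Component 0 (largest
    singular value) is the steady state; its amplitudes are positive for
    every sample after sign fixing.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    G: np.ndarray
    lam: np.ndarray
    singular_values: np.ndarray
    pseudocount: float
    thresholds: np.ndarray | None = None
    n_significant: int | None = None

    @property
    def rank(self) -> int:
        return self.G.shape[1]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None


@dataclass
class NoiseEstimate:
    """Measurement-noise floor from the most stable transcripts."""

    sigma: float
    stable_gene_ids: list[str]
    fraction: float
    degenerate: bool = False  # constant matrix: sigma 0, nothing to estimate


def decompose(L: LogMatrix) -> SurprisalDecomposition:
    """Full SVD of the log matrix with a deterministic sign convention.

    Each (G, lambda) column pair is flipped so the column sum of lambda is
    positive (tie-break: largest-|weight| gene weight made positive), which
    in particular makes every steady-state amplitude lambda_0(k) positive
    for nonnegative-log data.
    """
    X = L.values
    if not np.all(np.isfinite(X)):
        raise ValueError("log matrix contains non-finite values")
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("surprisal analysis needs at least 2 samples")

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    lam = Vt.T * s  # samples x r; column norms = singular values

    colsum = lam.sum(axis=0)
    flip = np.sign(colsum)
    # tie-break on exactly balanced amplitudes: orient by the dominant weight
    for a in np.flatnonzero(flip == 0):
        flip[a] = np.sign(U[np.argmax(np.abs(U[:, a])), a]) or 1.0
    U = U * flip
    lam = lam * flip

    return SurprisalDecomposition(
        gene_ids=list(L.gene_ids),
        sample_ids=list(L.sample_ids),
        G=U,
        lam=lam,
        singular_values=s,
        pseudocount=L.pseudocount,
    )


def estimate_noise_sigma(L: LogMatrix, fraction: float = 0.01) -> NoiseEstimate:
    """Noise floor = mean per-gene SD of the most stable transcripts.

    Genes are ranked by the SD of their log expression across samples; the
    lowest ``ceil(fraction * n_genes)`` form the stable set and the mean of
    their SDs is the noise sigma.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if L.n_samples < 2:
        raise ValueError("per-gene SD undefined with a single sample")
    sds = L.values.std(axis=1, ddof=1)
    n_stable = max(int(np.ceil(fraction * L.n_genes)), 1)
    order = np.argsort(sds, kind="stable")
    stable_idx = order[:n_stable]
    sigma = float(sds[stable_idx].mean())
    return NoiseEstimate(
        sigma=sigma,
        stable_gene_ids=[L.gene_ids[i] for i in stable_idx],
        fraction=fraction,
        degenerate=bool(sigma == 0.0),
    )


def compute_amplitude_thresholds(
    d: SurprisalDecomposition,
    noise: NoiseEstimate,
    n_surrogates: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-process error limits from surrogate noise-only decompositions.

    Each surrogate is an i.i.d. Gaussian(0, sigma) matrix of the data's
    shape, decomposed like the data; the threshold for process alpha is
    mean + 2 SD of max_k |lambda_a(k)| across surrogates. Amplitudes below
    their threshold are indistinguishable from measurement noise.

    The thresholds are stored on ``d`` and returned.
    """
    if n_surrogates < 10:
        raise ValueError("need at least 10 surrogates")
    if noise.sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    r = d.rank
    if noise.sigma == 0:
        thresholds = np.full(r, THRESHOLD_FLOOR)
        d.thresholds = thresholds
        return thresholds

    n_genes, n_samples = d.G.shape[0], d.lam.shape[0]
    rng = np.random.default_rng(seed)
    maxima = np.empty((n_surrogates, r))
    for b in range(n_surrogates):
        E = generate_noise_matrix(
            n_genes, n_samples, noise.sigma, seed=int(rng.integers(2**31))
        )
        _, sv, Vt = np.linalg.svd(E, full_matrices=False)
        lam_sur = np.abs(Vt.T * sv)
        maxima[b] = lam_sur.max(axis=0)[:r]
    thresholds = maxima.mean(axis=0) + 2.0 * maxima.std(axis=0, ddof=1)
    thresholds = np.maximum(thresholds, THRESHOLD_FLOOR)
    d.thresholds = thresholds
    return thresholds


def reconstruct(d: SurprisalDecomposition, n_processes: int) -> LogMatrix:
    """Truncated reconstruction: steady state + the first n processes."""
    if not 0 <= n_processes <= d.rank - 1:
        raise ValueError(
            f"n_processes must be in [0, {d.rank - 1}], got {n_processes}"
        )
    r = 1 + n_processes
    values = d.G[:, :r] @ d.lam[:, :r].T
    return LogMatrix(
        gene_ids=list(d.gene_ids),
        sample_ids=list(d.sample_ids),
        values=values,
        pseudocount=d.pseudocount,
        provenance={"reconstruction_rank": r},
    )


def count_significant_processes(
    d: SurprisalDecomposition,
    noise: NoiseEstimate,
    within_fraction: float = 0.95,
    sigma_multiple: float = 2.0,
    L: LogMatrix | None = None,
) -> int:
    """Smallest number of processes that reproduces the data within noise.

    Returns the smallest m >= 0 such that the rank-(1+m) reconstruction
    leaves at least ``within_fraction`` of residual entries within
    ``sigma_multiple * sigma``. The steady state is not counted. When no
    truncation satisfies the tolerance (e.g. sigma = 0 on full-rank data)
    the maximum, rank - 1, is returned.

    The result is stored on ``d`` as ``n_significant``.
    """
    data = L.values if L is not None else d.G @ d.lam.T
    tol = sigma_multiple * noise.sigma
    n_entries = data.size
    # running truncation: add one component at a time
    approx = np.outer(d.G[:, 0], d.lam[:, 0])
    m = d.rank - 1
    for i in range(d.rank):
        if i > 0:
            approx = approx + np.outer(d.G[:, i], d.lam[:, i])
        resid = np.abs(data - approx)
        if np.count_nonzero(resid <= tol + 1e-12) >= within_fraction * n_entries:
            m = i
            break
    d.n_significant = m
    return m


def deviation_terms(
    d: SurprisalDecomposition,
    sample_id: str,
    significant_only: bool = False,
) -> np.ndarray:
    """Per-gene deviation from the steady state for one sample.

    Returns sum over alpha >= 1 of G_ia * lambda_a(k); with
    ``significant_only`` the sum is restricted to processes whose
    amplitude in this sample exceeds its error limit.
    """
    k = d.sample_index(sample_id)
    lam_k = d.lam[k, 1:].copy()
    if significant_only:
        if d.thresholds is None:
            raise ValueError("thresholds not computed; run compute_amplitude_thresholds")
        lam_k[np.abs(lam_k) <= d.thresholds[1:]] = 0.0
    return d.G[:, 1:] @ lam_k
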