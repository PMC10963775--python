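"""Synthetic transcriptome cohorts with planted ground truth.

The generator emulates the structure this package is built to recover from
bulk AML/normal RNA-seq: a dominant, sample-invariant steady-state
expression pattern; a small number of planted unbalanced processes active
in group-structured subsets of samples; log-additive Gaussian measurement
noise; a "stable transcript" subset that carries no process signal and
therefore sits at the measurement-noise floor; a latent 1-D state
coordinate with three clusters (normal / transition / AML); and a
designated pseudotime marker gene loaded positively on the state-coupled
process.

The planted log-matrix is ``ln X = G @ Lambda.T + E`` with exactly
orthonormal columns of G (process loadings live on disjoint gene blocks),
so parameter-recovery tests can compare recovered and planted components
directly. Construction choices that make the cohort identifiable:

* Process 1 is coupled to the latent state coordinate (amplitude 0 /
  m / 2m in normal / transition / AML), so the mean-centered amplitude
  seen by the decomposition is -m / 0 / +m: the state-space orders the
  groups with the transition cluster in the middle, as a transition
  state must be.
* Processes 2..P are active in all transition samples (mutually
  orthogonal Walsh sign patterns) and in one AML "subtype" each
  (sign-balanced halves), giving a known, deterministic set of distinct
  barcodes and making transition samples carry the largest summed
  process amplitude.
* Amplitude columns are orthogonalized exactly within their supports, and
  an amplitude ladder keeps singular values well separated, so the SVD
  recovers each planted process as one component.
* Process gene weights are two-level (up on the high-expression half of
  the block, down on the low half, balanced to stay orthogonal to the
  steady-state profile). Every process therefore moves abundant
  transcripts coherently and contributes a structurally nonzero
  free-energy change, as real unbalanced processes do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, SampleTable

__all__ = ["SyntheticSpec", "GroundTruth", "generate_dataset", "generate_noise_matrix"]

# latent state coordinate per group: well centres and within-group spread
_GROUP_CENTRES = {"normal": 0.0, "transition": 0.5, "AML": 1.0}
_GROUP_SPREAD = {"normal": 0.04, "transition": 0.06, "AML": 0.04}


@dataclass
class SyntheticSpec:
    """Parameters of a planted cohort.

    Parameters
    ----------
    n_genes, n_samples : int
        Matrix dimensions (genes x samples).
    n_processes : int
        Number of planted unbalanced processes (excluding the steady state).
    steady_state_amplitude : float
        Constant amplitude lambda_0(k) of the steady-state component, in
        log-expression units. Default 100 puts log expression in a
        realistic ~0.7-7 natural-log range for 1000 genes.
    process_amplitudes : tuple of float, optional
        Per-process amplitude scale in log-expression units (process 1:
        the transition-group value, doubled in AML; others: the
        transition-side value, with the AML-subtype side at 75%).
        Default: a ladder of 30x / 32x / 26x / ... ``noise_sd`` -- every
        planted amplitude is at least ~20 noise SDs, and the differing
        scales keep singular values separated (identifiability).
    active_fraction : float, optional
        Fraction of AML samples in each AML subtype (processes 2..P).
        Default ``None`` uses halving fractions 1/2, 1/4, ... with the
        remainder carrying process 1 only.
    noise_sd : float
        SD of the additive Gaussian noise on log expression. Default 0.25
        (~25% multiplicative noise, a realistic bulk RNA-seq scale).
    stable_fraction : float
        Fraction of genes in the stable-transcript subset (no process
        loadings). Default 0.04 so the stable set is large enough at
        desk-scale gene counts for a steady noise-floor estimate.
    stable_noise_factor : float
        Multiplier on ``noise_sd`` for stable genes. Default 1.0: stable
        transcripts carry full technical noise but no process signal, so
        their variability IS the noise floor. Set <1 to emulate
        lower-variance subsets instead.
    group_fractions : (float, float, float)
        Proportions of normal / transition / AML samples; must sum to 1.
    marker_gene_index : int
        Row index of the pseudotime marker gene; it is placed in the
        state-coupled process's gene block with a large positive loading.
    seed : int
        Seed for all randomness in the generator.
    """

    n_genes: int = 1000
    n_samples: int = 120
    n_processes: int = 3
    steady_state_amplitude: float = 100.0
    process_amplitudes: tuple[float, ...] | None = None
    active_fraction: float | None = None
    noise_sd: float = 0.25
    stable_fraction: float = 0.04
    stable_noise_factor: float = 1.0
    group_fractions: tuple[float, float, float] = (0.4, 0.2, 0.4)
    marker_gene_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_processes < 0:
            raise ValueError("n_processes must be >= 0")
        if self.n_processes >= min(self.n_genes, self.n_samples):
            raise ValueError("n_processes must be < min(n_genes, n_samples)")
        if self.steady_state_amplitude <= 0:
            raise ValueError("steady_state_amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.stable_fraction < 1:
            raise ValueError("stable_fraction must be in [0, 1)")
        if self.stable_noise_factor < 0:
            raise ValueError("stable_noise_factor must be >= 0")
        if abs(sum(self.group_fractions) - 1.0) > 1e-9:
            raise ValueError("group_fractions must sum to 1")
        if any(f < 0 for f in self.group_fractions):
            raise ValueError("group_fractions must be nonnegative")
        if not 0 <= self.marker_gene_index < self.n_genes:
            raise ValueError("marker_gene_index out of range")
        if self.process_amplitudes is not None:
            if len(self.process_amplitudes) != self.n_processes:
                raise ValueError(
                    "process_amplitudes must have one entry per process"
                )
            if any(a <= 0 for a in self.process_amplitudes):
                raise ValueError("process_amplitudes must be positive")
        if self.active_fraction is not None:
            if not 0 < self.active_fraction <= 1:
                raise ValueError("active_fraction must be in (0, 1]")

    def resolved_amplitudes(self) -> np.ndarray:
        """Per-process amplitude scales in log-expression units."""
        if self.process_amplitudes is not None:
            return np.asarray(self.process_amplitudes, dtype=float)
        s = self.noise_sd if self.noise_sd > 0 else 0.25
        amps = [30.0 * s]
        for j in range(2, self.n_processes + 1):
            amps.append(max(32.0 - 6.0 * (j - 2), 20.0) * s)
        return np.asarray(amps[: self.n_processes], dtype=float)


@dataclass
class GroundTruth:
    """Everything planted: loadings, amplitudes, groups, codes.

    ``planted_codes`` holds the ternary barcode the analysis should
    recover for each sample: the sign pattern of the process amplitudes
    relative to their cohort mean (the steady-state component absorbs the
    mean of each amplitude column, so recovered amplitudes are centered).
    """

    planted_G: np.ndarray            # genes x (1 + n_processes), orthonormal cols
    planted_lambda: np.ndarray       # samples x (1 + n_processes)
    state_coordinate: np.ndarray     # per-sample latent coordinate
    group: np.ndarray                # per-sample {normal, transition, AML}
    active_sets: list[np.ndarray]    # per-process sample indices (alpha >= 1)
    planted_codes: np.ndarray = field(default=None)  # samples x n_processes ternary

    @property
    def n_distinct_codes(self) -> int:
        return len({tuple(row) for row in self.planted_codes})


def generate_noise_matrix(
    n_genes: int, n_samples: int, sd: float, seed: int
) -> np.ndarray:
    """Seeded i.i.d. Gaussian(0, sd) matrix of the given shape."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return np.zeros((n_genes, n_samples))
    return rng.normal(0.0, sd, size=(n_genes, n_samples))


def _assign_groups(spec: SyntheticSpec) -> np.ndarray:
    target = np.asarray(spec.group_fractions) * spec.n_samples
    counts = np.floor(target).astype(int)
    while counts.sum() < spec.n_samples:
        counts[int(np.argmax(target - counts))] += 1
    return np.repeat(
        np.array(["normal", "transition", "AML"], dtype=object), counts
    )


def _gene_blocks(
    spec: SyntheticSpec, stable: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    """Disjoint gene blocks per process; process 1 gets a small block."""
    p = spec.n_processes
    nonstable = np.flatnonzero(~stable)
    nonstable = rng.permutation(nonstable)
    # move the marker gene into process 1's block
    m = spec.marker_gene_index
    pos = int(np.flatnonzero(nonstable == m)[0])
    nonstable[[0, pos]] = nonstable[[pos, 0]]
    if p == 1:
        return [np.sort(nonstable)]
    weights = np.array([0.1] + [0.6 ** (j - 2) for j in range(2, p + 1)])
    weights[1:] *= 0.9 / weights[1:].sum()
    bounds = np.round(np.cumsum(weights) * len(nonstable)).astype(int)
    blocks, start = [], 0
    for b in bounds:
        blocks.append(nonstable[start:b])
        start = b
    blocks[0] = np.concatenate([[m], np.setdiff1d(blocks[0], [m])])
    return blocks


def _planted_loadings(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exactly orthonormal G: steady-state profile + block-wise processes.

    The steady-state column is a positive, mildly varying expression
    profile. Each process column is two-level on its own gene block: up
    on the high-expression half, down on the low half, with magnitudes
    balanced so the column is exactly orthogonal to the steady-state
    profile; disjoint blocks make the process columns mutually
    orthogonal. The marker gene gets a boosted positive loading on
    process 1.
    """
    n, p = spec.n_genes, spec.n_processes
    n_stable = int(np.ceil(spec.stable_fraction * n)) if spec.stable_fraction > 0 else 0
    stable = np.zeros(n, dtype=bool)
    if n_stable:
        candidates = [i for i in range(n - 1, -1, -1) if i != spec.marker_gene_index]
        stable[candidates[:n_stable]] = True

    profile = np.clip(1.0 + 0.45 * rng.normal(size=n), 0.25, 2.5)
    G = np.zeros((n, 1 + p))
    G[:, 0] = profile / np.linalg.norm(profile)

    if p:
        blocks = _gene_blocks(spec, stable, rng)
        for j, blk in enumerate(blocks):
            order = blk[np.argsort(-profile[blk], kind="stable")]
            # top ~30% by steady-state profile are up-weighted: the
            # profile-mass balance then gives near-equal +/- magnitudes
            # (no gene sits near the noise floor) while the exponential
            # expression asymmetry makes the process's net effect on
            # abundant transcripts structurally positive
            n_up = max(int(round(0.3 * len(blk))), 1)
            high, low = order[:n_up], order[n_up:]
            mag = np.ones(n)
            if j == 0:
                if spec.marker_gene_index not in high:
                    high = np.concatenate([[spec.marker_gene_index], high[:-1]])
                    low = np.setdiff1d(order, high)
                mag[spec.marker_gene_index] = 3.0
            col = np.zeros(n)
            col[high] = mag[high]
            hi_mass = float(np.sum(mag[high] * profile[high]))
            lo_mass = float(np.sum(profile[low]))
            col[low] = -hi_mass / lo_mass
            G[:, 1 + j] = col / np.linalg.norm(col)
    return G, stable


def _walsh_signs(n: int, bit: int) -> np.ndarray:
    """Mutually orthogonal, near-balanced +/-1 patterns over n positions."""
    i = np.arange(n)
    return np.where((i >> bit) % 2 == 0, 1.0, -1.0)


def _subtype_sizes(spec: SyntheticSpec, n_aml: int) -> list[int]:
    p = spec.n_processes
    if spec.active_fraction is not None:
        sizes = [int(np.ceil(spec.active_fraction * n_aml))] * (p - 1)
    else:
        sizes = [max(int(np.floor(n_aml * 0.5**j)), 2) for j in range(1, p)]
    if sum(sizes) > n_aml:
        raise ValueError(
            f"AML subtypes need {sum(sizes)} samples but only {n_aml} AML "
            f"samples exist; increase n_samples or the AML fraction"
        )
    return sizes


def _planted_amplitudes(
    spec: SyntheticSpec,
    groups: np.ndarray,
    coord: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Amplitude matrix Lambda, per-process active sets, planted codes."""
    k, p = len(groups), spec.n_processes
    lam = np.zeros((k, 1 + p))
    lam[:, 0] = spec.steady_state_amplitude
    if p == 0:
        return lam, [], np.zeros((k, 0), dtype=int)

    s = spec.noise_sd if spec.noise_sd > 0 else 0.25
    amps = spec.resolved_amplitudes()
    trans = np.flatnonzero(groups == "transition")
    aml = np.flatnonzero(groups == "AML")
    if len(trans) == 0 or len(aml) == 0:
        raise ValueError(
            "planting processes requires both transition and AML samples; "
            "adjust group_fractions or set n_processes = 0"
        )
    active_sets: list[np.ndarray] = []

    # process 1: state-coupled, amplitude m in transition and 2m in AML
    m1 = amps[0]
    lam[trans, 1] = m1 * (1.0 + 0.4 * (coord[trans] - 0.5))
    lam[aml, 1] = 2.0 * m1 * (1.0 + 0.4 * (coord[aml] - 1.0))
    active_sets.append(np.sort(np.concatenate([trans, aml])))

    if p > 1:
        if len(trans) < 2 ** (p - 2):
            raise ValueError(
                f"need at least {2 ** (p - 2)} transition samples for "
                f"{p} processes"
            )
        sizes = _subtype_sizes(spec, len(aml))
        start = 0
        for j in range(2, p + 1):
            t_j = amps[j - 1]
            v_j = 0.75 * t_j
            sub = aml[start : start + sizes[j - 2]]
            start += sizes[j - 2]
            col = np.zeros(k)
            col[trans] = (
                t_j
                * _walsh_signs(len(trans), j - 2)
                * (1.0 + 0.02 * rng.normal(size=len(trans)))
            )
            half = len(sub) // 2
            col[sub[:half]] = v_j * (1.0 + 0.02 * rng.normal(size=half))
            col[sub[half:]] = -v_j * (1.0 + 0.02 * rng.normal(size=len(sub) - half))
            # exact orthogonalization against the constant and prior
            # amplitude columns, restricted to this process's support
            support = np.concatenate([trans, sub])
            B = np.column_stack(
                [np.ones(k)] + [lam[:, i] for i in range(1, j)]
            )[support]
            beta, *_ = np.linalg.lstsq(B, col[support], rcond=None)
            col[support] -= B @ beta
            lam[:, j] = col
            active_sets.append(np.sort(support))

    centered = lam[:, 1:] - lam[:, 1:].mean(axis=0)
    codes = (np.sign(centered) * (np.abs(centered) > 8.0 * s)).astype(int)
    return lam, active_sets, codes


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, SampleTable, GroundTruth]:
    """Generate a planted cohort: expression, metadata and ground truth.

    The log-matrix is ``G @ Lambda.T + E`` with E Gaussian(0, noise_sd)
    (stable genes scaled by ``stable_noise_factor``); expression is its
    exponential. Transition samples are labelled AML in the metadata --
    the transition state is a disease state, distinguishable only through
    the latent coordinate -- while the ground truth keeps all three
    groups. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    groups = _assign_groups(spec)
    coord = np.array(
        [rng.normal(_GROUP_CENTRES[g], _GROUP_SPREAD[g]) for g in groups]
    )
    G, stable = _planted_loadings(spec, rng)
    lam, active_sets, codes = _planted_amplitudes(spec, groups, coord, rng)

    noise = generate_noise_matrix(
        spec.n_genes, spec.n_samples, spec.noise_sd, seed=int(rng.integers(2**31))
    )
    if stable.any() and spec.stable_noise_factor != 1.0:
        noise[stable, :] *= spec.stable_noise_factor

    logx = G @ lam.T + noise
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{k:04d}" for k in range(spec.n_samples)]
    matrix = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=np.exp(logx)
    )
    meta = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": np.where(groups == "normal", "normal", "AML"),
            }
        )
    )
    truth = GroundTruth(
        planted_G=G,
        planted_lambda=lam,
        state_coordinate=coord,
        group=groups,
        active_sets=active_sets,
        planted_codes=codes,
    )
    return matrix, meta, truth
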