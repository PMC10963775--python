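"""1-D transcriptome state-space with mutual-information feature selection.

The state-space is built from mean-centered log expression of the training
cohort (normal + primary AML): with samples in rows, ``Xhat = U S Vt`` and
the principal components ``PC = U S`` give each sample a coordinate per
component; the columns of V are the "eigengenes" used to project held-out
samples. The retained component is the one that best separates the normal
and AML clusters, where separation is the gap between the maximum normal
coordinate and the minimum AML coordinate after orienting AML to the right.

Feature selection ranks genes by mutual information between their log
expression and the binary normal/AML indicator (k-nearest-neighbour
mixed continuous/discrete estimator) and drops the least informative genes
until the clusters separate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .dataio import LogMatrix, SampleTable

__all__ = [
    "MIRanking",
    "StateSpace",
    "FeatureSelection",
    "mutual_information_mixed",
    "rank_genes_by_mi",
    "cluster_separation",
    "build_state_space",
    "project_samples",
    "select_features",
]


def _binary_labels(groups: np.ndarray) -> np.ndarray:
    y = np.asarray([1 if g == "AML" else 0 for g in groups])
    if len(np.unique(y)) < 2:
        raise ValueError("need both normal and AML samples")
    return y


def mutual_information_mixed(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 3,
    seed: int = 0,
    return_raw: bool = False,
) -> float | tuple[float, float]:
    """kNN mutual information between a continuous x and binary y, in nats.

    Implements the mixed continuous/discrete estimator: for each point,
    the distance to its k-th nearest neighbour within its own class sets a
    radius, and the count m_i of points of any class inside that radius
    enters ``MI = psi(N) - <psi(N_y)> + psi(k) - <psi(m_i)>``. Distance
    ties are broken with a tiny seeded jitter. Negative estimates (possible
    at finite n) are clipped to zero; the raw value is available via
    ``return_raw``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y).ravel()
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have the same length")
    if n < 10:
        raise ValueError("need at least 10 samples")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("y must contain both classes")
    if set(classes.tolist()) - {0, 1}:
        raise ValueError("y must take values {0, 1}")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if k >= min(counts.values()):
        raise ValueError(f"k={k} must be smaller than the smallest class size")

    if np.ptp(x) == 0:  # constant signal carries no information
        return (0.0, 0.0) if return_raw else 0.0

    rng = np.random.default_rng(seed)
    scale = np.std(x) or 1.0
    xj = x + rng.normal(0.0, 1e-10 * scale, size=n)

    radius = np.empty(n)
    n_class = np.empty(n)
    for c in classes:
        mask = y == c
        pts = xj[mask, None]
        tree = cKDTree(pts)
        dist, _ = tree.query(pts, k=k + 1)
        radius[mask] = dist[:, k]
        n_class[mask] = counts[c]

    full_tree = cKDTree(xj[:, None])
    m = np.array(
        full_tree.query_ball_point(xj[:, None], r=radius, return_length=True),
        dtype=float,
    ) - 1.0  # exclude the point itself
    m = np.maximum(m, k)

    raw = float(digamma(n) - np.mean(digamma(n_class)) + digamma(k) - np.mean(digamma(m)))
    mi = max(raw, 0.0)
    return (mi, raw) if return_raw else mi


@dataclass
class MIRanking:
    """Genes ranked by MI against the disease indicator (descending)."""

    gene_ids: list[str]
    mi_nats: np.ndarray
    raw_mi_nats: np.ndarray
    k_neighbors: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "mi_nats": self.mi_nats, "raw_mi_nats": self.raw_mi_nats}
        )


def rank_genes_by_mi(L: LogMatrix, labels: SampleTable, k: int = 3, seed: int = 0) -> MIRanking:
    """Per-gene MI with the normal/AML indicator, sorted descending.

    Ties are broken by gene id so the ranking is deterministic.
    """
    y = _binary_labels(labels.groups_for(L.sample_ids))
    mis = np.empty(L.n_genes)
    raws = np.empty(L.n_genes)
    for i in range(L.n_genes):
        mis[i], raws[i] = mutual_information_mixed(
            L.values[i], y, k=k, seed=seed, return_raw=True
        )
    order = sorted(range(L.n_genes), key=lambda i: (-mis[i], L.gene_ids[i]))
    return MIRanking(
        gene_ids=[L.gene_ids[i] for i in order],
        mi_nats=mis[order],
        raw_mi_nats=raws[order],
        k_neighbors=k,
    )


def cluster_separation(coords: np.ndarray, groups: np.ndarray) -> float:
    """Gap between clusters: min(AML) - max(normal) after orientation.

    Positive iff the groups are perfectly separated; invariant under a
    global sign flip of the coordinates (the orientation rule always puts
    the AML mean on the right before measuring).
    """
    coords = np.asarray(coords, dtype=float)
    groups = np.asarray(groups, dtype=object)
    aml = coords[groups == "AML"]
    norm = coords[groups == "normal"]
    if len(aml) == 0 or len(norm) == 0:
        raise ValueError("both normal and AML samples are required")
    if aml.mean() < norm.mean():
        coords = -coords
        aml, norm = -aml, -norm
    return float(aml.min() - norm.max())


@dataclass
class StateSpace:
    """Fitted eigengene state-space mapping samples to a scalar coordinate."""

    gene_ids: list[str]
    sample_ids: list[str]
    eigengenes: np.ndarray       # genes x r, orthonormal columns (V)
    mean_vector: np.ndarray      # per-gene training mean
    pcs: np.ndarray              # samples x r, PC = U S
    chosen_component: int
    orientation: float           # +/-1: AML coordinates exceed normal
    separation: float

    @property
    def coordinates(self) -> pd.Series:
        """Training-sample coordinates on the chosen, oriented component."""
        return pd.Series(
            self.orientation * self.pcs[:, self.chosen_component],
            index=self.sample_ids,
            name="coordinate",
        )


def build_state_space(
    L: LogMatrix,
    labels: SampleTable,
    gene_subset: list[str] | None = None,
) -> StateSpace:
    """Mean-center, SVD, and pick the best-separating component.

    Training samples are all samples of ``L`` (callers restrict to
    normal + primary AML). The chosen component maximizes
    :func:`cluster_separation`; ties go to the lower component index.
    """
    if L.n_samples < 3:
        raise ValueError("need at least 3 samples to build a state-space")
    groups = labels.groups_for(L.sample_ids)
    _binary_labels(groups)  # both groups must be present

    if gene_subset is not None:
        index = {g: i for i, g in enumerate(L.gene_ids)}
        missing = [g for g in gene_subset if g not in index]
        if missing:
            raise KeyError(f"genes missing from matrix: {missing[:10]}")
        rows = [index[g] for g in gene_subset]
        values = L.values[rows]
        gene_ids = list(gene_subset)
    else:
        values = L.values
        gene_ids = list(L.gene_ids)

    mean_vector = values.mean(axis=1)
    A = (values - mean_vector[:, None]).T  # samples x genes
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    pcs = U * s
    eigengenes = Vt.T

    best, best_sep = 0, -np.inf
    for j in range(pcs.shape[1]):
        sep = cluster_separation(pcs[:, j], groups)
        if sep > best_sep + 1e-12:
            best, best_sep = j, sep
    aml_mean = pcs[groups == "AML", best].mean()
    norm_mean = pcs[groups == "normal", best].mean()
    orientation = 1.0 if aml_mean >= norm_mean else -1.0

    return StateSpace(
        gene_ids=gene_ids,
        sample_ids=list(L.sample_ids),
        eigengenes=eigengenes,
        mean_vector=mean_vector,
        pcs=pcs,
        chosen_component=best,
        orientation=orientation,
        separation=best_sep,
    )


def project_samples(s: StateSpace, L_new: LogMatrix) -> pd.Series:
    """Project samples into the state-space via the stored eigengenes.

    Subtracts the stored training mean, multiplies by the chosen eigengene
    and applies the stored orientation. All state-space genes must be
    present in the new matrix.
    """
    index = {g: i for i, g in enumerate(L_new.gene_ids)}
    missing = [g for g in s.gene_ids if g not in index]
    if missing:
        raise KeyError(f"genes missing from matrix: {missing[:10]}")
    rows = [index[g] for g in s.gene_ids]
    centered = L_new.values[rows] - s.mean_vector[:, None]
    coord = s.orientation * (centered.T @ s.eigengenes[:, s.chosen_component])
    return pd.Series(coord, index=L_new.sample_ids, name="coordinate")


@dataclass
class FeatureSelection:
    """Outcome of the MI-guided gene-removal loop."""

    selected_gene_ids: list[str]
    separated: bool
    trace: list[tuple[int, float]] = field(default_factory=list)
    ranking: MIRanking | None = None


def select_features(
    L: LogMatrix,
    labels: SampleTable,
    k: int = 3,
    batch_step: int = 1,
    floor: int = 10,
    seed: int = 0,
) -> FeatureSelection:
    """Drop the least-informative genes until the clusters separate.

    Genes are ranked once by MI; while the chosen component's separation
    is <= 0, the lowest-MI remaining genes are removed (``batch_step`` at a
    time) and the state-space rebuilt. Stops at positive separation or at
    the ``floor`` gene count, in which case the retained set is returned
    flagged unseparated. Batched removal reaches the same kind of fixed
    point as single-gene removal but with far fewer SVDs.
    """
    if L.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if batch_step < 1:
        raise ValueError("batch_step must be >= 1")
    groups = labels.groups_for(L.sample_ids)
    ranking = rank_genes_by_mi(L, labels, k=k, seed=seed)
    retained = list(ranking.gene_ids)  # descending MI

    trace: list[tuple[int, float]] = []
    while True:
        space = build_state_space(L, labels, gene_subset=retained)
        sep = cluster_separation(space.coordinates.to_numpy(), groups)
        trace.append((len(retained), sep))
        if sep > 0:
            return FeatureSelection(retained, True, trace, ranking)
        if len(retained) - batch_step < floor:
            warnings.warn(
                "separation not achieved before reaching the floor gene "
                "count; returning the retained set unseparated"
            )
            return FeatureSelection(retained, False, trace, ranking)
        retained = retained[: len(retained) - batch_step]
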