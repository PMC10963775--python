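"""Free-energy change, PaSSS barcodes, and critical-point statistics.

The free-energy change of sample k relative to the steady state, in units
of RT, is

    FEC/RT = sum_i X_i(k) * sum_alpha G_ia * lambda_a(k)

where X_i(k) is the linear-scale expression and the inner sum runs over
the significant unbalanced processes of that sample: processes whose
amplitude exceeds its noise-derived error limit. The set of such
processes is the sample's patient-specific signaling signature (PaSSS),
recorded as a ternary barcode: +1 / -1 for an amplitude beyond the
positive / negative error limit, 0 otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix
from .surprisal import SurprisalDecomposition

__all__ = [
    "FECRecord",
    "BarcodeTable",
    "compute_fec",
    "compute_fec_table",
    "make_barcodes",
    "catalog_passs",
    "fec_by_critical_point",
    "AnovaResult",
]


@dataclass
class FECRecord:
    sample_id: str
    fec_signed: float
    fec_abs: float
    n_active_processes: int


def _check_axes(m: ExpressionMatrix, d: SurprisalDecomposition) -> None:
    if m.gene_ids != d.gene_ids or m.sample_ids != d.sample_ids:
        raise ValueError("matrix and decomposition axes do not match")


def _active_lambda(d: SurprisalDecomposition, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Amplitudes of sample k gated by the error limits, for alpha 1..n_sig."""
    if d.thresholds is None:
        raise ValueError("thresholds not computed; run compute_amplitude_thresholds")
    n_proc = d.n_significant if d.n_significant is not None else d.rank - 1
    lam = d.lam[k, 1 : 1 + n_proc].copy()
    thr = d.thresholds[1 : 1 + n_proc]
    active = np.abs(lam) > thr
    lam[~active] = 0.0
    return lam, active


def compute_fec(
    m: ExpressionMatrix, d: SurprisalDecomposition, sample_id: str
) -> FECRecord:
    """FEC/RT of one sample over its significant processes.

    Returns both the signed value and its absolute value; zero when no
    process passes its error limit. The gene sum runs over the full
    transcript set -- thresholds gate processes, not genes.
    """
    _check_axes(m, d)
    k = d.sample_index(sample_id)
    lam, active = _active_lambda(d, k)
    if not active.any():
        return FECRecord(sample_id, 0.0, 0.0, 0)
    deviation = d.G[:, 1 : 1 + len(lam)] @ lam
    fec = float(m.values[:, k] @ deviation)
    return FECRecord(sample_id, fec, abs(fec), int(active.sum()))


def compute_fec_table(m: ExpressionMatrix, d: SurprisalDecomposition) -> pd.DataFrame:
    """Per-sample FEC table: fec_signed, fec_abs, n_active_processes."""
    records = [compute_fec(m, d, s) for s in m.sample_ids]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "fec_signed": [r.fec_signed for r in records],
            "fec_abs": [r.fec_abs for r in records],
            "n_active_processes": [r.n_active_processes for r in records],
        }
    )


@dataclass
class BarcodeTable:
    """Ternary PaSSS barcodes over processes alpha = 1..n."""

    sample_ids: list[str]
    codes: np.ndarray  # samples x n_processes, entries in {-1, 0, 1}

    def passs(self, sample_id: str) -> set[int]:
        """Active process indices (1-based alpha) of one sample."""
        k = self.sample_ids.index(sample_id)
        return {a + 1 for a in np.flatnonzero(self.codes[k])}

    def code_strings(self) -> list[str]:
        return [",".join(str(int(c)) for c in row) for row in self.codes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "barcode": self.code_strings(),
                "n_active": np.count_nonzero(self.codes, axis=1),
            }
        )


def make_barcodes(d: SurprisalDecomposition) -> BarcodeTable:
    """Discretize amplitudes into ternary barcodes against the error limits.

    For each significant process alpha: +1 if lambda_a(k) > limit, -1 if
    lambda_a(k) < -limit, else 0 (an amplitude exactly at the limit is 0).
    """
    if d.thresholds is None:
        raise ValueError("thresholds not computed; run compute_amplitude_thresholds")
    n_proc = d.n_significant if d.n_significant is not None else d.rank - 1
    lam = d.lam[:, 1 : 1 + n_proc]
    thr = d.thresholds[1 : 1 + n_proc]
    codes = np.where(lam > thr, 1, np.where(lam < -thr, -1, 0))
    return BarcodeTable(sample_ids=list(d.sample_ids), codes=codes.astype(int))


def catalog_passs(b: BarcodeTable) -> pd.DataFrame:
    """Distinct barcodes with sample counts, most frequent first.

    Counts sum to the number of samples; ties in count are ordered
    lexicographically by code string.
    """
    if len(b.sample_ids) == 0:
        raise ValueError("empty barcode table")
    counts = pd.Series(b.code_strings()).value_counts()
    df = pd.DataFrame({"barcode": counts.index, "count": counts.to_numpy()})
    return (
        df.sort_values(["count", "barcode"], ascending=[False, True])
        .reset_index(drop=True)
    )


@dataclass
class AnovaResult:
    """Per-critical-point |FEC| summary with one-way ANOVA and post-hocs."""

    group_stats: pd.DataFrame  # assigned, n, mean, sd of |FEC|
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame     # group_a, group_b, t, p_raw, p_holm


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    n = len(pvals)
    adj = np.empty(n)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (n - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj


def fec_by_critical_point(
    fec_table: pd.DataFrame, assignments: pd.DataFrame
) -> AnovaResult:
    """Compare |FEC| across critical-point groups (one-way ANOVA).

    Groups with fewer than 2 samples are excluded with a warning; at least
    two groups must remain. Pairwise Welch t-tests are reported with raw
    and Holm-adjusted p-values.
    """
    merged = fec_table.merge(
        assignments[["sample_id", "assigned"]], on="sample_id", how="inner"
    )
    if merged.empty:
        raise ValueError("no overlapping samples between FEC table and assignments")
    groups: dict[str, np.ndarray] = {}
    for name, sub in merged.groupby("assigned"):
        vals = sub["fec_abs"].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"critical point {name} has <2 samples; excluded")
            continue
        groups[str(name)] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 critical-point groups with >=2 samples")

    names = sorted(groups)
    stats_df = pd.DataFrame(
        {
            "assigned": names,
            "n": [len(groups[g]) for g in names],
            "mean_abs_fec": [float(np.mean(groups[g])) for g in names],
            "sd_abs_fec": [float(np.std(groups[g], ddof=1)) for g in names],
        }
    )
    arrays = [groups[g] for g in names]
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        f_stat, p_val = 0.0, 1.0  # identical constants: no variance anywhere
    else:
        f_stat, p_val = stats.f_oneway(*arrays)

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, p = stats.ttest_ind(arrays[i], arrays[j], equal_var=False)
            rows.append({"group_a": names[i], "group_b": names[j], "t": t, "p_raw": p})
    pairwise = pd.DataFrame(rows)
    if not pairwise.empty:
        pairwise["p_holm"] = _holm(pairwise["p_raw"].to_numpy(dtype=float))
    return AnovaResult(
        group_stats=stats_df,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pairwise,
    )
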