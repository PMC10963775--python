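"""Input/output and elementary transforms for expression matrices.

The package-wide axis convention is genes in rows, samples in columns.
Expression values are normalized, nonnegative and unit-agnostic (TPM- or
FPKM-like); all downstream modelling operates on natural-log expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "LogMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "collapse_duplicate_samples",
    "log_transform",
    "inverse_log_transform",
]

VALID_GROUPS = ("normal", "AML")


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x samples matrix with identifier axes.

    ``values`` holds normalized expression X_i(k) for gene i (row) in
    sample k (column).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if np.any(self.values < 0):
            i, k = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value {self.values[i, k]} at "
                f"gene {self.gene_ids[i]!r}, sample {self.sample_ids[k]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )


@dataclass
class SampleTable:
    """Per-sample metadata: group label plus optional patient/tissue."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        ids = self.table["sample_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        bad = set(self.table["group"].dropna()) - set(VALID_GROUPS)
        if bad:
            raise ValueError(
                f"unknown group labels {sorted(bad)}; expected {VALID_GROUPS}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table["sample_id"]]

    def group_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return str(row["group"].iloc[0])

    def groups_for(self, sample_ids: list[str]) -> np.ndarray:
        lut = dict(zip(self.table["sample_id"].astype(str), self.table["group"]))
        missing = [s for s in sample_ids if s not in lut]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
        return np.array([lut[s] for s in sample_ids], dtype=object)


@dataclass
class LogMatrix:
    """Natural-log expression ln(X + pseudocount) on the same axes."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    pseudocount: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("log matrix shape does not match id axes")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def read_expression_matrix(path: str, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples table (first column gene ids, header sample ids)."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"empty expression matrix in {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = df.index[coerced.isna().argmax()]
            raise ValueError(
                f"non-numeric cell at gene {row!r}, sample {col!r} in {path}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise ValueError(f"missing values in expression matrix {path}")
    return ExpressionMatrix.from_frame(df)


def write_expression_matrix(
    m: ExpressionMatrix, path: str, delimiter: str | None = None
) -> None:
    sep = _delimiter_for(path, delimiter)
    m.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_sample_table(path: str, delimiter: str | None = None) -> SampleTable:
    sep = _delimiter_for(path, delimiter)
    return SampleTable(pd.read_csv(path, sep=sep, dtype={"sample_id": str}))


def collapse_duplicate_samples(
    m: ExpressionMatrix, meta: SampleTable
) -> tuple[ExpressionMatrix, SampleTable]:
    """Average columns that belong to the same patient.

    Samples sharing a ``patient_id`` are replaced by a single column equal to
    their arithmetic mean, keyed by the patient id; samples without a patient
    id (or with a unique one) pass through unchanged. Column order follows
    first occurrence. A patient whose samples carry conflicting group labels
    is rejected.
    """
    tab = meta.table
    if "patient_id" not in tab.columns:
        return m, meta
    lut = {
        str(r["sample_id"]): r for _, r in tab.iterrows()
    }
    missing = [s for s in m.sample_ids if s not in lut]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")

    order: list[str] = []          # output keys, first-occurrence order
    members: dict[str, list[int]] = {}
    key_meta: dict[str, dict] = {}
    for k, sid in enumerate(m.sample_ids):
        row = lut[sid]
        pid = row.get("patient_id")
        key = str(pid) if pid is not None and not pd.isna(pid) else sid
        if key not in members:
            order.append(key)
            members[key] = []
            key_meta[key] = {
                "sample_id": key,
                "group": row["group"],
                "patient_id": pid,
                "tissue": row.get("tissue"),
            }
        else:
            if key_meta[key]["group"] != row["group"]:
                raise ValueError(
                    f"patient {key!r} has samples with conflicting group "
                    f"labels ({key_meta[key]['group']!r} vs {row['group']!r})"
                )
        members[key].append(k)

    values = np.column_stack(
        [m.values[:, members[key]].mean(axis=1) for key in order]
    )
    out_meta = SampleTable(pd.DataFrame([key_meta[k] for k in order]))
    return (
        ExpressionMatrix(gene_ids=list(m.gene_ids), sample_ids=order, values=values),
        out_meta,
    )


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> LogMatrix:
    """Elementwise ln(X + pseudocount); the pseudocount is recorded."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    return LogMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        values=np.log(m.values + pseudocount),
        pseudocount=float(pseudocount),
        provenance={"pseudocount": float(pseudocount)},
    )


def inverse_log_transform(L: LogMatrix) -> ExpressionMatrix:
    """Invert :func:`log_transform`: exp(values) - pseudocount."""
    back = np.exp(L.values) - L.pseudocount
    back[np.abs(back) < 1e-12] = 0.0
    return ExpressionMatrix(
        gene_ids=list(L.gene_ids), sample_ids=list(L.sample_ids), values=back
    )
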