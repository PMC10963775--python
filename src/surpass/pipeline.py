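"""End-to-end analysis: decompose -> state-space -> potential -> FEC/barcodes.

Glues the modules together the way a cohort analysis runs: surprisal
decomposition of log expression with noise-derived significance, a 1-D
state-space from the labelled samples, a fitted double-well potential with
critical-point assignment, and per-sample FEC and PaSSS barcodes. Results
can be written as a directory of TSV tables plus a run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import fec as fec_mod
from . import state_space as ss
from . import state_transition as st
from . import surprisal as sa
from .dataio import ExpressionMatrix, LogMatrix, SampleTable, log_transform

__all__ = ["PipelineResult", "run_pipeline", "write_results"]


@dataclass
class PipelineResult:
    log_matrix: LogMatrix
    decomposition: sa.SurprisalDecomposition
    noise: sa.NoiseEstimate
    n_significant: int
    state_space: ss.StateSpace
    coordinates: pd.Series
    potential: st.PotentialModel
    potential_info: dict
    assignments: pd.DataFrame
    fec_table: pd.DataFrame
    barcodes: fec_mod.BarcodeTable
    passs_catalog: pd.DataFrame
    anova: fec_mod.AnovaResult | None
    config: dict


def run_pipeline(
    matrix: ExpressionMatrix,
    meta: SampleTable,
    pseudocount: float = 1.0,
    noise_fraction: float = 0.01,
    n_surrogates: int = 100,
    feature_selection: bool = False,
    mi_k: int = 3,
    batch_step: int = 1,
    scale: float | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full cohort analysis with one seed for all randomness."""
    L = log_transform(matrix, pseudocount=pseudocount)

    decomp = sa.decompose(L)
    noise = sa.estimate_noise_sigma(L, fraction=noise_fraction)
    sa.compute_amplitude_thresholds(decomp, noise, n_surrogates=n_surrogates, seed=seed)
    n_sig = sa.count_significant_processes(decomp, noise, L=L)

    if feature_selection:
        selection = ss.select_features(
            L, meta, k=mi_k, batch_step=batch_step, seed=seed
        )
        space = ss.build_state_space(L, meta, gene_subset=selection.selected_gene_ids)
    else:
        space = ss.build_state_space(L, meta)
    coords = space.coordinates

    groups = meta.groups_for(list(coords.index))
    model, info = st.fit_potential(coords.to_numpy(), groups, scale=scale, seed=seed)
    assignments = st.assign_critical_points(coords, model)

    fec_table = fec_mod.compute_fec_table(matrix, decomp)
    barcodes = fec_mod.make_barcodes(decomp)
    catalog = fec_mod.catalog_passs(barcodes)
    try:
        anova = fec_mod.fec_by_critical_point(fec_table, assignments)
    except ValueError:
        anova = None

    config = {
        "pseudocount": pseudocount,
        "noise_fraction": noise_fraction,
        "n_surrogates": n_surrogates,
        "feature_selection": feature_selection,
        "mi_k": mi_k,
        "batch_step": batch_step,
        "scale": model.scale,
        "seed": seed,
    }
    return PipelineResult(
        log_matrix=L,
        decomposition=decomp,
        noise=noise,
        n_significant=n_sig,
        state_space=space,
        coordinates=coords,
        potential=model,
        potential_info=info,
        assignments=assignments,
        fec_table=fec_table,
        barcodes=barcodes,
        passs_catalog=catalog,
        anova=anova,
        config=config,
    )


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    """Write TSV tables and a JSON run manifest to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = result.decomposition
    pd.DataFrame(
        d.lam, index=d.sample_ids, columns=[f"lambda_{a}" for a in range(d.rank)]
    ).to_csv(out / "lambda.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(
        d.G, index=d.gene_ids, columns=[f"G_{a}" for a in range(d.rank)]
    ).to_csv(out / "gene_weights.tsv", sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"alpha": range(d.rank), "threshold": d.thresholds}
    ).to_csv(out / "thresholds.tsv", sep="\t", index=False)
    result.coordinates.to_frame().to_csv(
        out / "state_space.tsv", sep="\t", index_label="sample_id"
    )
    result.assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
    result.fec_table.to_csv(out / "fec.tsv", sep="\t", index=False)
    result.barcodes.to_frame().to_csv(out / "barcodes.tsv", sep="\t", index=False)
    result.passs_catalog.to_csv(out / "passs_catalog.tsv", sep="\t", index=False)
    m = result.potential
    pd.DataFrame(
        [
            {
                "c1": m.c1,
                "c2": m.c2,
                "c3": m.c3,
                "scale": m.scale,
                "beta_inv": m.beta_inv,
                "c2_residual": result.potential_info["c2_residual"],
            }
        ]
    ).to_csv(out / "critical_points.tsv", sep="\t", index=False)
    manifest = {
        "config": result.config,
        "noise_sigma": result.noise.sigma,
        "n_significant_processes": result.n_significant,
        "chosen_component": result.state_space.chosen_component,
        "separation": result.state_space.separation,
        "potential_info": result.potential_info,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
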