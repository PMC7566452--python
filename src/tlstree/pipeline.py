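"""End-to-end synthetic study: generate a cohort, measure, model, compare.

This module wires the stages together the way a field campaign would use
them: a three-plot cohort of synthetic redwood-like stems plus one outlying
giant is generated, every tree is measured (H, DBH, fDBH, DTB), a subset of
plots gets full cylinder-model volume ensembles, volumes are converted to
AGB via wood density, the allometric model bank is evaluated on the measured
stem dimensions, and the standard comparison tables (model-vs-TLS
regressions, per-plot AGBD) are produced together with new power-law fits to
the TLS-derived volumes.

It backs both the test suite and ``scripts/acceptance.py``; everything is
deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import PowerLawFit, fit_power_law, load_models, predict_agb, tls_agb
from .io import PipelineConfig
from .plots import table1_report, table2_report
from .qsm import qsm_ensemble
from .stem import measure_tree
from .synthetic import cohort_specs, generate_tree

log = logging.getLogger("tlstree")

__all__ = ["StudyResult", "run_cohort_study"]


@dataclass
class StudyResult:
    """Everything a synthetic campaign produces, one object per run."""

    metrics: pd.DataFrame  # per-tree stem metrics + ground truth
    agb: pd.DataFrame  # per-tree AGB by method (QSM'd subset)
    table1: pd.DataFrame  # model-vs-TLS regression summary
    table2: pd.DataFrame  # per-plot AGBD summary
    fdbh_rel_mean_percent: float  # cohort mean of 100*(DBH-fDBH)/fDBH
    fdbh_rel_sd_percent: float
    refit: PowerLawFit  # DTB,H power law refit to TLS volumes
    refit_rmse_percent: float
    original_rmse_percent: float  # same form, shipped stand-in coefficients
    h_only_rmse_percent: float


def run_cohort_study(
    seed: int = 0,
    qsm_plots: tuple[str, ...] = ("CAL-01", "CA"),
    qsm_patch_sizes: tuple[float, ...] = (0.4, 0.6),
    qsm_runs_per_size: int = 1,
    mc_n: int = 500,
    cfg: PipelineConfig | None = None,
    target_points: int = 12000,
) -> StudyResult:
    """Run the full synthetic study; see the module docstring.

    QSM ensembles are restricted to ``qsm_plots`` to keep the run tractable;
    stem metrics and the fDBH statistic cover the whole cohort.
    """
    cfg = cfg or PipelineConfig(seed=seed)
    cohort = cohort_specs(seed=seed, target_points=target_points)
    models = load_models()
    model_by_id = {m.model_id: m for m in models}

    rows = []
    ens_by_tree: dict[str, tuple[float, float]] = {}
    for _, rec in cohort.iterrows():
        cloud, gt = generate_tree(rec["spec"])
        cloud.tree_id = rec["tree_id"]
        m = measure_tree(cloud, cfg)
        row = m.as_dict()
        row.update(
            plot_id=rec["plot_id"],
            dbh_true_m=gt.dbh_true_m,
            total_volume_true_m3=gt.total_volume_m3,
        )
        if rec["plot_id"] in qsm_plots:
            ens = qsm_ensemble(cloud, qsm_patch_sizes, qsm_runs_per_size,
                               seed=cfg.seed)
            ens_by_tree[rec["tree_id"]] = (ens.volume_mean_m3, ens.volume_sd_m3)
            row.update(qsm_volume_m3=ens.volume_mean_m3, qsm_volume_sd_m3=ens.volume_sd_m3)
        rows.append(row)
    metrics = pd.DataFrame(rows)

    ok = metrics.dropna(subset=["DBH_m", "fDBH_m"])
    rel = 100.0 * (ok["DBH_m"] - ok["fDBH_m"]) / ok["fDBH_m"]
    log.info("fDBH statistic over %d trees: mean %.2f%%, sd %.2f%%",
             len(rel), rel.mean(), rel.std(ddof=1))

    # per-tree AGB by every method, for the QSM'd subset
    from .stem import StemMetrics

    agb_rows = []
    for _, r in metrics[metrics["tree_id"].isin(ens_by_tree)].iterrows():
        sm = StemMetrics(
            tree_id=r["tree_id"], height_m=r["H_m"],
            dbh_m=r["DBH_m"], dbh_rmse_m=r["DBH_rmse_m"],
            fdbh_m=r["fDBH_m"], fdbh_rmse_m=r["fDBH_rmse_m"],
            dtb_m=r["DTB_m"], dtb_rmse_m=r["DTB_rmse_m"],
        )
        est = tls_agb(ens_by_tree[r["tree_id"]], cfg.wood_density_kg_m3,
                      tree_id=r["tree_id"])
        entry = dict(tree_id=r["tree_id"], plot_id=r["plot_id"],
                     tls=est.agb_t, tls_sd=est.agb_sd_t)
        for model in models:
            try:
                e = predict_agb(model, sm, mc_n=mc_n, seed=cfg.seed)
            except Exception as exc:
                log.warning("%s/%s: %s", r["tree_id"], model.model_id, exc)
                continue
            entry[model.model_id] = e.agb_t
            entry[model.model_id + "_sd"] = e.agb_sd_t
        agb_rows.append(entry)
    agb = pd.DataFrame(agb_rows).dropna()

    model_cols = [m.model_id for m in models if m.model_id in agb.columns]
    table1 = table1_report(agb[["tls"] + model_cols], reference_col="tls")
    table2 = table2_report(
        agb[agb["plot_id"] != "CA"],
        area_ha=0.25,
        method_cols=tuple(["tls"] + model_cols),
    )

    # new allometries against TLS-derived volume
    vol = metrics.dropna(subset=["DTB_m"]).loc[lambda d: d["tree_id"].isin(ens_by_tree)]
    records = pd.DataFrame({
        "DTB": vol["DTB_m"].to_numpy(),
        "H": vol["H_m"].to_numpy(),
        "V": vol["qsm_volume_m3"].to_numpy(),
    })
    refit = fit_power_law(records, "V", ("DTB", "H"), weighting="none")
    sillett2019 = model_by_id["sillett2019"]
    pred_orig = (
        sillett2019.coefficients["a"]
        * records["DTB"] ** sillett2019.coefficients["b_DTB"]
        * records["H"] ** sillett2019.coefficients["b_H"]
    )
    original_rmse = 100.0 * float(np.sqrt(np.mean((pred_orig - records["V"]) ** 2))) \
        / float(records["V"].mean())
    h_only = fit_power_law(records, "V", ("H",), weighting="none")

    return StudyResult(
        metrics=metrics,
        agb=agb,
        table1=table1,
        table2=table2,
        fdbh_rel_mean_percent=float(rel.mean()),
        fdbh_rel_sd_percent=float(rel.std(ddof=1)),
        refit=refit,
        refit_rmse_percent=refit.rmse_percent,
        original_rmse_percent=original_rmse,
        h_only_rmse_percent=h_only.rmse_percent,
    )
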