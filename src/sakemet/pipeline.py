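"""End-to-end orchestration: preprocess, QC, model per attribute, report.

`run_analysis` is the in-memory pipeline; `run_full` wraps it with file IO
driven by a :class:`RunConfig`; `simulate_and_run` couples the pipeline to
the synthetic generator and scores the result against the planted ground
truth (the acceptance dashboard).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import peaks as pk
from . import sensory as sn
from .containers import AnnotationLibrary, PeakTable, SensoryPanel
from .modeling import AttributeModelResult, build_attribute_model
from .synthetic import GeneratorConfig, SyntheticDataset, generate_dataset, split_years
from .transfer import (
    TransferResult,
    align_variables,
    common_important,
    predict_external,
    refit_reduced,
)

logger = logging.getLogger("sakemet")

__all__ = [
    "AnalysisParams",
    "RunConfig",
    "RunReport",
    "run_analysis",
    "run_full",
    "run_transfer",
    "simulate_and_run",
]


@dataclass
class AnalysisParams:
    """Statistical settings of the pipeline (defaults follow the method:
    10% replicate-CV filter, 0.1 min / 0.007 Da annotation tolerances,
    7-fold replicate-grouped CV, 100 permutations, VIPpred threshold 1.5,
    ANOVA gate at alpha = 0.05)."""

    cv_threshold: float = 10.0
    rt_tol: float = 0.1
    mz_tol: float = 0.007
    alpha: float = 0.05
    k_folds: int = 7
    seed: int = 17
    max_n_ortho: int = 8
    n_perm: int = 100
    vip_threshold: float = 1.5
    run_permutation: bool = True
    scale_in_fold: bool = True


@dataclass
class RunConfig:
    """File-based run description for the CLI."""

    peaks_path: str
    panel_path: str
    out_dir: str
    library_path: str | None = None
    scales_path: str | None = None
    extras_path: str | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    attributes: list | None = None  # default: all panel attributes


@dataclass
class RunReport:
    """Per-attribute model table plus filter and QC audit trail."""

    filter_summary: dict
    anova_table: pd.DataFrame
    attribute_table: pd.DataFrame
    results: dict
    removed_outliers: pd.DataFrame
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "filter_summary": {
                k: v for k, v in self.filter_summary.items() if isinstance(v, (int, float))
            },
            "anova": self.anova_table.to_dict(orient="records"),
            "models": self.attribute_table.to_dict(orient="records"),
            "n_removed_outliers": int(len(self.removed_outliers)),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def run_analysis(
    table: PeakTable,
    panel: SensoryPanel,
    library: AnnotationLibrary | None = None,
    extras: pd.DataFrame | None = None,
    params: AnalysisParams | None = None,
    attributes: list | None = None,
) -> RunReport:
    """Execute preprocessing, sensory QC, the ANOVA gate and one OPLS model
    per passing attribute.

    Attributes failing the gate appear in the report with no model, the way
    a non-discriminating attribute is dropped from a panel analysis.
    """
    params = params or AnalysisParams()

    processed, filt = pk.preprocess(
        table,
        library=library,
        cv_threshold=params.cv_threshold,
        rt_tol=params.rt_tol,
        mz_tol=params.mz_tol,
        extras=extras,
    )
    logger.info(
        "peak filters: %d -> %d -> %d peaks",
        filt["n_input_peaks"],
        filt["n_after_zero_max"],
        filt["n_after_cv_filter"],
    )
    annotations = None
    if "annotations" in filt:
        annotations = filt.pop("annotations").annotations

    clean, removed = sn.remove_outliers(panel)
    logger.info("sensory QC removed %d of %d records", len(removed), len(panel.records))
    anova = sn.anova_all(clean, alpha=params.alpha)
    anova_table = pd.DataFrame(
        [
            {
                "attribute": a.attribute,
                "f_value": a.f_value,
                "p_value": a.p_value,
                "pass": a.pass_flag,
            }
            for a in anova
        ]
    )
    means = sn.sample_means(clean)

    wanted = attributes if attributes is not None else clean.attributes
    passing = {a.attribute for a in anova if a.pass_flag}
    results: dict[str, AttributeModelResult] = {}
    rows = []
    sample_ids = processed.injections["sample_id"].to_numpy()
    for attr in wanted:
        if attr not in passing:
            rows.append(
                {
                    "attribute": attr,
                    "latent_variables": None,
                    "r2": None,
                    "rmse": None,
                    "q2": None,
                    "n_selected": None,
                    "cv_anova_p": None,
                    "permutation_valid": None,
                }
            )
            continue
        means.require_complete([attr])
        res = build_attribute_model(
            processed.intensities,
            sample_ids,
            means.means[attr],
            attribute=attr,
            k_folds=params.k_folds,
            seed=params.seed,
            max_n_ortho=params.max_n_ortho,
            n_perm=params.n_perm,
            vip_threshold=params.vip_threshold,
            run_permutation=params.run_permutation,
            scale_in_fold=params.scale_in_fold,
            annotations=annotations,
        )
        results[attr] = res
        rows.append(res.summary_row())
        logger.info(
            "%s: %s, R2=%.3f Q2=%.3f", attr, res.notation, res.model.r2, res.model.q2
        )
    return RunReport(
        filter_summary=filt,
        anova_table=anova_table,
        attribute_table=pd.DataFrame(rows),
        results=results,
        removed_outliers=removed,
        seed=params.seed,
    )


def run_full(config: RunConfig) -> RunReport:
    """File-based pipeline: read CSV inputs, run, write artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = PeakTable.from_csv(config.peaks_path)
    panel = SensoryPanel.from_csv(config.panel_path, scales_path=config.scales_path)
    library = (
        AnnotationLibrary.from_csv(config.library_path) if config.library_path else None
    )
    extras = (
        pd.read_csv(config.extras_path, index_col=0) if config.extras_path else None
    )
    report = run_analysis(
        table,
        panel,
        library=library,
        extras=extras,
        params=config.params,
        attributes=config.attributes,
    )
    report.to_json(out / "report.json")
    report.attribute_table.to_csv(out / "models.csv", index=False)
    report.anova_table.to_csv(out / "anova.csv", index=False)
    for attr, res in report.results.items():
        stem = attr.replace(" ", "_").replace("/", "-")
        res.vip.to_csv(out / f"vip_{stem}.csv")
        with open(out / f"model_{stem}.json", "w") as fh:
            json.dump(res.model.to_dict(), fh)
        if res.permutation is not None:
            with open(out / f"permutation_{stem}.json", "w") as fh:
                json.dump(res.permutation.to_dict(), fh)
    return report


def run_transfer(
    report_a: RunReport,
    table_a: PeakTable,
    means_a: pd.DataFrame,
    report_b: RunReport,
    table_b: PeakTable,
    means_b: pd.DataFrame,
    attribute_pairs: list[tuple[str, str]],
    params: AnalysisParams | None = None,
) -> list[TransferResult]:
    """Cross-dataset validation for declared attribute correspondences.

    ``attribute_pairs`` maps an attribute of dataset A to the corresponding
    attribute of dataset B (the correspondence is user-declared, not
    inferred).
    """
    params = params or AnalysisParams()
    pairing = align_variables(
        table_a.peak_meta.loc[[v for v in table_a.peak_ids]],
        table_b.peak_meta.loc[[v for v in table_b.peak_ids]],
        rt_tol=params.rt_tol,
        mz_tol=params.mz_tol,
    )
    b_to_a = {b: a for a, b in pairing.mapping().items()}
    a_to_b = pairing.mapping()
    out = []
    ids_a = table_a.injections["sample_id"].to_numpy()
    ids_b = table_b.injections["sample_id"].to_numpy()
    for attr_a, attr_b in attribute_pairs:
        if attr_a not in report_a.results or attr_b not in report_b.results:
            out.append(
                TransferResult(
                    attribute_a=attr_a,
                    attribute_b=attr_b,
                    skipped_reason="no model for one of the attributes",
                )
            )
            continue
        res_a = report_a.results[attr_a]
        res_b = report_b.results[attr_b]
        tr = TransferResult(attribute_a=attr_a, attribute_b=attr_b)
        tr.full_a = res_a
        tr.full_b = res_b
        tr.validation_a_on_b = predict_external(
            res_a.model,
            table_b.intensities,
            means_b[attr_b].loc[ids_b].to_numpy(),
            sample_ids=ids_b,
            rename=b_to_a,
        )
        tr.validation_b_on_a = predict_external(
            res_b.model,
            table_a.intensities,
            means_a[attr_a].loc[ids_a].to_numpy(),
            sample_ids=ids_a,
            rename=a_to_b,
        )
        common = common_important(
            res_a.vip, res_b.vip, pairing, threshold=params.vip_threshold
        )
        tr = refit_reduced(
            table_a.intensities,
            ids_a,
            means_a[attr_a],
            table_b.intensities,
            ids_b,
            means_b[attr_b],
            common,
            pairing,
            tr,
            k_folds=params.k_folds,
            seed=params.seed,
            n_perm=params.n_perm,
            run_permutation=params.run_permutation,
            max_n_ortho=params.max_n_ortho,
        )
        out.append(tr)
    return out


def simulate_and_run(
    gen_config: GeneratorConfig,
    params: AnalysisParams | None = None,
    transfer_fraction: float | None = 0.5,
) -> dict:
    """Generate a synthetic study, run the full pipeline, and score the
    result against the planted ground truth.

    Returns a JSON-serializable dashboard: filter exactness, outlier-QC
    exactness, per-attribute fit/validation metrics and driver recovery,
    and (optionally) split-year transfer metrics.
    """
    params = params or AnalysisParams(seed=gen_config.seed)
    ds = generate_dataset(gen_config)
    dashboard: dict = {"seed": gen_config.seed}

    # filter exactness against the planted sets
    filtered, _ = pk.preprocess(ds.peaks, cv_threshold=params.cv_threshold)
    surviving = set(filtered.peak_ids)
    dashboard["filters_exact"] = surviving == set(ds.truth.informative_peaks)
    dashboard["n_retained_peaks"] = len(surviving)

    # outlier QC exactness
    _, removed = sn.remove_outliers(ds.panel)
    removed_keys = {
        (r.panelist_id, r.sample_id, r.attribute, int(r.round))
        for r in removed.itertuples()
    }
    dashboard["outliers_exact"] = removed_keys == ds.truth.injected_outliers
    dashboard["n_outliers_removed"] = len(removed_keys)
    dashboard["n_outliers_injected"] = len(ds.truth.injected_outliers)

    report = run_analysis(ds.peaks, ds.panel, library=ds.library, params=params)
    per_attr = {}
    for attr, res in report.results.items():
        drivers = ds.truth.driver_map.get(attr, {})
        sel = set(res.vip.selected)
        recovered = [p for p in drivers if p in sel]
        signs_ok = [
            p
            for p in recovered
            if np.sign(res.vip.table.at[p, "signed_vip"]) == np.sign(drivers[p])
        ]
        per_attr[attr] = {
            "latent_variables": res.notation,
            "r2": round(res.model.r2, 4),
            "q2": round(res.model.q2, 4),
            "rmse": round(res.model.rmse, 4),
            "n_selected": int(res.vip.table["selected"].sum()),
            "cv_anova_p": res.cv_anova_p,
            "permutation_valid": (
                bool(res.permutation.valid_flag) if res.permutation else None
            ),
            "driver_recovery": (
                len(recovered) / len(drivers) if drivers else None
            ),
            "sign_agreement": (
                len(signs_ok) / len(recovered) if recovered else None
            ),
        }
    dashboard["attributes"] = per_attr
    gated_out = set(ds.panel.attributes) - set(report.results)
    dashboard["gated_out_attributes"] = sorted(gated_out)

    if transfer_fraction is not None:
        ds_a, ds_b = split_years(ds, transfer_fraction, seed=gen_config.seed)
        # each year is filtered on its own data; models for transfer are
        # built on the peaks surviving the filters in BOTH years (the
        # cross-year matching step)
        filt_a = pk.preprocess(ds_a.peaks, cv_threshold=params.cv_threshold)[0]
        filt_b = pk.preprocess(ds_b.peaks, cv_threshold=params.cv_threshold)[0]
        common_peaks = [p for p in filt_a.peak_ids if p in set(filt_b.peak_ids)]
        tab_a = filt_a.subset_peaks(common_peaks)
        tab_b = filt_b.subset_peaks(common_peaks)
        rep_a = run_analysis(tab_a, ds_a.panel, params=params)
        rep_b = run_analysis(tab_b, ds_b.panel, params=params)
        means_a = sn.sample_means(sn.remove_outliers(ds_a.panel)[0]).means
        means_b = sn.sample_means(sn.remove_outliers(ds_b.panel)[0]).means
        pairs = [(a, a) for a in rep_a.results if a in rep_b.results]
        transfers = run_transfer(
            rep_a, tab_a, means_a, rep_b, tab_b, means_b, pairs, params=params
        )
        tr_dash = {}
        for tr in transfers:
            entry = {"skipped": tr.skipped_reason}
            if tr.validation_a_on_b is not None:
                entry.update(
                    {
                        "r2_validation_a_on_b": round(tr.validation_a_on_b.r2_validation, 4),
                        "r2_validation_b_on_a": round(tr.validation_b_on_a.r2_validation, 4),
                        "n_common": tr.n_common_variables,
                    }
                )
            if tr.reduced_validation_a_on_b is not None:
                entry.update(
                    {
                        "reduced_r2_validation_a_on_b": round(
                            tr.reduced_validation_a_on_b.r2_validation, 4
                        ),
                        "reduced_r2_validation_b_on_a": round(
                            tr.reduced_validation_b_on_a.r2_validation, 4
                        ),
                    }
                )
            tr_dash[tr.attribute_a] = entry
        dashboard["transfer"] = tr_dash
    return dashboard
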