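"""Peak-table preprocessing: the two retention filters, annotation, extras.

The exported peak table is reduced in a fixed order: first peaks whose
maximum intensity over all injections is zero, then peaks whose replicate
coefficient of variation reaches 10% in any sample.  Retained peaks are
annotated against an in-house compound library by retention time and m/z
tolerance, and per-sample general-property columns (acidity, aroma
compounds, ...) can be appended as pseudo-peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AnnotationLibrary, PeakTable

__all__ = [
    "remove_zero_max_peaks",
    "filter_by_replicate_cv",
    "replicate_cv",
    "annotate_peaks",
    "AnnotatedPeakTable",
    "merge_extra_variables",
    "preprocess",
]


def remove_zero_max_peaks(table: PeakTable) -> PeakTable:
    """Drop peaks whose maximum intensity over all injections is zero.

    Column order of the surviving peaks is preserved; an empty result is
    allowed.
    """
    keep = table.intensities.max(axis=0) > 0
    return table.subset_peaks(table.intensities.columns[keep])


def replicate_cv(table: PeakTable) -> pd.DataFrame:
    """Percent CV of replicate intensities per (sample, peak).

    CV = 100 * sd(replicates, n-1 denominator) / mean(replicates).  A zero
    replicate mean yields +inf so the peak is guaranteed to fail the filter.
    """
    counts = table.injections.groupby("sample_id").size()
    if (counts < 2).any():
        raise ValueError("replicate CV undefined: some sample has < 2 injections")
    g = table.intensities.groupby(table.injections["sample_id"].values)
    mean = g.mean()
    sd = g.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd.to_numpy() / mean.to_numpy()
    cv[~np.isfinite(cv)] = np.inf
    return pd.DataFrame(cv, index=mean.index, columns=mean.columns)


def filter_by_replicate_cv(table: PeakTable, threshold_percent: float = 10.0) -> PeakTable:
    """Drop peaks whose worst-sample replicate CV is >= the threshold.

    The comparison is inclusive: a peak with a maximum CV of exactly the
    threshold is removed.
    """
    cv = replicate_cv(table)
    keep = cv.max(axis=0) < threshold_percent
    return table.subset_peaks(cv.columns[keep])


@dataclass
class AnnotatedPeakTable:
    """A peak table plus per-peak annotation.

    ``annotations`` is indexed by peak_id with columns ``compound_name``,
    ``compound_group``, ``delta_rt``, ``delta_mz`` (NaN rows are
    unannotated peaks).  ``candidates`` lists every library entry inside
    both tolerances for a peak, with its normalized combined distance.
    """

    table: PeakTable
    annotations: pd.DataFrame
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_annotated(self) -> int:
        return int(self.annotations["compound_name"].notna().sum())


def annotate_peaks(
    table: PeakTable,
    library: AnnotationLibrary,
    rt_tol: float = 0.1,
    mz_tol: float = 0.007,
    inclusive: bool = True,
) -> AnnotatedPeakTable:
    """Match peaks to library compounds within rt/mz tolerances.

    A library entry is a candidate iff |delta rt| <= rt_tol and
    |delta m/z| <= mz_tol (strict < with ``inclusive=False``).  The assigned
    annotation minimizes the normalized combined distance
    |drt|/rt_tol + |dmz|/mz_tol, ties broken by compound name.
    """
    if rt_tol <= 0 or mz_tol <= 0:
        raise ValueError("tolerances must be positive")
    lib = library.entries
    lib_rt = lib["rt"].to_numpy()
    lib_mz = lib["mz"].to_numpy()
    rows = []
    cand_rows = []
    for pid, meta in table.peak_meta.iterrows():
        if not np.isfinite(meta["rt"]):
            rows.append((pid, None, None, np.nan, np.nan))
            continue
        drt = lib_rt - meta["rt"]
        dmz = lib_mz - meta["mz"]
        if inclusive:
            hit = (np.abs(drt) <= rt_tol) & (np.abs(dmz) <= mz_tol)
        else:
            hit = (np.abs(drt) < rt_tol) & (np.abs(dmz) < mz_tol)
        idx = np.flatnonzero(hit)
        if len(idx) == 0:
            rows.append((pid, None, None, np.nan, np.nan))
            continue
        dist = np.abs(drt[idx]) / rt_tol + np.abs(dmz[idx]) / mz_tol
        cand = lib.iloc[idx].assign(
            peak_id=pid, delta_rt=drt[idx], delta_mz=dmz[idx], distance=dist
        )
        cand = cand.sort_values(["distance", "compound_name"], kind="mergesort")
        cand_rows.append(cand)
        best = cand.iloc[0]
        rows.append(
            (
                pid,
                best["compound_name"],
                best["compound_group"],
                best["delta_rt"],
                best["delta_mz"],
            )
        )
    annotations = pd.DataFrame(
        rows,
        columns=["peak_id", "compound_name", "compound_group", "delta_rt", "delta_mz"],
    ).set_index("peak_id")
    candidates = (
        pd.concat(cand_rows, ignore_index=True)
        if cand_rows
        else pd.DataFrame(
            columns=[
                "compound_name",
                "rt",
                "mz",
                "compound_group",
                "peak_id",
                "delta_rt",
                "delta_mz",
                "distance",
            ]
        )
    )
    return AnnotatedPeakTable(table=table, annotations=annotations, candidates=candidates)


def merge_extra_variables(table: PeakTable, extras: pd.DataFrame) -> PeakTable:
    """Append general-property / aroma columns as pseudo-peak variables.

    ``extras`` is indexed by sample_id (one value per sample, broadcast over
    that sample's injections) or has exactly one row per injection, in which
    case values are used as-is.  Pseudo-peaks carry NaN rt/mz metadata.
    """
    if extras.shape[1] == 0:
        return table
    overlap = set(extras.columns) & set(table.peak_ids)
    if overlap:
        raise ValueError(f"extra variables collide with peak ids: {sorted(overlap)[:5]}")
    if len(extras) == len(table.injections) and not set(extras.index) <= set(
        table.sample_ids
    ):
        values = extras.reset_index(drop=True)
    else:
        missing = set(table.sample_ids) - set(extras.index)
        if missing:
            raise ValueError(f"extras missing samples: {sorted(missing)[:5]}")
        values = extras.loc[table.injections["sample_id"].values].reset_index(drop=True)
    meta_extra = pd.DataFrame(
        {"rt": np.nan, "mz": np.nan},
        index=pd.Index(extras.columns, name="peak_id"),
    )
    return PeakTable(
        intensities=pd.concat([table.intensities, values], axis=1),
        injections=table.injections.copy(),
        peak_meta=pd.concat([table.peak_meta, meta_extra]),
    )


def preprocess(
    table: PeakTable,
    library: AnnotationLibrary | None = None,
    cv_threshold: float = 10.0,
    rt_tol: float = 0.1,
    mz_tol: float = 0.007,
    extras: pd.DataFrame | None = None,
) -> tuple[PeakTable, dict]:
    """Full preprocessing chain with a filter-audit report.

    Applies the zero-maximum filter, then the replicate-CV filter, optional
    annotation and optional extra-variable merge.  The report records peak
    counts before and after each stage.
    """
    report: dict = {"n_input_peaks": table.n_peaks}
    t1 = remove_zero_max_peaks(table)
    report["n_after_zero_max"] = t1.n_peaks
    t2 = filter_by_replicate_cv(t1, cv_threshold)
    report["n_after_cv_filter"] = t2.n_peaks
    if library is not None:
        ann = annotate_peaks(t2, library, rt_tol=rt_tol, mz_tol=mz_tol)
        report["n_annotated"] = ann.n_annotated
        report["annotations"] = ann
    if extras is not None:
        t2 = merge_extra_variables(t2, extras)
        report["n_with_extras"] = t2.n_peaks
    return t2, report
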