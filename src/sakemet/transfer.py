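"""Cross-year transfer validation of fitted sensory models.

A model fitted on one year's data is applied, unchanged, to the other
year's peak table: the target X is scaled with the *model's* scaling
parameters, the orthogonal filter is applied with the model's weights, and
validation metrics are computed against the target's sensory means.  Peaks
are paired across years by mutual nearest match within the annotation
rt/mz tolerances.  Variables important in both years (|signed VIPpred| above
the threshold in each) define reduced models that are refitted per year and
cross-validated again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import OplsModel
from .modeling import AttributeModelResult, VipReport, build_attribute_model

__all__ = [
    "align_variables",
    "VariablePairing",
    "ExternalValidation",
    "predict_external",
    "common_important",
    "TransferResult",
    "refit_reduced",
]


@dataclass
class VariablePairing:
    """Peak pairing across two datasets.

    ``pairs`` columns: ``peak_a``, ``peak_b``, ``delta_rt``, ``delta_mz``,
    ``distance`` (normalized).  ``unpaired_a``/``unpaired_b`` list peaks
    without a mutual match; ``ties`` records ambiguous equal-distance
    matches that were broken by identifier order.
    """

    pairs: pd.DataFrame
    unpaired_a: list = field(default_factory=list)
    unpaired_b: list = field(default_factory=list)
    ties: list = field(default_factory=list)

    def mapping(self) -> dict:
        return dict(zip(self.pairs["peak_a"], self.pairs["peak_b"]))


def align_variables(
    meta_a: pd.DataFrame,
    meta_b: pd.DataFrame,
    rt_tol: float = 0.1,
    mz_tol: float = 0.007,
) -> VariablePairing:
    """Pair peaks across datasets by mutual nearest normalized distance.

    A pair is kept iff each peak is the other's nearest in-tolerance match,
    where distance = |drt|/rt_tol + |dmz|/mz_tol.
    """
    if rt_tol <= 0 or mz_tol <= 0:
        raise ValueError("tolerances must be positive")
    ids_a = meta_a.index.to_numpy()
    ids_b = meta_b.index.to_numpy()
    drt = np.abs(meta_a["rt"].to_numpy()[:, None] - meta_b["rt"].to_numpy()[None, :])
    dmz = np.abs(meta_a["mz"].to_numpy()[:, None] - meta_b["mz"].to_numpy()[None, :])
    ok = (drt <= rt_tol) & (dmz <= mz_tol)
    dist = drt / rt_tol + dmz / mz_tol
    dist[~ok] = np.inf

    rows, ties = [], []
    if dist.size:
        best_b = dist.argmin(axis=1)
        best_a = dist.argmin(axis=0)
        for i, j in enumerate(best_b):
            if not np.isfinite(dist[i, j]) or best_a[j] != i:
                continue
            # detect exact-distance ambiguity (broken by argmin's first hit)
            if (dist[i] == dist[i, j]).sum() > 1 or (dist[:, j] == dist[i, j]).sum() > 1:
                ties.append((str(ids_a[i]), str(ids_b[j])))
            rows.append(
                (
                    ids_a[i],
                    ids_b[j],
                    meta_a["rt"].iloc[i] - meta_b["rt"].iloc[j],
                    meta_a["mz"].iloc[i] - meta_b["mz"].iloc[j],
                    dist[i, j],
                )
            )
    pairs = pd.DataFrame(
        rows, columns=["peak_a", "peak_b", "delta_rt", "delta_mz", "distance"]
    )
    return VariablePairing(
        pairs=pairs,
        unpaired_a=sorted(set(ids_a) - set(pairs["peak_a"])),
        unpaired_b=sorted(set(ids_b) - set(pairs["peak_b"])),
        ties=ties,
    )


@dataclass
class ExternalValidation:
    """Validation-set metrics of a model applied to an independent dataset.

    ``r2_validation`` is the coefficient of determination 1 - SS_res/SS_tot
    on the target's scaled y (scaled with the model's y parameters; can be
    negative); ``r2_correlation`` is the squared Pearson correlation
    variant; ``rmse_validation`` is on the original score scale.
    """

    r2_validation: float
    r2_correlation: float
    rmse_validation: float
    n_samples: int
    n_injections: int


def predict_external(
    model: OplsModel,
    X_target: pd.DataFrame,
    y_target,
    sample_ids=None,
    rename: dict | None = None,
) -> ExternalValidation:
    """Apply a fitted model to an independent dataset.

    ``rename`` maps target column names onto the model's variable names
    (from :func:`align_variables`).  The target is scaled with the model's
    training parameters — the target year is treated as fully unknown.
    """
    X = X_target.rename(columns=rename) if rename else X_target
    missing = set(model.variables) - set(X.columns)
    if missing:
        raise ValueError(f"unmatched model variables: {sorted(missing)[:5]}")
    y = np.asarray(y_target, dtype=float).ravel()
    if sample_ids is not None:
        n_samples = len(pd.unique(np.asarray(sample_ids)))
    else:
        n_samples = len(y)
    if n_samples < 5:
        raise ValueError("need at least 5 target samples for validation")

    y_scaled = (y - model.y_mean) / model.y_sd
    y_hat_scaled = model.predict_scaled(X)
    ss_res = float(((y_scaled - y_hat_scaled) ** 2).sum())
    ss_tot = float((y_scaled**2).sum())
    y_hat = y_hat_scaled * model.y_sd + model.y_mean
    if np.std(y_hat) > 0 and np.std(y) > 0:
        r2_corr = float(np.corrcoef(y, y_hat)[0, 1] ** 2)
    else:
        r2_corr = 0.0
    return ExternalValidation(
        r2_validation=1.0 - ss_res / ss_tot,
        r2_correlation=r2_corr,
        rmse_validation=float(np.sqrt(np.mean((y - y_hat) ** 2))),
        n_samples=n_samples,
        n_injections=len(y),
    )


def common_important(
    vip_a: VipReport,
    vip_b: VipReport,
    pairing: VariablePairing,
    threshold: float = 1.5,
) -> list[tuple]:
    """Paired variables with |signed VIPpred| strictly above the threshold in
    BOTH datasets; an empty list is allowed."""
    ta, tb = vip_a.table, vip_b.table
    out = []
    for a_id, b_id in pairing.mapping().items():
        if a_id not in ta.index or b_id not in tb.index:
            continue
        if (
            abs(ta.at[a_id, "signed_vip"]) > threshold
            and abs(tb.at[b_id, "signed_vip"]) > threshold
        ):
            out.append((a_id, b_id))
    return out


@dataclass
class TransferResult:
    """Cross-dataset validation summary for one attribute pair."""

    attribute_a: str
    attribute_b: str
    full_a: AttributeModelResult | None = None
    full_b: AttributeModelResult | None = None
    validation_a_on_b: ExternalValidation | None = None
    validation_b_on_a: ExternalValidation | None = None
    common_variables: list = field(default_factory=list)
    reduced_a: AttributeModelResult | None = None
    reduced_b: AttributeModelResult | None = None
    reduced_validation_a_on_b: ExternalValidation | None = None
    reduced_validation_b_on_a: ExternalValidation | None = None
    skipped_reason: str | None = None

    @property
    def n_common_variables(self) -> int:
        return len(self.common_variables)


def refit_reduced(
    X_a: pd.DataFrame,
    sample_ids_a,
    y_means_a: pd.Series,
    X_b: pd.DataFrame,
    sample_ids_b,
    y_means_b: pd.Series,
    common: list[tuple],
    pairing: VariablePairing,
    result: TransferResult,
    k_folds: int = 7,
    seed: int = 0,
    n_perm: int = 100,
    run_permutation: bool = True,
    max_n_ortho: int = 8,
) -> TransferResult:
    """Refit both years on the common important variables and re-evaluate
    transfer; with an empty selection an explicit skip record is returned."""
    if not common:
        result.skipped_reason = "no common variables above the VIP threshold"
        return result
    ids_a = [a for a, _ in common]
    ids_b = [b for _, b in common]
    b_to_a = {b: a for a, b in common}
    a_to_b = {a: b for a, b in common}

    result.common_variables = common
    result.reduced_a = build_attribute_model(
        X_a[ids_a], sample_ids_a, y_means_a,
        attribute=result.attribute_a, k_folds=k_folds, seed=seed,
        n_perm=n_perm, run_permutation=run_permutation, max_n_ortho=max_n_ortho,
    )
    result.reduced_b = build_attribute_model(
        X_b[ids_b], sample_ids_b, y_means_b,
        attribute=result.attribute_b, k_folds=k_folds, seed=seed,
        n_perm=n_perm, run_permutation=run_permutation, max_n_ortho=max_n_ortho,
    )
    result.reduced_validation_a_on_b = predict_external(
        result.reduced_a.model,
        X_b[ids_b],
        y_means_b.loc[np.asarray(sample_ids_b)].to_numpy(),
        sample_ids=sample_ids_b,
        rename=b_to_a,
    )
    result.reduced_validation_b_on_a = predict_external(
        result.reduced_b.model,
        X_a[ids_a],
        y_means_a.loc[np.asarray(sample_ids_a)].to_numpy(),
        sample_ids=sample_ids_a,
        rename=a_to_b,
    )
    return result
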