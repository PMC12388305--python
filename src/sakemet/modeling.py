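"""Model building: orthogonal-component selection, permutation validation,
CV-ANOVA, and signed VIPpred variable importance.

The number of X-orthogonal components is chosen by forward search, keeping
the largest count for which cross-validated Q2 still increases.  The fitted
configuration is then validated by a permutation test (y re-assigned across
samples, model refitted with the same component count and folds); the
regression lines of permuted R2 and Q2 on the correlation between permuted
and original y give the intercept criteria (R2 intercept < 0.3 and Q2
intercept < -0.05).  If the criteria fail, orthogonal components are
removed one at a time and the test repeated.

Variable importance uses VIPpred — VIP over the single predictive
component, vip_j = sqrt(p) * |w_j| (w has unit norm) — signed by the
Pearson correlation of each variable's sample means with the attribute's
sample-mean score.  Variables with VIPpred > 1.5 are flagged as selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import (
    FoldCache,
    OplsModel,
    cv_sstot,
    fit_model,
    fit_opls,
    grouped_q2,
    make_grouped_folds,
)

__all__ = [
    "ComponentSearchTrace",
    "select_orthogonal_components",
    "PermutationReport",
    "permutation_test",
    "reduce_until_valid",
    "cv_anova",
    "vip_pred",
    "VipReport",
    "sign_and_select",
    "AttributeModelResult",
    "build_attribute_model",
]


# ---------------------------------------------------------------------------
# component selection
# ---------------------------------------------------------------------------


@dataclass
class ComponentSearchTrace:
    """Forward-search record: (n_ortho, r2, q2) triples visited, the chosen
    orthogonal-component count, and why the search stopped."""

    visited: list = field(default_factory=list)  # (a_o, r2, q2)
    chosen: int = 0
    stopping_reason: str = ""


def select_orthogonal_components(
    X: pd.DataFrame,
    y,
    folds: np.ndarray,
    max_n_ortho: int = 8,
    scale_in_fold: bool = True,
    q2_fn=None,
) -> ComponentSearchTrace:
    """Forward search over the orthogonal-component count.

    Starting at zero, one more component is accepted only while Q2 strictly
    increases; the chosen count is the last accepted.  ``q2_fn(a_o)`` may be
    injected for testing; by default it runs grouped cross-validation.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
    y = np.asarray(y, dtype=float).ravel()
    if q2_fn is None:
        cache = FoldCache(Xv, folds, scale_in_fold=scale_in_fold)
        Xg, yg = _global_scaled(Xv, y)

    def _default_q2(a_o: int):
        try:
            q2, _ = cache.q2(y, a_o)
            r2 = fit_opls(Xg, yg, a_o)["r2"]
            return q2, r2
        except ValueError:
            return None

    evaluate = q2_fn if q2_fn is not None else _default_q2
    trace = ComponentSearchTrace()
    result = evaluate(0)
    if result is None:
        raise ValueError("cannot fit the zero-orthogonal-component model")
    q2_prev, r2 = result
    trace.visited.append((0, r2, q2_prev))
    trace.chosen = 0
    for a_o in range(1, max_n_ortho + 1):
        result = evaluate(a_o)
        if result is None:
            trace.stopping_reason = "no further orthogonal component extractable"
            return trace
        q2, r2 = result
        trace.visited.append((a_o, r2, q2))
        if q2 > q2_prev:
            trace.chosen = a_o
            q2_prev = q2
        else:
            trace.stopping_reason = "Q2 stopped increasing"
            return trace
    trace.stopping_reason = "reached max_n_ortho"
    return trace


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationReport:
    """Permutation-test record: per-permutation |r|, R2 and Q2; the
    intercepts of the R2 and Q2 regression lines (fitted through the
    permuted cloud plus the unpermuted anchor at correlation 1); and the
    validity flag.

    A configuration is valid when the intercept criteria hold (R2 intercept
    < 0.3 and Q2 intercept < -0.05) *and* the unpermuted model's Q2 exceeds
    every permuted Q2 — the intercepts alone cannot reject a no-signal
    model, whose anchor sits inside the permuted cloud and whose (low)
    intercepts pass trivially.  The full permutation cloud is serialized so
    alternative readings of the criteria can be applied downstream."""

    n_perm: int
    correlations: np.ndarray
    r2_perm: np.ndarray
    q2_perm: np.ndarray
    r2_model: float
    q2_model: float
    r2_intercept: float
    q2_intercept: float
    valid_flag: bool
    n_ortho: int = 0

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "correlations": self.correlations.tolist(),
            "r2_perm": self.r2_perm.tolist(),
            "q2_perm": self.q2_perm.tolist(),
            "r2_model": self.r2_model,
            "q2_model": self.q2_model,
            "r2_intercept": self.r2_intercept,
            "q2_intercept": self.q2_intercept,
            "valid_flag": self.valid_flag,
            "n_ortho": self.n_ortho,
        }


def _intercept(x: np.ndarray, z: np.ndarray) -> float:
    """Intercept of the least-squares line z ~ x."""
    slope, intercept = np.polyfit(x, z, 1)
    return float(intercept)


def _global_scaled(Xv: np.ndarray, y: np.ndarray):
    """Autoscale arrays once (zero-variance columns dropped)."""
    xm = Xv.mean(axis=0)
    xs = Xv.std(axis=0, ddof=1)
    keep = xs > 1e-12
    Xg = (Xv[:, keep] - xm[keep]) / xs[keep]
    ysd = float(np.std(y, ddof=1))
    if ysd <= 1e-12:
        raise ValueError("response is constant")
    return Xg, (y - float(y.mean())) / ysd


def permutation_test(
    X: pd.DataFrame,
    y,
    sample_ids,
    n_ortho: int,
    folds: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    scale_in_fold: bool = True,
    r2_threshold: float = 0.3,
    q2_threshold: float = -0.05,
) -> PermutationReport:
    """Validate a fitted configuration by response permutation.

    y is permuted over samples (every injection of a sample keeps the
    permuted sample value, preserving the replicate structure); the model is
    refitted with the same component count and folds for each permutation.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
    y = np.asarray(y, dtype=float).ravel()
    sample_ids = np.asarray(sample_ids)
    uniq, inverse = np.unique(sample_ids, return_inverse=True)
    # one y value per sample (replicates share the sample's score)
    y_sample = np.array([y[inverse == i].mean() for i in range(len(uniq))])

    cache = FoldCache(Xv, folds, scale_in_fold=scale_in_fold)
    Xg, yg = _global_scaled(Xv, y)
    r2_model = fit_opls(Xg, yg, n_ortho)["r2"]
    q2_model, _ = cache.q2(y, n_ortho)

    rng = np.random.default_rng(seed)
    corr = np.empty(n_perm)
    r2s = np.empty(n_perm)
    q2s = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(uniq))
        y_perm = y_sample[perm][inverse]
        corr[i] = abs(float(np.corrcoef(y_sample[perm], y_sample)[0, 1]))
        try:
            _, yp = _global_scaled(Xv, y_perm)
            r2s[i] = fit_opls(Xg, yp, n_ortho)["r2"]
            q2s[i], _ = cache.q2(y_perm, n_ortho)
        except ValueError:
            # orthogonal components unextractable under this permutation
            r2s[i] = np.nan
            q2s[i] = np.nan
    ok = np.isfinite(r2s)
    xs = np.append(corr[ok], 1.0)  # unpermuted anchor at correlation 1
    r2_int = _intercept(xs, np.append(r2s[ok], r2_model))
    q2_int = _intercept(xs, np.append(q2s[ok], q2_model))
    separated = bool(np.all(q2s[ok] < q2_model))
    return PermutationReport(
        n_perm=n_perm,
        correlations=corr,
        r2_perm=r2s,
        q2_perm=q2s,
        r2_model=r2_model,
        q2_model=q2_model,
        r2_intercept=r2_int,
        q2_intercept=q2_int,
        valid_flag=bool(
            r2_int < r2_threshold and q2_int < q2_threshold and separated
        ),
        n_ortho=n_ortho,
    )


def reduce_until_valid(
    X: pd.DataFrame,
    y,
    sample_ids,
    trace: ComponentSearchTrace,
    folds: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    scale_in_fold: bool = True,
) -> tuple[OplsModel, PermutationReport]:
    """Starting at the chosen component count, drop orthogonal components
    until the permutation criteria pass (or zero is reached).

    Returns the final fitted model (with Q2 attached) and the last
    permutation report; a model that never validates is returned at zero
    orthogonal components with ``valid_flag=False``.
    """
    X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    y = np.asarray(y, dtype=float).ravel()
    a_o = trace.chosen
    while True:
        report = permutation_test(
            X_df, y, sample_ids, a_o, folds, n_perm=n_perm, seed=seed,
            scale_in_fold=scale_in_fold,
        )
        if report.valid_flag or a_o == 0:
            break
        a_o -= 1
    model = fit_model(X_df, y, a_o)
    model.q2, model.press = grouped_q2(
        X_df.to_numpy(dtype=float), y, a_o, folds, scale_in_fold=scale_in_fold
    )
    model.ss_tot_cv = cv_sstot(y, folds, scale_in_fold=scale_in_fold)
    model.folds = np.asarray(folds)
    return model, report


# ---------------------------------------------------------------------------
# CV-ANOVA
# ---------------------------------------------------------------------------


def cv_anova(press: float, ss_tot: float, n: int, a: int) -> tuple[float, float]:
    """F-test of cross-validated predictive residuals against total y
    variation.

    The variation explained in cross-validation (ss_tot - press, a degrees
    of freedom for a model with ``a`` components) is compared against the
    predictive residual mean square (press on n - a - 1 degrees of
    freedom); p comes from the F distribution.
    """
    df1 = a
    df2 = n - a - 1
    if df1 <= 0 or df2 <= 0:
        raise ValueError("non-positive degrees of freedom")
    ms_model = max(ss_tot - press, 0.0) / df1
    ms_resid = press / df2
    if ms_resid <= 0:
        return np.inf, 0.0
    f = ms_model / ms_resid
    return float(f), float(stats.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# VIPpred
# ---------------------------------------------------------------------------


@dataclass
class VipReport:
    """Per-variable VIPpred with correlation sign and selection flag.

    ``table`` columns: ``vip``, ``pearson_r``, ``signed_vip``, ``selected``,
    plus annotation passthrough columns when provided.
    """

    table: pd.DataFrame
    threshold: float = 1.5

    @property
    def selected(self) -> list:
        return list(self.table.index[self.table["selected"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def vip_pred(model: OplsModel) -> pd.Series:
    """Unsigned VIPpred over the single predictive component.

    With one predictive component and unit-norm w, vip_j = sqrt(p) * |w_j|;
    orthogonal components do not enter by definition of the predictive VIP.
    The identity mean(vip^2) = 1 holds for every fitted model.
    """
    p = len(model.w)
    w = model.w / np.linalg.norm(model.w)
    return pd.Series(np.sqrt(p) * np.abs(w), index=model.variables, name="vip")


def sign_and_select(
    model: OplsModel,
    x_sample_means: pd.DataFrame,
    y_means,
    threshold: float = 1.5,
    annotations: pd.DataFrame | None = None,
) -> VipReport:
    """Sign VIPpred by the Pearson correlation with the sample-mean response
    and flag variables with VIPpred strictly above the threshold.

    Correlations are computed on sample-level means, where sensory scores
    live.  A zero-variance variable gets sign 0 and is never selected.
    """
    vips = vip_pred(model)
    xm = x_sample_means[model.variables].to_numpy(dtype=float)
    ym = np.asarray(y_means, dtype=float).ravel()
    xc = xm - xm.mean(axis=0)
    yc = ym - ym.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / denom
    r[~np.isfinite(r)] = 0.0
    zero_var = (xc**2).sum(axis=0) <= 1e-24
    r[zero_var] = 0.0
    table = pd.DataFrame(
        {
            "vip": vips.to_numpy(),
            "pearson_r": r,
            "signed_vip": np.sign(r) * vips.to_numpy(),
            "selected": (vips.to_numpy() > threshold) & ~zero_var,
        },
        index=pd.Index(model.variables, name="peak_id"),
    )
    if annotations is not None:
        table = table.join(annotations, how="left")
    return VipReport(table=table, threshold=threshold)


# ---------------------------------------------------------------------------
# high-level per-attribute build
# ---------------------------------------------------------------------------


@dataclass
class AttributeModelResult:
    attribute: str
    model: OplsModel
    trace: ComponentSearchTrace
    permutation: PermutationReport | None
    vip: VipReport
    cv_anova_f: float
    cv_anova_p: float

    @property
    def notation(self) -> str:
        return self.model.notation

    def summary_row(self) -> dict:
        return {
            "attribute": self.attribute,
            "latent_variables": self.notation,
            "r2": round(self.model.r2, 3),
            "rmse": round(self.model.rmse, 2),
            "q2": round(self.model.q2, 3) if self.model.q2 is not None else None,
            "n_selected": int(self.vip.table["selected"].sum()),
            "cv_anova_p": self.cv_anova_p,
            "permutation_valid": (
                self.permutation.valid_flag if self.permutation else None
            ),
        }


def build_attribute_model(
    X: pd.DataFrame,
    injection_sample_ids,
    y_sample_means: pd.Series,
    attribute: str = "",
    k_folds: int = 7,
    seed: int = 0,
    max_n_ortho: int = 8,
    n_perm: int = 100,
    vip_threshold: float = 1.5,
    run_permutation: bool = True,
    scale_in_fold: bool = True,
    annotations: pd.DataFrame | None = None,
) -> AttributeModelResult:
    """Fit and validate one attribute's OPLS model end to end.

    ``X`` is the preprocessed injection x variable matrix,
    ``injection_sample_ids`` maps rows to samples, and ``y_sample_means``
    holds the attribute's post-QC mean score per sample (broadcast over each
    sample's injections for fitting).
    """
    sample_ids = np.asarray(injection_sample_ids)
    y = y_sample_means.loc[sample_ids].to_numpy(dtype=float)
    folds = make_grouped_folds(sample_ids, k=k_folds, seed=seed)
    trace = select_orthogonal_components(
        X, y, folds, max_n_ortho=max_n_ortho, scale_in_fold=scale_in_fold
    )
    if run_permutation:
        model, report = reduce_until_valid(
            X, y, sample_ids, trace, folds, n_perm=n_perm, seed=seed,
            scale_in_fold=scale_in_fold,
        )
    else:
        report = None
        model = fit_model(X, y, trace.chosen, attribute=attribute)
        model.q2, model.press = grouped_q2(
            X.to_numpy(dtype=float), y, trace.chosen, folds,
            scale_in_fold=scale_in_fold,
        )
        model.ss_tot_cv = cv_sstot(y, folds, scale_in_fold=scale_in_fold)
        model.folds = folds
    model.attribute = attribute

    n = len(y)
    a_total = 1 + model.n_ortho
    f, p = cv_anova(model.press, model.ss_tot_cv, n, a_total)

    x_means = X.groupby(pd.Series(sample_ids, name="sample_id").values).mean()
    y_means_aligned = y_sample_means.loc[x_means.index]
    vip = sign_and_select(
        model, x_means, y_means_aligned, threshold=vip_threshold,
        annotations=annotations,
    )
    return AttributeModelResult(
        attribute=attribute,
        model=model,
        trace=trace,
        permutation=report,
        vip=vip,
        cv_anova_f=f,
        cv_anova_p=p,
    )
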