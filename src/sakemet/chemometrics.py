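"""Chemometric core: UV scaling, PCA, single-response OPLS, grouped CV.

The estimator here is the single-y orthogonal projections to latent
structures (OPLS) regression fitted by NIPALS.  The model separates X
variation predictive of y (one component, since y is a single column) from
X variation orthogonal to y (``n_ortho`` components, removed before the
predictive component is extracted).  Component counts are written in the
conventional ``1 + k + 0`` notation: one predictive, k X-orthogonal, zero
y-orthogonal components.

Cross-validation is replicate-aware: all injections of a sample are assigned
to the same fold so replicate leakage cannot inflate Q2.  Scaling parameters
are re-estimated inside each training fold by default; ``scale_in_fold=False``
reproduces the global-scaling convention of common commercial software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScalingParams",
    "uv_scale",
    "PcaResult",
    "pca",
    "fit_opls",
    "OplsModel",
    "fit_model",
    "make_grouped_folds",
    "grouped_q2",
    "FoldCache",
    "cv_sstot",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# UV scaling
# ---------------------------------------------------------------------------


@dataclass
class ScalingParams:
    """Per-variable mean and standard deviation (n-1 denominator).

    ``dropped`` lists variables whose training standard deviation was zero;
    they carry no information after autoscaling and are removed.
    """

    mean: pd.Series
    sd: pd.Series
    dropped: list = field(default_factory=list)

    @property
    def variables(self) -> list:
        return list(self.mean.index)


def uv_scale(matrix: pd.DataFrame, params: ScalingParams | None = None):
    """Autoscale columns to mean 0 / unit variance (UV scaling).

    With ``params`` given (e.g. scaling validation data with training
    parameters) those statistics are applied instead of re-estimating them.
    Returns ``(scaled DataFrame, ScalingParams)``.
    """
    if params is not None:
        missing = set(params.variables) - set(matrix.columns)
        if missing:
            raise ValueError(f"matrix lacks scaled variables: {sorted(missing)[:5]}")
        sub = matrix[params.variables]
        scaled = (sub - params.mean) / params.sd
        return scaled, params

    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    keep = sd > _EPS
    dropped = list(matrix.columns[~keep])
    if not keep.any():
        raise ValueError("all variables have zero variance")
    params = ScalingParams(mean=mean[keep], sd=sd[keep], dropped=dropped)
    scaled = (matrix.loc[:, keep] - params.mean) / params.sd
    return scaled, params


def _uv_scale_arrays(X: np.ndarray, y: np.ndarray):
    """Array fast path used inside cross-validation folds.

    Returns scaled X (zero-variance columns masked out), scaled y, and the
    statistics needed to scale held-out data.
    """
    xm = X.mean(axis=0)
    xs = X.std(axis=0, ddof=1)
    keep = xs > _EPS
    ym = float(y.mean())
    ys = float(y.std(ddof=1))
    if ys <= _EPS:
        raise ValueError("response is constant")
    Xs = (X[:, keep] - xm[keep]) / xs[keep]
    return Xs, (y - ym) / ys, xm, xs, keep, ym, ys


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray  # sample x component
    loadings: np.ndarray  # variable x component
    explained_variance_ratio: np.ndarray


def pca(matrix, n_components: int | None = None) -> PcaResult:
    """SVD-based PCA of a UV-scaled matrix.

    Explained variance ratio of component k is sigma_k^2 / sum(sigma^2).
    The input is assumed centered (UV scaling centers); rows are samples.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    if total <= _EPS:
        raise ValueError("rank-0 input")
    if n_components is None:
        n_components = int((s > np.sqrt(_EPS)).sum())
    n_components = min(n_components, len(s))
    return PcaResult(
        scores=U[:, :n_components] * s[:n_components],
        loadings=Vt[:n_components].T,
        explained_variance_ratio=(s[:n_components] ** 2) / total,
    )


# ---------------------------------------------------------------------------
# OPLS core (NIPALS, single y)
# ---------------------------------------------------------------------------


def fit_opls(X: np.ndarray, y: np.ndarray, n_ortho: int = 0) -> dict:
    """Fit single-response OPLS on already-scaled arrays.

    For each of the ``n_ortho`` rounds the weight w is taken proportional to
    X'y, the loading p of the predictive score is computed, and the part of p
    orthogonal to w defines the orthogonal weight w_o; the orthogonal score
    t_o = X w_o is deflated from X.  The predictive component is then fitted
    on the deflated matrix.

    Returns a dict with predictive weights/scores/loading ``w, t, p, c``,
    orthogonal blocks ``W_o, P_o, T_o`` (columns are components), and the
    coefficient vector ``beta`` such that ``y_hat_scaled = X @ beta``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if float(np.std(y)) <= _EPS:
        raise ValueError("response is constant")
    n, p = X.shape
    Xd = X.copy()
    W_o = np.zeros((p, n_ortho))
    P_o = np.zeros((p, n_ortho))
    T_o = np.zeros((n, n_ortho))
    extracted = 0
    for _ in range(n_ortho):
        w = Xd.T @ y
        w_norm = np.linalg.norm(w)
        if w_norm <= _EPS:
            break
        w /= w_norm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        p_load = Xd.T @ t / tt
        w_ortho = p_load - float(w @ p_load) * w
        wo_norm = np.linalg.norm(w_ortho)
        if wo_norm <= 1e-10:
            break  # no y-orthogonal structure left to remove
        w_ortho /= wo_norm
        t_ortho = Xd @ w_ortho
        tot = float(t_ortho @ t_ortho)
        if tot <= _EPS:
            break
        p_ortho = Xd.T @ t_ortho / tot
        Xd -= np.outer(t_ortho, p_ortho)
        W_o[:, extracted] = w_ortho
        P_o[:, extracted] = p_ortho
        T_o[:, extracted] = t_ortho
        extracted += 1
    if extracted < n_ortho:
        raise ValueError(
            f"could only extract {extracted} of {n_ortho} orthogonal components"
        )

    w = Xd.T @ y
    w_norm = np.linalg.norm(w)
    if w_norm <= _EPS:
        raise ValueError("X carries no covariance with y")
    w /= w_norm
    t = Xd @ w
    tt = float(t @ t)
    p_load = Xd.T @ t / tt
    c = float(y @ t) / tt

    # beta on the *original* scaled X: t = X (I - w_o1 p_o1') ... (I - w_ok p_ok') w
    v = w.copy()
    for j in range(extracted - 1, -1, -1):
        v -= W_o[:, j] * float(P_o[:, j] @ v)
    beta = c * v

    y_hat = t * c
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return {
        "w": w,
        "t": t,
        "p": p_load,
        "c": c,
        "W_o": W_o,
        "P_o": P_o,
        "T_o": T_o,
        "beta": beta,
        "n_ortho": extracted,
        "r2": 1.0 - ss_res / ss_tot,
        "y_hat": y_hat,
    }


# ---------------------------------------------------------------------------
# Fitted-model container and high-level fit
# ---------------------------------------------------------------------------


@dataclass
class OplsModel:
    """A fitted single-response OPLS model with its scaling parameters.

    ``n_components`` is the ``(1, n_ortho, 0)`` triple.  ``r2`` is computed
    on the scaled response; ``rmse`` on the original score scale with
    denominator n.  ``q2``/``press`` are attached when grouped
    cross-validation was run.
    """

    variables: list
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    w: np.ndarray
    t: np.ndarray
    p: np.ndarray
    c: float
    W_o: np.ndarray
    P_o: np.ndarray
    T_o: np.ndarray
    beta: np.ndarray
    n_components: tuple
    r2: float
    rmse: float
    q2: float | None = None
    press: float | None = None
    ss_tot_cv: float | None = None
    folds: np.ndarray | None = None
    attribute: str | None = None

    @property
    def n_ortho(self) -> int:
        return self.n_components[1]

    @property
    def notation(self) -> str:
        a, b, cc = self.n_components
        return f"{a} + {b} + {cc}"

    def _scale_x(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = set(self.variables) - set(X.columns)
            if missing:
                raise ValueError(
                    f"target matrix lacks model variables: {sorted(missing)[:5]}"
                )
            X = X[self.variables].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] != len(self.variables):
                raise ValueError("variable count mismatch")
        return (X - self.x_mean) / self.x_sd

    def predict_scaled(self, X) -> np.ndarray:
        """Predictions on the scaled-y scale (orthogonal filtering + t*c)."""
        return self._scale_x(X) @ self.beta

    def predict(self, X) -> np.ndarray:
        """Predictions on the original score scale."""
        return self.predict_scaled(X) * self.y_sd + self.y_mean

    def predictive_score(self, X) -> np.ndarray:
        """Predictive component score t for new data (orthogonal variation
        removed with the model's W_o/P_o)."""
        Xs = self._scale_x(X)
        for j in range(self.W_o.shape[1]):
            t_o = Xs @ self.W_o[:, j]
            Xs = Xs - np.outer(t_o, self.P_o[:, j])
        return Xs @ self.w

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "variables": list(map(str, self.variables)),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "c": self.c,
            "W_o": self.W_o.tolist(),
            "P_o": self.P_o.tolist(),
            "beta": self.beta.tolist(),
            "n_components": list(self.n_components),
            "r2": self.r2,
            "rmse": self.rmse,
            "q2": self.q2,
            "press": self.press,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OplsModel":
        W_o = np.asarray(d["W_o"], dtype=float)
        P_o = np.asarray(d["P_o"], dtype=float)
        if W_o.ndim == 1:
            W_o = W_o.reshape(len(d["variables"]), -1)
            P_o = P_o.reshape(len(d["variables"]), -1)
        return cls(
            variables=list(d["variables"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            y_mean=float(d["y_mean"]),
            y_sd=float(d["y_sd"]),
            w=np.asarray(d["w"], dtype=float),
            t=np.zeros(0),
            p=np.asarray(d["p"], dtype=float),
            c=float(d["c"]),
            W_o=W_o,
            P_o=P_o,
            T_o=np.zeros((0, W_o.shape[1])),
            beta=np.asarray(d["beta"], dtype=float),
            n_components=tuple(d["n_components"]),
            r2=float(d["r2"]),
            rmse=float(d["rmse"]),
            q2=d.get("q2"),
            press=d.get("press"),
            attribute=d.get("attribute"),
        )


def fit_model(
    X: pd.DataFrame,
    y,
    n_ortho: int = 0,
    attribute: str | None = None,
) -> OplsModel:
    """UV-scale raw data and fit OPLS with ``n_ortho`` orthogonal components.

    ``X`` is the raw injection x variable matrix, ``y`` the raw response per
    injection (sample-mean sensory scores broadcast over replicates).  Both X
    and y are autoscaled before fitting.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xs_df, xp = uv_scale(X)
    ym = float(y.mean())
    ysd = float(np.std(y, ddof=1))
    if ysd <= _EPS:
        raise ValueError("response is constant")
    ys = (y - ym) / ysd
    core = fit_opls(Xs_df.to_numpy(dtype=float), ys, n_ortho)
    y_hat_orig = core["y_hat"] * ysd + ym
    rmse = float(np.sqrt(np.mean((y - y_hat_orig) ** 2)))
    return OplsModel(
        variables=xp.variables,
        x_mean=xp.mean.to_numpy(dtype=float),
        x_sd=xp.sd.to_numpy(dtype=float),
        y_mean=ym,
        y_sd=ysd,
        w=core["w"],
        t=core["t"],
        p=core["p"],
        c=core["c"],
        W_o=core["W_o"],
        P_o=core["P_o"],
        T_o=core["T_o"],
        beta=core["beta"],
        n_components=(1, core["n_ortho"], 0),
        r2=core["r2"],
        rmse=rmse,
        attribute=attribute,
    )


# ---------------------------------------------------------------------------
# Grouped (replicate-aware) cross-validation
# ---------------------------------------------------------------------------


def make_grouped_folds(sample_ids, k: int = 7, seed: int = 0) -> np.ndarray:
    """Assign each injection to one of ``k`` folds, keeping every injection
    of a sample in the same fold.

    Samples are shuffled by ``seed`` and dealt round-robin, so fold sizes
    differ by at most one sample.  Returns an integer fold label per
    injection.
    """
    sample_ids = np.asarray(sample_ids)
    uniq = list(pd.unique(sample_ids))
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > len(uniq):
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    fold_of_sample = {uniq[idx]: i % k for i, idx in enumerate(order)}
    return np.asarray([fold_of_sample[s] for s in sample_ids], dtype=int)


class FoldCache:
    """Pre-scaled training/held-out X blocks for a fixed fold assignment.

    Scaling of X does not depend on y, so when the same folds are reused for
    many responses (orthogonal-component search, the 100 permutation refits)
    the per-fold autoscaled X matrices are computed once.
    """

    def __init__(self, X, folds: np.ndarray, scale_in_fold: bool = True):
        X = np.asarray(X, dtype=float)
        self.folds = np.asarray(folds, dtype=int)
        self.scale_in_fold = scale_in_fold
        self.blocks = []
        if not scale_in_fold:
            xm = X.mean(axis=0)
            xs = X.std(axis=0, ddof=1)
            keep = xs > _EPS
            Xg = (X[:, keep] - xm[keep]) / xs[keep]
        for f in np.unique(self.folds):
            train = self.folds != f
            test = ~train
            if scale_in_fold:
                xm = X[train].mean(axis=0)
                xs = X[train].std(axis=0, ddof=1)
                keep = xs > _EPS
                Xtr = (X[train][:, keep] - xm[keep]) / xs[keep]
                Xte = (X[test][:, keep] - xm[keep]) / xs[keep]
            else:
                Xtr = Xg[train]
                Xte = Xg[test]
            self.blocks.append((train, test, Xtr, Xte))

    def q2(self, y, n_ortho: int) -> tuple[float, float]:
        """(Q2, PRESS) for a response vector using the cached folds."""
        y = np.asarray(y, dtype=float).ravel()
        press = 0.0
        ss = 0.0
        for train, test, Xtr, Xte in self.blocks:
            if self.scale_in_fold:
                ym = float(y[train].mean())
                ysd = float(np.std(y[train], ddof=1))
            else:
                ym = float(y.mean())
                ysd = float(np.std(y, ddof=1))
            if ysd <= _EPS:
                raise ValueError("response is constant within a training fold")
            core = fit_opls(Xtr, (y[train] - ym) / ysd, n_ortho)
            yte = (y[test] - ym) / ysd
            y_hat = Xte @ core["beta"]
            press += float(((yte - y_hat) ** 2).sum())
            ss += float((yte**2).sum())
        return 1.0 - press / ss, press

    def sstot(self, y) -> float:
        """Total SS of held-out scaled y (the Q2 denominator)."""
        y = np.asarray(y, dtype=float).ravel()
        ss = 0.0
        for train, test, _, _ in self.blocks:
            if self.scale_in_fold:
                ym = float(y[train].mean())
                ysd = float(np.std(y[train], ddof=1))
            else:
                ym, ysd = float(y.mean()), float(np.std(y, ddof=1))
            ss += float((((y[test] - ym) / ysd) ** 2).sum())
        return ss


def grouped_q2(
    X,
    y,
    n_ortho: int,
    folds: np.ndarray,
    scale_in_fold: bool = True,
) -> tuple[float, float]:
    """Cross-validated Q2 = 1 - PRESS/SS over grouped folds.

    For each fold, scaling parameters and the OPLS model are estimated on
    the training injections only; held-out injections (their y scaled by the
    training fold's parameters) contribute squared prediction errors to
    PRESS and squared deviations to the total SS.  With
    ``scale_in_fold=False`` the data are scaled once globally before the CV
    loop, reproducing the convention of commercial chemometrics software.
    """
    return FoldCache(X, folds, scale_in_fold=scale_in_fold).q2(y, n_ortho)


def cv_sstot(y, folds, scale_in_fold: bool = True) -> float:
    """Total SS of held-out scaled y accumulated across folds (the
    denominator of Q2), needed by CV-ANOVA."""
    y = np.asarray(y, dtype=float).ravel()
    folds = np.asarray(folds, dtype=int)
    ss = 0.0
    for f in np.unique(folds):
        train = folds != f
        if scale_in_fold:
            ym, ysd = float(y[train].mean()), float(np.std(y[train], ddof=1))
        else:
            ym, ysd = float(y.mean()), float(np.std(y, ddof=1))
        ss += float((((y[~train] - ym) / ysd) ** 2).sum())
    return ss
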