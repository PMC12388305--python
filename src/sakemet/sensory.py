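"""Sensory-panel QC: box-whisker outlier removal, ANOVA gate, sample means.

Quality control of QDA data follows the standard box-and-whisker
convention: per (sample, attribute) group, quartiles by linear
interpolation, whiskers anchored at the most extreme observations within
1.5 * IQR of the quartiles, and records strictly outside the whiskers
removed in a single pass.  Attributes are then gated by a one-way
fixed-effects ANOVA with sample as the factor: attributes that do not
discriminate between samples (p >= alpha) are excluded from modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SensoryPanel

__all__ = [
    "remove_outliers",
    "AnovaResult",
    "anova_gate",
    "anova_all",
    "SensoryMeans",
    "sample_means",
]


def tukey_whiskers(scores: np.ndarray) -> tuple[float, float]:
    """(lower, upper) whiskers: extreme observations within 1.5*IQR fences."""
    q1, q3 = np.quantile(scores, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = scores[(scores >= lo_fence) & (scores <= hi_fence)]
    return float(inside.min()), float(inside.max())


def remove_outliers(
    panel: SensoryPanel, min_group: int = 4
) -> tuple[SensoryPanel, pd.DataFrame]:
    """Single-pass box-whisker outlier removal per (sample, attribute).

    Panelists and rounds are pooled within a group.  Groups smaller than
    ``min_group`` pass through untouched (quartiles are not meaningful).
    Returns the cleaned panel and the removed records.
    """
    rec = panel.records
    drop = np.zeros(len(rec), dtype=bool)
    for _, idx in rec.groupby(["sample_id", "attribute"]).indices.items():
        if len(idx) < min_group:
            continue
        scores = rec["score"].to_numpy()[idx]
        lo, hi = tukey_whiskers(scores)
        drop[idx] = (scores < lo) | (scores > hi)
    removed = rec.loc[drop].reset_index(drop=True)
    cleaned = SensoryPanel(
        records=rec.loc[~drop].reset_index(drop=True), scales=dict(panel.scales)
    )
    return cleaned, removed


@dataclass
class AnovaResult:
    attribute: str
    f_value: float
    p_value: float
    pass_flag: bool
    df_between: int
    df_within: int


def anova_gate(panel: SensoryPanel, attribute: str, alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA of post-QC scores with sample as factor.

    ``pass_flag`` is True when p < alpha, i.e. the attribute discriminates
    between samples and is kept for modeling.  Zero within-group variance
    with non-zero between-group variance yields F = inf, p = 0; identical
    group means yield F = 0, p = 1.
    """
    sub = panel.records.loc[panel.records["attribute"] == attribute]
    groups = [g["score"].to_numpy() for _, g in sub.groupby("sample_id")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 samples with >= 2 scores each")
    n = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_within <= 1e-12:
        f = np.inf if ss_between > 1e-12 else 0.0
        p = 0.0 if ss_between > 1e-12 else 1.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        attribute=attribute,
        f_value=float(f),
        p_value=p,
        pass_flag=bool(p < alpha),
        df_between=df_b,
        df_within=df_w,
    )


def anova_all(panel: SensoryPanel, alpha: float = 0.05) -> list[AnovaResult]:
    return [anova_gate(panel, a, alpha) for a in panel.attributes]


@dataclass
class SensoryMeans:
    """Sample x attribute mean scores with per-cell record counts."""

    means: pd.DataFrame
    n_used: pd.DataFrame

    def require_complete(self, attributes=None) -> None:
        cols = list(attributes) if attributes is not None else list(self.means.columns)
        bad = self.means[cols].isna()
        if bad.to_numpy().any():
            cells = [
                (s, a) for s in self.means.index for a in cols if bad.at[s, a]
            ]
            raise ValueError(f"missing sensory cells: {cells[:5]}")


def sample_means(panel: SensoryPanel) -> SensoryMeans:
    """Arithmetic mean score per (sample, attribute) over remaining records."""
    g = panel.records.groupby(["sample_id", "attribute"])["score"]
    means = g.mean().unstack("attribute")
    n_used = g.size().unstack("attribute").fillna(0).astype(int)
    order = panel.sample_ids
    return SensoryMeans(means=means.loc[order], n_used=n_used.loc[order])
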