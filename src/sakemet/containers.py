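"""Core data containers: LC-MS peak tables, compound libraries, sensory panels.

A :class:`PeakTable` holds the injection-by-peak intensity matrix exported by
peak-picking software, together with per-injection metadata (which sample an
injection belongs to, replicate index) and per-peak metadata (retention time
in minutes, mass-to-charge ratio in daltons).  A :class:`SensoryPanel` holds
long-format quantitative descriptive analysis (QDA) records: one score per
(panelist, sample, attribute, round).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PeakTable",
    "AnnotationLibrary",
    "SensoryPanel",
]

_HEADER_RE = re.compile(r"^(?P<pid>[^@]+)@(?P<rt>[0-9.eE+-]+)/(?P<mz>[0-9.eE+-]+)$")


@dataclass
class PeakTable:
    """Injection x peak intensity matrix with metadata.

    Parameters
    ----------
    intensities : DataFrame
        Rows are injections (positional index), columns are peak identifiers.
        Values are non-negative intensities in arbitrary units.
    injections : DataFrame
        One row per injection with columns ``sample_id`` and ``replicate``.
    peak_meta : DataFrame
        Indexed by peak identifier with columns ``rt`` (minutes) and ``mz``
        (daltons).
    """

    intensities: pd.DataFrame
    injections: pd.DataFrame
    peak_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.intensities) != len(self.injections):
            raise ValueError("intensities and injections row counts differ")
        if not self.intensities.columns.equals(self.peak_meta.index):
            # allow same set, different order
            if set(self.intensities.columns) != set(self.peak_meta.index):
                raise ValueError("peak_meta does not cover intensity columns")
            self.peak_meta = self.peak_meta.loc[self.intensities.columns]
        if self.peak_meta.index.has_duplicates:
            raise ValueError("peak identifiers must be unique")
        self.intensities = self.intensities.reset_index(drop=True)
        self.injections = self.injections.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def peak_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def sample_ids(self) -> list[str]:
        """Distinct sample identifiers in order of first appearance."""
        return list(pd.unique(self.injections["sample_id"]))

    @property
    def n_peaks(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        """Raise if invariants are broken (negative intensities, uneven
        replicate counts, non-positive rt/mz)."""
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities")
        counts = self.injections.groupby("sample_id").size()
        if counts.nunique() > 1:
            raise ValueError("unequal replicate counts across samples")
        meta = self.peak_meta.dropna()
        if (meta[["rt", "mz"]].to_numpy() <= 0).any():
            raise ValueError("non-positive rt or mz in peak metadata")

    # -- transforms ------------------------------------------------------
    def sample_means(self) -> pd.DataFrame:
        """Mean intensity over replicate injections, sample x peak."""
        grouped = self.intensities.groupby(self.injections["sample_id"].values).mean()
        return grouped.loc[self.sample_ids]

    def subset_peaks(self, peak_ids) -> "PeakTable":
        peak_ids = list(peak_ids)
        return PeakTable(
            intensities=self.intensities[peak_ids].copy(),
            injections=self.injections.copy(),
            peak_meta=self.peak_meta.loc[peak_ids].copy(),
        )

    def subset_samples(self, sample_ids) -> "PeakTable":
        keep = self.injections["sample_id"].isin(set(sample_ids)).to_numpy()
        return PeakTable(
            intensities=self.intensities.loc[keep].reset_index(drop=True),
            injections=self.injections.loc[keep].reset_index(drop=True),
            peak_meta=self.peak_meta.copy(),
        )

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path, meta_path=None) -> None:
        """Write the wide CSV layout: ``sample_id, replicate, <peak columns>``.

        Peak column headers encode metadata as ``id@rt/mz``; if ``meta_path``
        is given a side-car CSV of peak metadata is written as well.
        """
        wide = self.injections[["sample_id", "replicate"]].copy()
        headers = [
            f"{pid}@{self.peak_meta.at[pid, 'rt']:.4f}/{self.peak_meta.at[pid, 'mz']:.4f}"
            if np.isfinite(self.peak_meta.at[pid, "rt"])
            else str(pid)
            for pid in self.peak_ids
        ]
        body = self.intensities.copy()
        body.columns = headers
        pd.concat([wide, body], axis=1).to_csv(path, index=False)
        if meta_path is not None:
            self.peak_meta.rename_axis("peak_id").to_csv(meta_path)

    @classmethod
    def from_csv(cls, path, meta_path=None) -> "PeakTable":
        df = pd.read_csv(path)
        if not {"sample_id", "replicate"} <= set(df.columns):
            raise ValueError("peak table CSV must start with sample_id, replicate")
        injections = df[["sample_id", "replicate"]].copy()
        body = df.drop(columns=["sample_id", "replicate"])
        # undetected peaks are exported as empty cells; read them as zero
        body = body.fillna(0.0).astype(float)
        ids, rts, mzs = [], [], []
        for col in body.columns:
            m = _HEADER_RE.match(str(col))
            if m:
                ids.append(m.group("pid"))
                rts.append(float(m.group("rt")))
                mzs.append(float(m.group("mz")))
            else:
                ids.append(str(col))
                rts.append(np.nan)
                mzs.append(np.nan)
        body.columns = ids
        meta = pd.DataFrame({"rt": rts, "mz": mzs}, index=pd.Index(ids, name="peak_id"))
        if meta_path is not None:
            side = pd.read_csv(meta_path, index_col=0)
            meta.loc[side.index, ["rt", "mz"]] = side[["rt", "mz"]]
        return cls(intensities=body, injections=injections, peak_meta=meta)


@dataclass
class AnnotationLibrary:
    """In-house compound library used to annotate peaks.

    ``entries`` has columns ``compound_name``, ``rt`` (minutes), ``mz``
    (daltons) and ``compound_group``.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"compound_name", "rt", "mz", "compound_group"}
        if not required <= set(self.entries.columns):
            raise ValueError(f"library requires columns {sorted(required)}")
        if (self.entries[["rt", "mz"]].to_numpy() <= 0).any():
            raise ValueError("library rt and mz must be positive")
        self.entries = self.entries.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path) -> None:
        out = self.entries.rename(columns={"rt": "rt_min", "compound_group": "group"})
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AnnotationLibrary":
        df = pd.read_csv(path)
        df = df.rename(columns={"rt_min": "rt", "group": "compound_group"})
        return cls(entries=df)


@dataclass
class SensoryPanel:
    """Long-format QDA panel scores.

    ``records`` columns: ``panelist_id``, ``sample_id``, ``attribute``,
    ``round``, ``score``.  ``scales`` maps each attribute to its
    ``(scale_min, scale_max)`` bounds (e.g. the 0-5 line scale used in QDA).
    """

    records: pd.DataFrame
    scales: dict = field(default_factory=dict)

    _COLS = ["panelist_id", "sample_id", "attribute", "round", "score"]

    def __post_init__(self) -> None:
        missing = set(self._COLS) - set(self.records.columns)
        if missing:
            raise ValueError(f"panel records missing columns {sorted(missing)}")
        self.records = self.records[self._COLS].reset_index(drop=True)

    @property
    def attributes(self) -> list[str]:
        return list(pd.unique(self.records["attribute"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.records["sample_id"]))

    def validate(self, allow_out_of_scale: bool = False) -> None:
        for attr, (lo, hi) in self.scales.items():
            scores = self.records.loc[self.records["attribute"] == attr, "score"]
            if not allow_out_of_scale and ((scores < lo) | (scores > hi)).any():
                raise ValueError(f"scores outside scale for attribute {attr!r}")

    def subset_samples(self, sample_ids) -> "SensoryPanel":
        keep = self.records["sample_id"].isin(set(sample_ids))
        return SensoryPanel(
            records=self.records.loc[keep].reset_index(drop=True),
            scales=dict(self.scales),
        )

    def subset_attributes(self, attributes) -> "SensoryPanel":
        keep = self.records["attribute"].isin(set(attributes))
        return SensoryPanel(
            records=self.records.loc[keep].reset_index(drop=True),
            scales={a: s for a, s in self.scales.items() if a in set(attributes)},
        )

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path, scales_path=None) -> None:
        self.records.to_csv(path, index=False)
        if scales_path is not None:
            with open(scales_path, "w") as fh:
                yaml.safe_dump(
                    {a: [float(lo), float(hi)] for a, (lo, hi) in self.scales.items()},
                    fh,
                )

    @classmethod
    def from_csv(cls, path, scales_path=None) -> "SensoryPanel":
        records = pd.read_csv(path)
        scales = {}
        if scales_path is not None:
            with open(scales_path) as fh:
                raw = yaml.safe_load(fh) or {}
            scales = {a: (float(v[0]), float(v[1])) for a, v in raw.items()}
        return cls(records=records, scales=scales)
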