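"""Synthetic sake-metabolome / sensory-panel generator with known ground truth.

The generator emulates the data structure the analysis assumes: tens of
samples injected in triplicate on an LC-MS instrument, a few hundred
retained peaks plus peaks destined for the zero-maximum and replicate-CV
filters, and a QDA panel scoring each sample on bounded line scales over
several rounds.

Peak intensities are log-normal per peak per sample.  Between-sample
variation follows a latent-factor model: one global "strength" factor
loading on every informative peak plus block factors shared by groups of
peaks, mimicking the strong mutual correlation of real metabolome peaks
(co-regulated metabolites, adducts and in-source fragments of the same
compound).  Replicate noise is multiplicative and constructed so that the
empirical replicate CV of each (peak, sample) cell equals a drawn target
below the 10% filter threshold; planted high-CV peaks get one sample whose
replicate CV is constructed to be at or above the threshold.

Each sensory attribute is a sparse linear function of the standardized
sample-mean intensities of its driver peaks, scaled by ``effect_size``,
plus a panelist bias and per-round noise.  Noise terms are uniform
(bounded), which keeps clean scores strictly inside the Tukey whiskers of
their (sample, attribute) group, so the planted outliers — displaced beyond
the group extreme by 3*IQR + 1 — are exactly the records a box-whisker QC
should remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import AnnotationLibrary, PeakTable, SensoryPanel

__all__ = [
    "AttributeSpec",
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "split_years",
]

_COMPOUND_GROUPS = [
    "monosaccharide",
    "disaccharide",
    "amino acid",
    "dipeptide",
    "organic acid",
    "sugar alcohol",
    "amine",
    "alcohol",
    "ester",
]


@dataclass
class AttributeSpec:
    """One sensory attribute: scale bounds, driver count, signal and noise."""

    name: str
    scale_min: float = 0.0
    scale_max: float = 5.0
    n_driver_peaks: int = 5
    effect_size: float = 1.0
    noise_sd: float = 0.3


def default_attributes() -> list[AttributeSpec]:
    """Five QDA attributes typical of a sake panel (taste, aroma, overall)."""
    return [
        AttributeSpec("sweetness"),
        AttributeSpec("sourness"),
        AttributeSpec("fruity aroma"),
        AttributeSpec("body"),
        AttributeSpec("overall quality", scale_min=1.0, scale_max=5.0),
    ]


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the larger of the two brewing-year designs emulated
    here: 40 samples in triplicate, 430 retained peaks (plus 5 peaks planted
    for the zero-maximum filter and 20 for the replicate-CV filter), a
    26-person panel scoring in 3 rounds.
    """

    n_samples: int = 40
    n_replicates: int = 3
    n_informative_peaks: int = 430
    n_zero_max_peaks: int = 5
    n_high_cv_peaks: int = 20
    n_panelists: int = 26
    n_rounds: int = 3
    attributes: list[AttributeSpec] = field(default_factory=default_attributes)
    replicate_cv_target: float = 5.0  # percent; retained peaks stay below 10
    outlier_rate: float = 0.05
    panelist_bias_sd: float = 0.52
    seed: int = 0
    # latent correlation structure of the informative peaks
    n_block_factors: int = 8
    global_factor_var: float = 0.25
    block_factor_var: float = 0.70
    uniqueness_var: float = 0.05
    # annotation library
    library_fraction: float = 0.28
    n_library_decoys: int = 40

    def validate(self) -> None:
        counts = [
            self.n_samples,
            self.n_replicates,
            self.n_informative_peaks,
            self.n_panelists,
            self.n_rounds,
            self.n_block_factors,
        ]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.n_zero_max_peaks < 0 or self.n_high_cv_peaks < 0:
            raise ValueError("planted peak counts must be >= 0")
        if not 0 <= self.outlier_rate < 0.5:
            raise ValueError("outlier_rate must be in [0, 0.5)")
        if self.replicate_cv_target <= 0:
            raise ValueError("replicate_cv_target must be positive")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates for a CV filter to apply")
        if self.n_rounds < 3:
            raise ValueError("panel sessions use at least 3 rounds")
        var_sum = self.global_factor_var + self.block_factor_var + self.uniqueness_var
        if not np.isclose(var_sum, 1.0, atol=0.05):
            raise ValueError("factor variances should sum to ~1")
        for a in self.attributes:
            if a.scale_min >= a.scale_max:
                raise ValueError(f"bad scale for attribute {a.name!r}")
            if a.n_driver_peaks > self.n_informative_peaks:
                raise ValueError("drivers exceed available informative peaks")
            margin = self.panelist_bias_sd + np.sqrt(3.0) * a.noise_sd
            if a.scale_min + margin >= a.scale_max - margin:
                raise ValueError(
                    f"attribute {a.name!r}: noise too large for its scale"
                )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["attributes"] = [AttributeSpec(**a) for a in d.get("attributes", [])]
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure the acceptance checks recover.

    ``driver_map``: attribute -> {peak_id: signed weight};
    ``injected_outliers``: set of (panelist_id, sample_id, attribute, round);
    ``planted_filter_peaks``: filter name -> set of peak ids;
    ``informative_peaks``: peaks that should survive both filters.
    """

    driver_map: dict
    injected_outliers: set
    planted_filter_peaks: dict
    informative_peaks: frozenset

    def to_json(self, path) -> None:
        payload = {
            "driver_map": {
                a: {p: float(w) for p, w in m.items()}
                for a, m in self.driver_map.items()
            },
            "injected_outliers": sorted(list(t) for t in self.injected_outliers),
            "planted_filter_peaks": {
                k: sorted(v) for k, v in self.planted_filter_peaks.items()
            },
            "informative_peaks": sorted(self.informative_peaks),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class SyntheticDataset:
    peaks: PeakTable
    library: AnnotationLibrary
    panel: SensoryPanel
    truth: GroundTruth
    config: GeneratorConfig

    def __iter__(self):
        # allow `table, lib, panel, truth = generate_dataset(cfg)`
        return iter((self.peaks, self.library, self.panel, self.truth))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _replicate_noise(rng, shape_cells: int, n_rep: int, cv: np.ndarray) -> np.ndarray:
    """Multiplicative deviations (1 + cv * e) whose empirical CV per cell is
    exactly ``cv``: Gaussian draws are centered and rescaled to unit sample
    SD within each replicate set."""
    eps = rng.standard_normal((shape_cells, n_rep))
    eps -= eps.mean(axis=1, keepdims=True)
    sd = eps.std(axis=1, ddof=1)
    # degenerate draws (prob ~0) regenerated deterministically from the mean
    sd[sd <= 0] = 1.0
    eps /= sd[:, None]
    return 1.0 + cv[:, None] * eps


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a peak table, annotation library, sensory panel and the
    ground truth for one synthetic brewing year."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    (
        s_structure,
        s_intensity,
        s_replicate,
        s_sensory,
        s_outlier,
        s_library,
    ) = root.spawn(6)
    rng_struct = np.random.default_rng(s_structure)
    rng_int = np.random.default_rng(s_intensity)
    rng_rep = np.random.default_rng(s_replicate)
    rng_sens = np.random.default_rng(s_sensory)
    rng_out = np.random.default_rng(s_outlier)
    rng_lib = np.random.default_rng(s_library)

    n_s = config.n_samples
    n_r = config.n_replicates
    n_inf = config.n_informative_peaks
    n_total = n_inf + config.n_zero_max_peaks + config.n_high_cv_peaks

    # ---- peak identities and metadata ---------------------------------
    order = rng_struct.permutation(n_total)
    peak_ids = np.array([f"P{i + 1:04d}" for i in range(n_total)])
    roles = np.array(
        ["informative"] * n_inf
        + ["zero_max"] * config.n_zero_max_peaks
        + ["high_cv"] * config.n_high_cv_peaks
    )[order]
    rt = rng_struct.uniform(0.5, 28.0, size=n_total)
    mz = rng_struct.uniform(80.0, 800.0, size=n_total)
    peak_meta = pd.DataFrame(
        {"rt": rt, "mz": mz}, index=pd.Index(peak_ids, name="peak_id")
    )
    inf_idx = np.flatnonzero(roles == "informative")
    zero_idx = np.flatnonzero(roles == "zero_max")
    high_idx = np.flatnonzero(roles == "high_cv")

    # ---- between-sample structure (latent factors, log scale) ---------
    lam_g = np.sqrt(config.global_factor_var)
    lam_b = np.sqrt(config.block_factor_var)
    tau = np.sqrt(config.uniqueness_var)
    block_of = rng_struct.integers(0, config.n_block_factors, size=n_inf)
    F_global = rng_int.standard_normal(n_s)
    F_block = rng_int.standard_normal((n_s, config.n_block_factors))
    z = np.empty((n_s, n_total))
    z[:, inf_idx] = (
        lam_g * F_global[:, None]
        + lam_b * F_block[:, block_of]
        + tau * rng_int.standard_normal((n_s, n_inf))
    )
    n_noise = len(zero_idx) + len(high_idx)
    z[:, np.concatenate([zero_idx, high_idx])] = rng_int.standard_normal(
        (n_s, n_noise)
    )

    mu = rng_int.uniform(3.0, 6.0, size=n_total)  # log10 location, a.u.
    sigma = rng_int.uniform(0.10, 0.30, size=n_total)  # log10 spread
    sample_level = 10.0 ** (mu[None, :] + sigma[None, :] * z)

    # ---- replicate noise with exact empirical CV -----------------------
    t_cv = config.replicate_cv_target / 100.0
    cv = rng_rep.uniform(0.4 * t_cv, min(1.6 * t_cv, 0.095), size=(n_s, n_total))
    # planted high-CV peaks: one sample each gets CV at/above the threshold
    bad_sample = rng_rep.integers(0, n_s, size=len(high_idx))
    cv[bad_sample, high_idx] = rng_rep.uniform(0.12, 0.25, size=len(high_idx))

    dev = _replicate_noise(rng_rep, n_s * n_total, n_r, cv.reshape(-1))
    intens = sample_level.reshape(-1, 1) * dev  # (n_s*n_total, n_r)
    intens = intens.reshape(n_s, n_total, n_r).transpose(0, 2, 1)  # s, r, p
    intens = intens.reshape(n_s * n_r, n_total)
    intens[:, zero_idx] = 0.0

    sample_ids = np.array([f"S{i + 1:02d}" for i in range(n_s)])
    injections = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_r),
            "replicate": np.tile(np.arange(1, n_r + 1), n_s),
        }
    )
    table = PeakTable(
        intensities=pd.DataFrame(intens, columns=peak_ids),
        injections=injections,
        peak_meta=peak_meta,
    )

    # ---- sensory panel --------------------------------------------------
    informative_ids = peak_ids[inf_idx]
    sample_means_raw = sample_level[:, inf_idx]  # expectations of replicates
    col_mean = sample_means_raw.mean(axis=0)
    col_sd = sample_means_raw.std(axis=0, ddof=1)
    x_std = (sample_means_raw - col_mean) / col_sd  # standardized drivers

    driver_map: dict = {}
    expectations = {}
    for ai, attr in enumerate(config.attributes):
        block = ai % config.n_block_factors
        pool = np.flatnonzero(block_of == block)
        if len(pool) < attr.n_driver_peaks:
            pool = np.arange(n_inf)
        chosen = rng_sens.choice(pool, size=attr.n_driver_peaks, replace=False)
        sign = float(rng_sens.choice([-1.0, 1.0]))
        weights = sign * rng_sens.uniform(0.8, 1.2, size=attr.n_driver_peaks)
        driver_map[attr.name] = {
            str(informative_ids[j]): float(wj) for j, wj in zip(chosen, weights)
        }
        y0 = x_std[:, chosen] @ weights
        if attr.effect_size > 0 and y0.std(ddof=1) > 0:
            y0 = (y0 - y0.mean()) / y0.std(ddof=1)
        else:
            y0 = np.zeros(n_s)
        mid = 0.5 * (attr.scale_min + attr.scale_max)
        # largest possible clean deviation: bias magnitude + noise half-width
        margin = config.panelist_bias_sd + np.sqrt(3.0) * attr.noise_sd
        # signal amplitude adapted to the interior of the scale so that
        # +-2 sd of the driver signal fits without clipping the expectation
        headroom = 0.5 * (attr.scale_max - attr.scale_min) - margin
        expect = np.clip(
            mid + attr.effect_size * 0.5 * headroom * y0,
            attr.scale_min + margin,
            attr.scale_max - margin,
        )
        expectations[attr.name] = expect

    panelist_ids = np.array([f"J{i + 1:02d}" for i in range(config.n_panelists)])
    half = np.sqrt(3.0)
    records = []
    injected_outliers: set = set()
    for attr in config.attributes:
        expect = expectations[attr.name]
        # bimodal panelist bias (balanced strict/lenient halves, sd equal to
        # panelist_bias_sd): keeps each (sample, attribute) score group
        # flat-topped and bounded, so its Tukey fences sit far outside the
        # clean-score support and only planted outliers cross them
        signs = np.ones(config.n_panelists)
        signs[: config.n_panelists // 2] = -1.0
        bias = config.panelist_bias_sd * rng_sens.permutation(signs)
        noise = rng_sens.uniform(
            -half * attr.noise_sd,
            half * attr.noise_sd,
            size=(config.n_panelists, n_s, config.n_rounds),
        )
        scores = expect[None, :, None] + bias[:, None, None] + noise
        scores = np.clip(scores, attr.scale_min, attr.scale_max)  # bounded scale

        out_mask = rng_out.random(scores.shape) < config.outlier_rate
        for s in range(n_s):
            hits = np.argwhere(out_mask[:, s, :])
            if len(hits) == 0:
                continue
            clean = scores[:, s, :]
            q1, q3 = np.quantile(clean, [0.25, 0.75])
            iqr = q3 - q1
            shift = 3.0 * iqr + 1.0
            gmin, gmax = clean.min(), clean.max()
            for p_i, r_i in hits:
                if rng_out.random() < 0.5:
                    scores[p_i, s, r_i] = gmax + shift
                else:
                    scores[p_i, s, r_i] = gmin - shift
                injected_outliers.add(
                    (
                        str(panelist_ids[p_i]),
                        str(sample_ids[s]),
                        attr.name,
                        int(r_i + 1),
                    )
                )

        p_idx, s_idx, r_idx = np.meshgrid(
            np.arange(config.n_panelists),
            np.arange(n_s),
            np.arange(config.n_rounds),
            indexing="ij",
        )
        records.append(
            pd.DataFrame(
                {
                    "panelist_id": panelist_ids[p_idx.ravel()],
                    "sample_id": sample_ids[s_idx.ravel()],
                    "attribute": attr.name,
                    "round": r_idx.ravel() + 1,
                    "score": scores.ravel(),
                }
            )
        )
    panel = SensoryPanel(
        records=pd.concat(records, ignore_index=True),
        scales={a.name: (a.scale_min, a.scale_max) for a in config.attributes},
    )

    # ---- annotation library ---------------------------------------------
    n_annot = int(round(config.library_fraction * n_inf))
    annotated = rng_lib.choice(inf_idx, size=n_annot, replace=False)
    entries = pd.DataFrame(
        {
            "compound_name": [f"compound_{i + 1:03d}" for i in range(n_annot)],
            "rt": rt[annotated] + rng_lib.uniform(-0.06, 0.06, size=n_annot),
            "mz": mz[annotated] + rng_lib.uniform(-0.005, 0.005, size=n_annot),
            "compound_group": rng_lib.choice(_COMPOUND_GROUPS, size=n_annot),
        }
    )
    decoys = pd.DataFrame(
        {
            "compound_name": [
                f"decoy_{i + 1:03d}" for i in range(config.n_library_decoys)
            ],
            "rt": rng_lib.uniform(0.5, 28.0, size=config.n_library_decoys),
            "mz": rng_lib.uniform(80.0, 800.0, size=config.n_library_decoys),
            "compound_group": rng_lib.choice(
                _COMPOUND_GROUPS, size=config.n_library_decoys
            ),
        }
    )
    library = AnnotationLibrary(entries=pd.concat([entries, decoys], ignore_index=True))

    truth = GroundTruth(
        driver_map=driver_map,
        injected_outliers=injected_outliers,
        planted_filter_peaks={
            "zero_max": set(map(str, peak_ids[zero_idx])),
            "high_cv": set(map(str, peak_ids[high_idx])),
        },
        informative_peaks=frozenset(map(str, informative_ids)),
    )
    return SyntheticDataset(
        peaks=table, library=library, panel=panel, truth=truth, config=config
    )


def split_years(
    dataset: SyntheticDataset, fraction: float, seed: int = 0
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Split samples into two disjoint "years" that share the generative
    driver weights; each part keeps its own (independently drawn) sensory
    noise.  ``fraction`` is the share of samples in the first part."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    samples = np.asarray(dataset.peaks.sample_ids)
    n_a = int(round(fraction * len(samples)))
    if n_a < 8 or len(samples) - n_a < 8:
        raise ValueError("both parts need at least 8 samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    set_a = set(samples[order[:n_a]])
    set_b = set(samples[order[n_a:]])

    def _part(keep: set) -> SyntheticDataset:
        return SyntheticDataset(
            peaks=dataset.peaks.subset_samples(keep),
            library=dataset.library,
            panel=dataset.panel.subset_samples(keep),
            truth=GroundTruth(
                driver_map=dataset.truth.driver_map,  # shared object
                injected_outliers={
                    t for t in dataset.truth.injected_outliers if t[1] in keep
                },
                planted_filter_peaks=dataset.truth.planted_filter_peaks,
                informative_peaks=dataset.truth.informative_peaks,
            ),
            config=dataset.config,
        )

    return _part(set_a), _part(set_b)
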