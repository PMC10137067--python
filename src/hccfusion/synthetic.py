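"""Synthetic radiogenomics cohorts with planted two-subtype structure.

The generator emulates the statistical structure the analysis assumes,
in place of downloaded imaging/expression cohorts:

* a multi-view feature table (4 views x 100 registry features) of standard
  normal noise, with mean shifts on a fraction of the texture features that
  differ between two latent subtypes;
* negative-binomial expression counts with an "immune" module elevated in
  subtype 1 and a "cell_cycle" module elevated in subtype 2;
* exponential survival with a planted subtype-2 log-hazard (default
  ln(1/0.146), the hazard-ratio magnitude reported for the discovery
  cohort) and uniform administrative censoring;
* AFP-like (log-normal, higher in subtype 2) and grade-like (ordinal,
  shifted higher in subtype 2) clinical covariates.

Optionally, 3D image volumes with ellipsoidal lesions on a liver-like
background can be rendered so the feature extractor itself can be
exercised: subtype-1 lesions carry low-intensity heterogeneous noise
(high texture contrast), subtype-2 lesions high-intensity smooth
gradients (low contrast), with a phase-specific intensity offset.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .radiomics.registry import MultiViewFeatureTable, feature_registry
from .radiomics.voi import VIEW_TYPES, ImageVolume, VOIMask
from .survival import SurvivalData

DEFAULT_MODULES = (
    ("immune", 100, 1, 2.0),
    ("cell_cycle", 80, 2, 2.0),
)


class ConfigError(ValueError):
    pass


class GeometryError(ValueError):
    pass


@dataclasses.dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the discovery-cohort conditions: 30 patients split
    16/14 between subtypes, and a subtype-2 log-hazard of ln(1/0.146).
    """

    n_patients: int = 30
    seed: int = 0
    subtype_proportions: Sequence[float] = (16 / 30, 14 / 30)
    texture_effect_sd: float = 1.5
    affected_feature_fraction: float = 0.3
    n_genes: int = 2000
    module_spec: Sequence[tuple[str, int, int, float]] = DEFAULT_MODULES
    nb_dispersion: float = 0.1
    subtype2_log_hazard: float = math.log(1.0 / 0.146)
    censoring_rate: float = 0.3
    median_survival_days: float = 900.0
    make_volumes: bool = False
    #: seed of the per-gene baseline-abundance catalog.  Kept separate from
    #: ``seed`` so independent cohorts (discovery vs validation) share the
    #: same gene baselines, as paired real cohorts measured on the same
    #: transcriptome do.
    gene_baseline_seed: int = 777

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigError("subtype_proportions must lie on the simplex")
        if self.texture_effect_sd < 0:
            raise ConfigError("texture_effect_sd must be >= 0")
        if not (0 <= self.affected_feature_fraction <= 1):
            raise ConfigError("affected_feature_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ConfigError("censoring_rate must be in [0, 1)")
        for name, size, subtype, _effect in self.module_spec:
            if size < 1:
                raise ConfigError(f"module {name} must have size >= 1")
            if subtype not in (1, 2):
                raise ConfigError("module subtype must be 1 or 2")
        if sum(m[1] for m in self.module_spec) > self.n_genes:
            raise ConfigError("module sizes exceed n_genes")


@dataclasses.dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    features: MultiViewFeatureTable
    counts: pd.DataFrame  # genes x patients, non-negative integers
    survival: SurvivalData
    clinical: pd.DataFrame  # patient_id, afp, grade
    truth: dict

    @property
    def patient_ids(self) -> np.ndarray:
        return np.asarray(self.features.patients)

    @property
    def subtype_labels(self) -> np.ndarray:
        return np.asarray(self.truth["subtype"])

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.features.write_csv(out / "features.csv")
        self.counts.to_csv(out / "counts.tsv", sep="\t")
        self.survival.to_frame().to_csv(out / "survival.csv", index=False)
        self.clinical.to_csv(out / "clinical.csv", index=False)
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.truth.items()
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


def _censor_horizon(rate: float, hazards: np.ndarray) -> float:
    """Upper bound of the uniform censoring window giving ~``rate`` censoring.

    For exponential event time with rate L and C ~ U(0, c),
    P(censored) = (1 - exp(-L c)) / (L c); solve for c by bisection on the
    cohort average.
    """
    if rate <= 0:
        return np.inf

    def mean_censored(c: float) -> float:
        return float(np.mean((1.0 - np.exp(-hazards * c)) / (hazards * c)))

    lo, hi = 1e-6, 1e9
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if mean_censored(mid) > rate:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort under ``config``; identical seeds give identical data."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    props = np.asarray(config.subtype_proportions, dtype=float)

    # deterministic subtype counts closest to the proportions
    counts_per = np.floor(props * n).astype(int)
    while counts_per.sum() < n:
        counts_per[np.argmax(props * n - counts_per)] += 1
    subtype = np.repeat(np.arange(1, props.size + 1), counts_per)
    rng.shuffle(subtype)
    patient_ids = np.array([f"P{i + 1:03d}" for i in range(n)])

    # --- multi-view features ------------------------------------------------
    registry = feature_registry()
    columns = [(v, c, f) for v in VIEW_TYPES for c, f in registry]
    X = rng.standard_normal((n, len(columns)))
    texture_cols = [
        i for i, (_v, c, _f) in enumerate(columns) if c not in ("first-order", "shape")
    ]
    n_affected = int(round(config.affected_feature_fraction * len(texture_cols)))
    affected = rng.choice(texture_cols, size=n_affected, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_affected)
    planted_effects = []
    for col_idx, sign in zip(affected, signs):
        shift = sign * config.texture_effect_sd
        X[subtype == 2, col_idx] += shift
        v, c, f = columns[col_idx]
        planted_effects.append(
            {"view_type": v, "class": c, "feature": f, "subtype2_shift": float(shift)}
        )
    data = pd.DataFrame(
        X,
        index=pd.Index(patient_ids, name="patient_id"),
        columns=pd.MultiIndex.from_tuples(
            columns, names=["view_type", "class", "feature"]
        ),
    )
    features = MultiViewFeatureTable(data)

    # --- expression counts --------------------------------------------------
    gene_ids = np.array([f"g{i + 1:05d}" for i in range(config.n_genes)])
    module_label = np.array(["grey"] * config.n_genes, dtype=object)
    log2_effect = np.zeros(config.n_genes)
    effect_subtype = np.zeros(config.n_genes, dtype=int)
    cursor = 0
    for name, size, up_subtype, effect in config.module_spec:
        sl = slice(cursor, cursor + size)
        module_label[sl] = name
        log2_effect[sl] = effect
        effect_subtype[sl] = up_subtype
        cursor += size

    baseline_rng = np.random.default_rng(config.gene_baseline_seed)
    base_mean = np.exp(baseline_rng.normal(loc=4.0, scale=1.0, size=config.n_genes))
    log2fc_per_patient = np.zeros((config.n_genes, n))
    for s in (1, 2):
        gene_sel = effect_subtype == s
        log2fc_per_patient[np.ix_(gene_sel, subtype == s)] = log2_effect[gene_sel][
            :, None
        ]
    mean = base_mean[:, None] * 2.0**log2fc_per_patient
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape=shape, scale=mean / shape)
    counts = rng.poisson(lam).astype(np.int64)
    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene"), columns=patient_ids
    )

    # --- survival -----------------------------------------------------------
    base_hazard = math.log(2.0) / config.median_survival_days
    hazards = base_hazard * np.exp(
        np.where(subtype == 2, config.subtype2_log_hazard, 0.0)
    )
    event_time = rng.exponential(1.0 / hazards)
    horizon = _censor_horizon(config.censoring_rate, hazards)
    if np.isinf(horizon):
        time, event = event_time, np.ones(n, dtype=int)
    else:
        censor_time = rng.uniform(0.0, horizon, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-3)
    survival = SurvivalData(time, event, endpoint="OS", patient_ids=patient_ids)

    # --- clinical covariates ------------------------------------------------
    afp = np.exp(rng.normal(loc=np.where(subtype == 2, 4.5, 3.0), scale=1.0))
    grade_scores = rng.normal(loc=np.where(subtype == 2, 1.0, 0.0), scale=0.8)
    grade = np.clip(np.round(grade_scores + 2.0), 1, 4).astype(int)
    clinical = pd.DataFrame(
        {"patient_id": patient_ids, "afp": afp, "grade": grade}
    )

    truth = {
        "subtype": subtype,
        "patient_ids": patient_ids,
        "gene_module": dict(zip(gene_ids, module_label)),
        "planted_feature_effects": planted_effects,
        "subtype2_log_hazard": config.subtype2_log_hazard,
    }
    return SyntheticCohort(features, counts_df, survival, clinical, truth)


# ---------------------------------------------------------------------------
# image volume rendering
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def generate_volumes(
    config: CohortConfig,
    shape: tuple[int, int, int] = (36, 36, 36),
    lesion_radii: tuple[float, float, float] = (8.0, 7.0, 6.0),
) -> list[tuple[str, dict[str, ImageVolume], VOIMask]]:
    """Render per-patient two-phase volumes with an ellipsoidal lesion.

    Returns a list of (patient_id, {"artery": vol, "venous": vol}, tumor
    mask).  Subtype 1 lesions: low mean intensity with heterogeneous voxel
    noise (high texture contrast).  Subtype 2: high mean intensity with a
    smooth spatial gradient (low contrast).  The venous phase adds a
    constant enhancement offset.
    """
    if not config.make_volumes:
        raise ConfigError("make_volumes is false in this config")
    if min(lesion_radii) <= 0:
        raise GeometryError("lesion radii must be positive")
    if any(2 * r >= s for r, s in zip(lesion_radii, shape)):
        raise GeometryError("volume smaller than lesion")
    rng = np.random.default_rng(config.seed + 1)
    cohort_rng = np.random.default_rng(config.seed)
    # reproduce the same subtype assignment as generate_cohort
    props = np.asarray(config.subtype_proportions, dtype=float)
    counts_per = np.floor(props * config.n_patients).astype(int)
    while counts_per.sum() < config.n_patients:
        counts_per[np.argmax(props * config.n_patients - counts_per)] += 1
    subtype = np.repeat(np.arange(1, props.size + 1), counts_per)
    cohort_rng.shuffle(subtype)

    center = tuple(s / 2.0 for s in shape)
    mask_arr = _ellipsoid_mask(shape, center, lesion_radii)
    if not mask_arr.any():
        raise GeometryError("empty lesion mask")
    zz = np.indices(shape, dtype=float)[0]
    out = []
    for i, s in enumerate(subtype):
        background = 60.0 + rng.normal(0.0, 3.0, size=shape)
        if s == 1:
            lesion = 85.0 + rng.normal(0.0, 30.0, size=shape)
        else:
            lesion = 150.0 + 2.0 * (zz - center[0]) + rng.normal(0.0, 3.0, size=shape)
        base = np.where(mask_arr, lesion, background)
        phases = {
            "artery": ImageVolume(base.copy()),
            "venous": ImageVolume(base + 20.0),
        }
        out.append((f"P{i + 1:03d}", phases, VOIMask(mask_arr.copy())))
    return out
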