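"""The multi-view feature registry: 100 features per VOI over four views.

Each lesion contributes four VOIs (tumor/peritumor x arterial/venous) and
each VOI yields 18 first-order + 14 shape + 68 texture features, i.e. 400
columns per patient.  Columns are keyed by ``(view_type, class, feature)``
and may be z-scored across patients before fusion.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import TEXTURE_CLASSES, texture_features
from .voi import (
    VIEW_ANNOTATIONS,
    VIEW_TYPES,
    DiscretizationParams,
    ImageVolume,
    VOIMask,
    dilate_peritumor,
    discretize,
    resample_isotropic,
)

logger = logging.getLogger(__name__)


def feature_registry() -> list[tuple[str, str]]:
    """The ordered (class, feature) registry for one VOI: exactly 100 entries."""
    entries = [("first-order", n) for n in FIRST_ORDER_NAMES]
    entries += [("shape", n) for n in SHAPE_NAMES]
    for cls, names in TEXTURE_CLASSES.items():
        entries += [(cls, n) for n in names]
    return entries


N_FIRST_ORDER = len(FIRST_ORDER_NAMES)
N_SHAPE = len(SHAPE_NAMES)
N_TEXTURE = sum(len(v) for v in TEXTURE_CLASSES.values())
N_PER_VOI = N_FIRST_ORDER + N_SHAPE + N_TEXTURE


@dataclasses.dataclass
class MultiViewFeatureTable:
    """Patients x (view, class, feature) matrix.

    ``data`` has a 3-level column MultiIndex (view_type, class, feature)
    and patient ids as the index.  ``standardized`` records whether the
    columns are z-scores.
    """

    data: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.data.columns.nlevels != 3:
            raise ValueError("columns must be (view_type, class, feature)")

    @property
    def patients(self) -> list:
        return list(self.data.index)

    def view(self, view_type: str) -> pd.DataFrame:
        """All columns of one view type (patients x 100)."""
        return self.data[view_type]

    def zscore(self, ddof: int = 0) -> "MultiViewFeatureTable":
        """Z-score each column across patients.

        Constant columns cannot be standardized; they are reported and set
        to 0 so downstream Euclidean distances ignore them.
        """
        mean = self.data.mean(axis=0)
        sd = self.data.std(axis=0, ddof=ddof)
        constant = sd <= 0
        if constant.any():
            logger.warning(
                "%d constant feature column(s) set to 0 during z-scoring: %s",
                int(constant.sum()),
                list(self.data.columns[constant][:5]),
            )
        sd = sd.where(~constant, 1.0)
        z = (self.data - mean) / sd
        z.loc[:, constant.values] = 0.0
        return MultiViewFeatureTable(z, standardized=True)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: patient_id, view_type, class, feature, value."""
        tidy = self.data.stack(level=[0, 1, 2], future_stack=True).reset_index()
        tidy.columns = ["patient_id", "view_type", "class", "feature", "value"]
        return tidy

    def write_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False)

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, standardized: bool = False):
        wide = tidy.pivot_table(
            index="patient_id",
            columns=["view_type", "class", "feature"],
            values="value",
            sort=False,
        )
        return cls(wide, standardized=standardized)

    @classmethod
    def read_csv(cls, path, standardized: bool = False):
        return cls.from_tidy(pd.read_csv(path), standardized=standardized)


def extract_voi_features(
    volume: ImageVolume,
    mask: VOIMask,
    params: DiscretizationParams | None = None,
) -> dict[tuple[str, str], float]:
    """All 100 features of one VOI, keyed by (class, feature)."""
    params = params or DiscretizationParams()
    out: dict[tuple[str, str], float] = {}
    for name, value in first_order_features(volume, mask, params).items():
        out[("first-order", name)] = value
    for name, value in shape_features(mask, volume.spacing).items():
        out[("shape", name)] = value
    levels = discretize(volume, mask, params)
    for cls, feats in texture_features(levels).items():
        for name, value in feats.items():
            out[(cls, name)] = value
    return out


def extract_multiview(
    patients: Iterable[
        tuple[object, ImageVolume, ImageVolume, VOIMask, VOIMask | None]
    ],
    params: DiscretizationParams | None = None,
    radius_mm: float = 10.0,
    standardize: bool = True,
) -> MultiViewFeatureTable:
    """Extract the 400-column multi-view feature table for a cohort.

    Parameters
    ----------
    patients : iterable of (patient_id, arterial, venous, tumor_mask,
        exclusion_mask_or_None).  Patients with a missing phase are skipped
        with a warning, mirroring cohort-assembly exclusions.
    params : discretization / resampling settings (defaults: 1 mm, width 25).
    radius_mm : peritumoral dilation radius.
    standardize : z-score columns across patients when True.
    """
    params = params or DiscretizationParams()
    rows: dict[object, dict[tuple[str, str, str], float]] = {}
    for entry in patients:
        patient_id, arterial, venous, tumor, exclusion = entry
        if arterial is None or venous is None:
            logger.warning("patient %s skipped: missing phase", patient_id)
            continue
        arterial_r, tumor_a = resample_isotropic(arterial, tumor, params)
        venous_r, tumor_v = resample_isotropic(venous, tumor, params)
        if exclusion is not None:
            _, exclusion_r = resample_isotropic(arterial, exclusion, params)
        else:
            exclusion_r = None
        peri = dilate_peritumor(
            tumor_a, arterial_r.spacing, radius_mm=radius_mm, exclusion=exclusion_r
        )
        view_inputs = {
            "type1": (arterial_r, tumor_a),
            "type2": (venous_r, tumor_v),
            "type3": (arterial_r, peri),
            "type4": (venous_r, peri),
        }
        row: dict[tuple[str, str, str], float] = {}
        for view_type in VIEW_TYPES:
            vol, msk = view_inputs[view_type]
            for (cls, name), value in extract_voi_features(vol, msk, params).items():
                row[(view_type, cls, name)] = value
        rows[patient_id] = row

    if not rows:
        raise ValueError("no patient with complete imaging data")
    columns = pd.MultiIndex.from_tuples(
        [(v, c, f) for v in VIEW_TYPES for c, f in feature_registry()],
        names=["view_type", "class", "feature"],
    )
    data = pd.DataFrame.from_dict(rows, orient="index")[list(columns)]
    data.columns = columns
    data.index.name = "patient_id"
    table = MultiViewFeatureTable(data)
    return table.zscore() if standardize else table


def annotate_feature(column: tuple[str, str, str]) -> dict[str, str]:
    """Phase/region/class annotation of a (view_type, class, feature) key."""
    view_type, cls, feature = column
    meta = dict(VIEW_ANNOTATIONS[view_type])
    meta.update({"view_type": view_type, "class": cls, "feature": feature})
    return meta
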