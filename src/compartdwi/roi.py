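"""ROI summarization and inter-observer agreement metrics.

Covers the reader-agreement machinery: ROI-mean parameter extraction from
voxel maps, segmentation overlap between two readers (Dice / recall /
precision), and the intraclass correlation coefficient for paired continuous
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import pingouin as pg

from .exceptions import InvalidInputError, UndefinedMetricError, UnfittableROIError


@dataclass(frozen=True)
class ROIMask:
    """A binary region of interest on the volume grid."""

    data: np.ndarray
    label: str = "lesion"
    reader: str = "A"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data).astype(bool)
        if arr.sum() < 1:
            raise InvalidInputError("an ROI must contain at least one voxel")
        object.__setattr__(self, "data", arr)


def _mask_array(mask) -> np.ndarray:
    if isinstance(mask, ROIMask):
        return mask.data
    return np.asarray(mask).astype(bool)


def summarize_roi(parameter_map, mask) -> float:
    """Arithmetic mean of a parameter map over in-mask, non-sentinel voxels.

    NaN is the missing-value sentinel of unfittable voxels and is excluded.
    Raises :class:`UnfittableROIError` when the mask is empty or covers only
    sentinel voxels.
    """
    pmap = np.asarray(parameter_map, dtype=float)
    m = _mask_array(mask)
    if pmap.shape != m.shape:
        raise InvalidInputError("map and mask are on different grids")
    inside = pmap[m]
    valid = inside[~np.isnan(inside)]
    if valid.size == 0:
        raise UnfittableROIError("no usable voxels inside the ROI")
    return float(valid.mean())


class OverlapMetrics(NamedTuple):
    dsc: float
    recall: float
    precision: float


def overlap_metrics(mask_a, mask_b) -> OverlapMetrics:
    """Dice coefficient, recall and precision of two segmentations.

    ``mask_a`` is the reference reader: recall = |A∩B|/|A|,
    precision = |A∩B|/|B|, dsc = 2|A∩B|/(|A|+|B|).
    """
    a, b = _mask_array(mask_a), _mask_array(mask_b)
    if a.shape != b.shape:
        raise InvalidInputError("masks are on different grids")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise UndefinedMetricError("overlap metrics undefined for two empty masks")
    inter = int((a & b).sum())
    dsc = 2.0 * inter / (na + nb)
    recall = inter / na if na else 0.0
    precision = inter / nb if nb else 0.0
    return OverlapMetrics(dsc=dsc, recall=recall, precision=precision)


#: Agreement bands on the ICC point estimate (lower-exclusive cut-points).
ICC_BANDS = [
    (0.80, "excellent"),
    (0.60, "good"),
    (0.40, "moderate"),
    (0.20, "fair"),
    (float("-inf"), "slight"),
]


def icc_band(icc: float) -> str:
    for lo, name in ICC_BANDS:
        if icc > lo:
            return name
    return "slight"


class ICCResult(NamedTuple):
    icc: float
    ci_low: float
    ci_high: float
    band: str
    p: float


def icc_agreement(values_a, values_b) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measures ICC.

    The standard choice for two interchangeable raters; 95% CI and the
    qualitative agreement band are returned alongside the estimate.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("paired 1-D measurement vectors required")
    if a.size < 5:
        raise InvalidInputError("ICC needs at least 5 paired measurements")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise UndefinedMetricError("ICC undefined: zero variance in both readers")
    n = a.size
    long = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["A", "B"], n),
        "score": np.concatenate([a, b]),
    })
    table = pg.intraclass_corr(long, targets="target", raters="rater",
                               ratings="score")
    # two-way random, absolute agreement, single measures; label differs
    # across pingouin versions
    row = table[table["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    icc = float(row["ICC"])
    ci_low, ci_high = (float(v) for v in row[ci_col])
    return ICCResult(icc=icc, ci_low=ci_low, ci_high=ci_high,
                     band=icc_band(icc), p=float(row["pval"]))


def agreement_report(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     parameters: list[str]) -> pd.DataFrame:
    """Per-parameter inter-reader ICC report (one row per parameter).

    ``table_a`` and ``table_b`` are lesion tables from the two readers with
    identical lesion ordering.
    """
    rows = []
    for p in parameters:
        res = icc_agreement(table_a[p].to_numpy(), table_b[p].to_numpy())
        rows.append({"parameter": p, "ICC": res.icc,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "band": res.band, "P": res.p})
    return pd.DataFrame(rows)
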