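"""Saliency-overlap analysis: normalization, optimal-threshold areas of interest and Dice scoring.

The scientific question this module serves is whether a classifier's saliency map
concentrates on a known lesion.  For each image the saliency field is min-max
normalized to [0, 1], an *area of interest* (AOI) is extracted by thresholding, and
the overlap between the AOI ``A`` and the ground-truth lesion mask ``B`` is scored
with Dice's similarity coefficient

    DSC(A, B) = 2 |A ∩ B| / (|A| + |B|).

The threshold is chosen per image to maximize the DSC, so the reported value is an
upper bound on how lesion-localized the saliency can appear under any thresholding.
The search is exact: candidate thresholds are exactly the distinct saliency values,
and a sorted prefix sweep evaluates all of them in O(P log P) for P pixels.

Conventions (fixed for reproducibility):

* thresholding keeps pixels with saliency **>= tau**, so pixels sharing a value
  enter or leave the AOI together and the top pixel is always selectable;
* among DSC-maximizing thresholds the **largest** tau (smallest AOI) is returned;
* medians and interquartile ranges use linear-interpolation quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, DegenerateInputError, ValidationError

__all__ = [
    "SaliencyMap",
    "LesionMask",
    "AreaOfInterest",
    "OverlapSummary",
    "normalize",
    "dsc_of",
    "optimal_aoi",
    "include_image",
    "summarize",
    "SaliencyLocalization",
    "LocalizationResults",
]


@dataclass(frozen=True)
class SaliencyMap:
    """Real-valued saliency field over image pixels.

    ``normalized`` records whether values have been min-max rescaled to [0, 1];
    ``degenerate`` flags a constant input map (normalized to all zeros).
    """

    values: np.ndarray
    normalized: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValidationError(f"saliency map must be 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("saliency map contains NaN or Inf values")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def in_unit_interval(self) -> bool:
        return bool(self.values.min() >= 0.0 and self.values.max() <= 1.0)


@dataclass(frozen=True)
class LesionMask:
    """Binary ground-truth lesion mask (the set ``B`` of the Dice formula)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise ValidationError(f"lesion mask must be 2-D, got shape {p.shape}")
        object.__setattr__(self, "pixels", p.astype(bool))

    @property
    def count(self) -> int:
        """Number of lesion pixels, |B|."""
        return int(np.count_nonzero(self.pixels))

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def empty(self) -> bool:
        return self.count == 0


@dataclass(frozen=True)
class AreaOfInterest:
    """Supra-threshold pixel set ``A`` with the threshold and DSC it achieves."""

    pixels: np.ndarray
    threshold: float
    dsc: float


@dataclass(frozen=True)
class OverlapSummary:
    n_images: int
    median_dsc: float
    iqr_dsc: float
    per_image: pd.DataFrame = field(repr=False)


def normalize(smap: SaliencyMap) -> SaliencyMap:
    """Min-max rescale a saliency map to [0, 1] per image.

    Non-constant maps come out with min 0 and max 1; constant maps are mapped to
    all zeros and flagged degenerate.  Idempotent on already-normalized maps.
    """
    v = smap.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return SaliencyMap(np.zeros_like(v), normalized=True, degenerate=True)
    return SaliencyMap((v - lo) / (hi - lo), normalized=True)


def _as_bool(a) -> np.ndarray:
    if isinstance(a, LesionMask):
        return a.pixels
    if isinstance(a, AreaOfInterest):
        return a.pixels
    return np.asarray(a).astype(bool)


def dsc_of(a, b) -> float:
    """Dice similarity 2|A∩B|/(|A|+|B|) between two same-shape binary sets.

    Raises :class:`DegenerateInputError` when both sets are empty (the quotient
    is undefined; a number is never fabricated).
    """
    A, B = _as_bool(a), _as_bool(b)
    if A.shape != B.shape:
        raise ConsistencyError(f"shape mismatch: {A.shape} vs {B.shape}")
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        raise DegenerateInputError("DSC undefined: both sets empty (|A|+|B| = 0)")
    return 2.0 * int(np.count_nonzero(A & B)) / (na + nb)


def optimal_aoi(smap: SaliencyMap, mask: LesionMask) -> AreaOfInterest:
    """Area of interest at the DSC-maximizing saliency threshold.

    Sorts pixels by descending saliency; with ``k`` pixels above the cut and
    ``TP(k)`` of them on the lesion, the Dice score of the prefix is
    ``2 TP(k) / (k + |B|)``.  Only prefixes ending at a boundary between distinct
    values are admissible (equal-valued pixels cannot be split), so the sweep is
    exactly equivalent to evaluating every distinct value as a threshold.  Ties in
    DSC resolve to the largest threshold, i.e. the smallest area of interest.
    """
    if not smap.normalized and not smap.in_unit_interval:
        raise ValidationError("saliency map must be normalized to [0,1] first")
    if smap.shape != mask.shape:
        raise ConsistencyError(f"saliency {smap.shape} vs mask {mask.shape}")
    if mask.empty:
        raise DegenerateInputError("optimal_aoi requires a nonempty lesion mask")

    s = smap.values.ravel()
    m = mask.pixels.ravel()
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    tp = np.cumsum(m[order])

    # prefix lengths k at which the value changes (admissible cuts), plus the full image
    boundaries = np.flatnonzero(np.diff(s_sorted)) + 1
    ks = np.concatenate([boundaries, [s.size]])
    dscs = 2.0 * tp[ks - 1] / (ks + mask.count)
    best = int(np.argmax(dscs))  # first max <-> smallest k <-> largest threshold
    tau = float(s_sorted[ks[best] - 1])
    return AreaOfInterest(pixels=smap.values >= tau, threshold=tau, dsc=float(dscs[best]))


def include_image(mask: Optional[LesionMask]) -> bool:
    """Inclusion rule for overlap analysis: a usable (present, nonempty) mask.

    Images whose lesion could not be segmented (absent or empty mask) are
    excluded from overlap scoring but still count toward detection evaluation.
    """
    return mask is not None and not mask.empty


def summarize(dscs: Sequence[float], image_ids=None, thresholds=None) -> OverlapSummary:
    """Median and IQR (Q3 - Q1, linear-interpolation quantiles) of per-image DSCs."""
    values = np.asarray(list(dscs), dtype=float)
    if values.size == 0:
        raise ValidationError("cannot summarize an empty DSC list")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    per_image = pd.DataFrame(
        {
            "image_id": list(image_ids) if image_ids is not None else [""] * values.size,
            "threshold": list(thresholds) if thresholds is not None else [np.nan] * values.size,
            "dsc": values,
        }
    )
    return OverlapSummary(
        n_images=int(values.size),
        median_dsc=float(med),
        iqr_dsc=float(q3 - q1),
        per_image=per_image,
    )


class SaliencyLocalization:
    """Model of lesion localization for one system's saliency maps.

    Built from parallel lists of saliency maps and lesion masks (a mask may be
    ``None`` or empty for images whose lesion could not be segmented; those are
    excluded from scoring and counted).  ``fit`` normalizes each map, extracts the
    optimal-threshold area of interest and returns a :class:`LocalizationResults`.
    """

    def __init__(self, saliency_maps, masks, image_ids=None):
        self.saliency_maps = list(saliency_maps)
        self.masks = list(masks)
        if len(self.saliency_maps) != len(self.masks):
            raise ValidationError("saliency_maps and masks must have equal length")
        self.image_ids = (
            list(image_ids)
            if image_ids is not None
            else [f"img{i}" for i in range(len(self.masks))]
        )
        if len(self.image_ids) != len(self.masks):
            raise ValidationError("image_ids length mismatch")

    def fit(self) -> "LocalizationResults":
        ids, taus, dscs, excluded = [], [], [], []
        for img_id, smap, mask in zip(self.image_ids, self.saliency_maps, self.masks):
            if not include_image(mask):
                excluded.append(img_id)
                continue
            aoi = optimal_aoi(normalize(smap), mask)
            ids.append(img_id)
            taus.append(aoi.threshold)
            dscs.append(aoi.dsc)
        if not dscs:
            raise DegenerateInputError(
                "no images with usable lesion masks; see excluded ids"
            )
        summary = summarize(dscs, image_ids=ids, thresholds=taus)
        return LocalizationResults(summary=summary, excluded_ids=excluded)


@dataclass(frozen=True)
class LocalizationResults:
    """Per-image optimal-threshold DSCs with the median/IQR summary."""

    summary: OverlapSummary
    excluded_ids: list

    @property
    def median_dsc(self) -> float:
        return self.summary.median_dsc

    @property
    def iqr_dsc(self) -> float:
        return self.summary.iqr_dsc

    @property
    def n_images(self) -> int:
        return self.summary.n_images

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)

    @property
    def per_image(self) -> pd.DataFrame:
        return self.summary.per_image

    def table_row(self) -> dict:
        return {
            "n_overlap_images": self.n_images,
            "n_excluded_images": self.n_excluded,
            "median_dsc": self.median_dsc,
            "iqr_dsc": self.iqr_dsc,
        }

    def summary_text(self) -> str:
        return (
            f"Saliency localization: n={self.n_images} images "
            f"({self.n_excluded} excluded), median DSC {self.median_dsc:.3f} "
            f"(IQR {self.iqr_dsc:.3f})"
        )
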