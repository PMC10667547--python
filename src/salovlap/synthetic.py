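"""Synthetic phantoms, saliency fields, detection scores and cohort tables.

Every pipeline stage is testable without any real mammograms.  The generators
emulate the statistical structure the analysis assumes, not radiological realism:

* **Phantoms** are a half-ellipse "breast" of smoothed noise texture on a dark
  background, with an additive bright elliptical lesion whose pixel set is the
  ground-truth mask (ground truth is independent of lesion conspicuity).
* **Saliency fields** interpolate between a smooth bump on the lesion centroid
  (localization ``lam = 1``) and a broad bump placed independently of the lesion
  (``lam = 0``, modelling systems that attend to large image regions), plus
  noise, then per-image min-max normalization.
* **Detection scores** follow the binormal model: controls ~ N(0,1), cases
  ~ N(mu,1), so the true AUC is the closed form Phi(mu / sqrt(2)).
* **Cohorts** carry the matching keys (birth year, screening year, mammographic
  system); the candidate pool is constructed so a full 1:1 matching exists.

All generators are pure functions of their parameter records including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .detection import Label, ScoredImage
from .exceptions import ParameterError, ValidationError
from .matching import CohortRecord
from .overlap import LesionMask, SaliencyMap, normalize
from .seeding import derive_seed

__all__ = [
    "PhantomParams",
    "SaliencyGenParams",
    "ScoreGenParams",
    "make_phantom",
    "make_saliency",
    "make_scores",
    "make_cohort",
    "SystemSpec",
    "make_dataset",
    "binormal_true_auc",
]

# Defaults chosen once to mirror a population screening setting: women aged
# 50-69 invited in 2015-2017, two mammographic vendors with the minority vendor
# at roughly one fifth of the sample, and cancer-type frequencies typical of a
# screen-detected series (DCIS 17%, ductal 64%, lobular 13%, other 6%).
DEFAULT_SCREENING_YEARS = (2015, 2016, 2017)
DEFAULT_BIRTH_RANGE = (1946, 1967)
DEFAULT_AGE_RANGE = (50, 69)
DEFAULT_SYSTEMS = ("PH", "GE")
DEFAULT_SYSTEM_PROPS = (0.22, 0.78)
CANCER_TYPES = ("DCIS", "ductal", "lobular", "other")
CANCER_TYPE_PROPS = (0.17, 0.64, 0.13, 0.06)


def binormal_true_auc(mu: float) -> float:
    """Closed-form AUC of the binormal model: Phi(mu / sqrt 2)."""
    from scipy.stats import norm

    return float(norm.cdf(mu / np.sqrt(2.0)))


def binormal_mu_for_auc(auc: float) -> float:
    """Mean shift giving a desired true AUC under the binormal model."""
    from scipy.stats import norm

    return float(norm.ppf(auc) * np.sqrt(2.0))


# ---------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class PhantomParams:
    """Phantom geometry and texture.  All lengths in pixels."""

    height: int = 128
    width: int = 128
    breast_semiaxes: Tuple[float, float] = (56.0, 100.0)  # (rows, cols), anchored left
    texture_smoothness: float = 4.0  # gaussian blur radius of background noise
    lesion_center: Tuple[float, float] = (64.0, 40.0)  # (row, col)
    lesion_axes: Tuple[float, float] = (6.0, 4.0)  # (row, col) semi-axes
    lesion_contrast: float = 0.5  # additive brightness, unitless >= 0
    seed: int = 0


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def make_phantom(params: PhantomParams) -> Tuple[np.ndarray, LesionMask]:
    """Phantom image plus its ground-truth lesion mask.

    The breast is the half-ellipse anchored at the left image edge; background
    texture is seeded noise blurred by ``texture_smoothness``; the lesion is an
    additive bright ellipse.  The mask marks exactly the discrete lesion-ellipse
    pixels regardless of contrast.  Deterministic given the seed.
    """
    if params.lesion_contrast < 0:
        raise ParameterError("lesion_contrast must be >= 0")
    shape = (params.height, params.width)
    breast = _ellipse_mask(
        shape, (params.height / 2.0, 0.0), params.breast_semiaxes
    )
    lesion = _ellipse_mask(shape, params.lesion_center, params.lesion_axes)
    if not lesion.any():
        raise ParameterError("lesion ellipse contains no pixels")
    if (lesion & ~breast).any():
        raise ParameterError("lesion ellipse extends outside the breast region")

    rng = np.random.default_rng(params.seed)
    texture = gaussian_filter(rng.normal(size=shape), params.texture_smoothness)
    span = texture.max() - texture.min()
    if span > 0:
        texture = (texture - texture.min()) / span
    image = np.where(breast, 0.2 + 0.5 * texture, 0.0)
    image = image + params.lesion_contrast * lesion
    return image, LesionMask(lesion)


# ---------------------------------------------------------------------------
# saliency fields


@dataclass(frozen=True)
class SaliencyGenParams:
    """Tunable localization of a synthetic saliency field.

    ``localization`` (lambda in [0,1]) mixes a bump on the lesion centroid with
    a broad bump placed independently of the lesion; ``noise_amplitude`` adds
    pixel noise before per-image normalization.
    """

    localization: float = 1.0
    lesion_kernel_width: float = 8.0
    diffuse_kernel_width: float = 48.0
    noise_amplitude: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.localization <= 1.0:
            raise ParameterError("localization must lie in [0, 1]")


def _bump(shape, center, width) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return np.exp(-d2 / (2.0 * width**2))


def make_saliency(
    mask: Optional[LesionMask],
    params: SaliencyGenParams,
    shape: Optional[Tuple[int, int]] = None,
) -> SaliencyMap:
    """Synthetic normalized saliency field for one image.

    field = lam * K_lesion + (1 - lam) * K_diffuse + noise, then min-max
    normalized.  ``K_lesion`` is a Gaussian bump on the lesion centroid (flat
    zero when the mask is empty or absent); ``K_diffuse`` is a broad bump at a
    uniform-random center, independent of the lesion.
    """
    if mask is not None:
        shape = mask.shape
    if shape is None:
        raise ValidationError("shape required when mask is absent")
    rng = np.random.default_rng(params.seed)
    lam = params.localization

    if mask is not None and not mask.empty:
        rr, cc = np.nonzero(mask.pixels)
        k_lesion = _bump(shape, (rr.mean(), cc.mean()), params.lesion_kernel_width)
    else:
        k_lesion = np.zeros(shape)
    center = (rng.uniform(0, shape[0]), rng.uniform(0, shape[1]))
    k_diffuse = _bump(shape, center, params.diffuse_kernel_width)
    field = lam * k_lesion + (1.0 - lam) * k_diffuse
    if params.noise_amplitude > 0:
        field = field + rng.normal(0.0, params.noise_amplitude, size=shape)
    return normalize(SaliencyMap(field))


# ---------------------------------------------------------------------------
# detection scores


@dataclass(frozen=True)
class ScoreGenParams:
    """Binormal score model: controls ~ N(0,1), cases ~ N(effect_mu, 1)."""

    n_cases: int
    n_controls: int
    effect_mu: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ParameterError("need at least one case and one control")

    @property
    def true_auc(self) -> float:
        return binormal_true_auc(self.effect_mu)


def make_scores(params: ScoreGenParams) -> List[ScoredImage]:
    rng = np.random.default_rng(params.seed)
    case_scores = rng.normal(params.effect_mu, 1.0, size=params.n_cases)
    control_scores = rng.normal(0.0, 1.0, size=params.n_controls)
    out = [
        ScoredImage(f"case{i:05d}", float(s), Label.CASE, woman_id=f"wc{i:05d}")
        for i, s in enumerate(case_scores)
    ]
    out += [
        ScoredImage(f"ctrl{i:05d}", float(s), Label.CONTROL, woman_id=f"wn{i:05d}")
        for i, s in enumerate(control_scores)
    ]
    return out


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(
    n_cases: int,
    n_pool: int,
    seed: int,
    screening_years=DEFAULT_SCREENING_YEARS,
    birth_range=DEFAULT_BIRTH_RANGE,
    systems=DEFAULT_SYSTEMS,
    system_props=DEFAULT_SYSTEM_PROPS,
) -> List[CohortRecord]:
    """Cases plus a control-candidate pool on shared matching keys.

    Ages are drawn uniformly on 50-69 (the screening invitation band) and birth
    years derived as screening year minus age, clipped to ``birth_range``.  The
    first ``n_cases`` pool candidates copy the case keys so a full 1:1 matching
    exists by construction.
    """
    if n_pool < n_cases:
        raise ParameterError("n_pool must be >= n_cases to guarantee a full matching")
    rng = np.random.default_rng(seed)

    def draw_key():
        sy = int(rng.choice(screening_years))
        age = int(rng.integers(DEFAULT_AGE_RANGE[0], DEFAULT_AGE_RANGE[1] + 1))
        by = int(np.clip(sy - age, birth_range[0], birth_range[1]))
        system = str(rng.choice(systems, p=system_props))
        return by, sy, system

    records: List[CohortRecord] = []
    case_keys = []
    for i in range(n_cases):
        by, sy, system = draw_key()
        case_keys.append((by, sy, system))
        records.append(
            CohortRecord(
                woman_id=f"case{i:05d}",
                status="case",
                birth_year=by,
                screening_year=sy,
                system=system,
                cancer_type=str(rng.choice(CANCER_TYPES, p=CANCER_TYPE_PROPS)),
            )
        )
    for i in range(n_pool):
        by, sy, system = case_keys[i] if i < n_cases else draw_key()
        records.append(
            CohortRecord(
                woman_id=f"ctrl{i:05d}",
                status="control",
                birth_year=by,
                screening_year=sy,
                system=system,
            )
        )
    return records


# ---------------------------------------------------------------------------
# complete dataset fixture-writer


@dataclass(frozen=True)
class SystemSpec:
    """One emulated detection system: saliency localization plus score effect."""

    localization: float
    effect_mu: float
    lesion_kernel_width: float = 8.0
    diffuse_kernel_width: float = 48.0
    noise_amplitude: float = 0.02


@dataclass(frozen=True)
class DatasetInfo:
    root: Path
    n_images: int
    n_lesion_images: int
    n_missing_masks: int


def make_dataset(
    out_dir,
    systems: Dict[str, SystemSpec],
    n_cases: int = 191,
    n_controls: int = 191,
    image_size: int = 128,
    n_missing_masks: int = 12,
    seed: int = 0,
    saliency_format: str = ".png",
) -> DatasetInfo:
    """Write a complete synthetic dataset directory consumable by the pipeline.

    Each woman contributes four images (left/right x CC/MLO).  Cases carry an
    elliptical lesion on both views of one affected breast; ``n_missing_masks``
    of those lesion images get no mask, emulating lesions conspicuous in only
    one view.  Per system, every image gets a detection score (binormal model
    keyed on the woman's status) and every mask-bearing image gets a saliency
    map at the system's localization level.
    """
    from . import io_formats as iof

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(derive_seed(seed, "dataset-layout"))

    cohort = make_cohort(n_cases, n_controls, derive_seed(seed, "cohort"))
    iof.write_cohort(cohort, out / "cohort.csv")

    manifest_rows = []
    lesion_images = []  # (image_id, mask)
    n_lesions_total = 2 * n_cases
    if not 0 <= n_missing_masks <= n_lesions_total:
        raise ParameterError("n_missing_masks out of range")

    for rec in cohort:
        affected = rng.choice(["left", "right"]) if rec.status == "case" else None
        for lat in ("left", "right"):
            for view in ("CC", "MLO"):
                image_id = f"{rec.woman_id}_{lat[0].upper()}{view}"
                has_lesion = rec.status == "case" and lat == affected
                mask_rel = ""
                if has_lesion:
                    # lesion geometry drawn inside the breast half-ellipse
                    ph = PhantomParams(
                        height=image_size,
                        width=image_size,
                        breast_semiaxes=(0.44 * image_size, 0.78 * image_size),
                        lesion_center=(
                            float(rng.uniform(0.3, 0.7) * image_size),
                            float(rng.uniform(0.15, 0.45) * image_size),
                        ),
                        lesion_axes=(
                            float(rng.uniform(3, 9)),
                            float(rng.uniform(3, 9)),
                        ),
                        seed=derive_seed(seed, f"phantom:{image_id}"),
                    )
                    _, mask = make_phantom(ph)
                    lesion_images.append((image_id, mask))
                    mask_rel = f"masks/{image_id}.png"
                    iof.write_mask(mask, out / mask_rel)
                manifest_rows.append(
                    {
                        "image_id": image_id,
                        "woman_id": rec.woman_id,
                        "laterality": lat,
                        "view": view,
                        "height": image_size,
                        "width": image_size,
                        "mask": mask_rel,
                    }
                )

    # emulate lesions conspicuous in only one view: for a sample of distinct
    # cases, drop the mask of exactly one of the two affected-breast views
    if n_missing_masks > n_cases:
        raise ParameterError("n_missing_masks cannot exceed the number of cases")
    hit_cases = rng.choice(n_cases, size=n_missing_masks, replace=False)
    drop = {2 * int(ci) + int(rng.integers(2)) for ci in hit_cases}
    kept_lesions = []
    dropped_ids = set()
    for i, (image_id, mask) in enumerate(lesion_images):
        if i in drop:
            dropped_ids.add(image_id)
            (out / f"masks/{image_id}.png").unlink()
        else:
            kept_lesions.append((image_id, mask))
    for row in manifest_rows:
        if row["image_id"] in dropped_ids:
            row["mask"] = ""
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)

    status_by_woman = {r.woman_id: r.status for r in cohort}
    for name, spec in sorted(systems.items()):
        sys_dir = out / "systems" / name
        score_rng = np.random.default_rng(derive_seed(seed, f"scores:{name}"))
        scored = []
        for row in manifest_rows:
            is_case = status_by_woman[row["woman_id"]] == "case"
            mean = spec.effect_mu if is_case else 0.0
            scored.append(
                ScoredImage(
                    image_id=row["image_id"],
                    woman_id=row["woman_id"],
                    score=float(score_rng.normal(mean, 1.0)),
                    label=Label.CASE if is_case else Label.CONTROL,
                )
            )
        iof.write_scores(scored, sys_dir / "scores.csv")
        for image_id, mask in kept_lesions:
            smap = make_saliency(
                mask,
                SaliencyGenParams(
                    localization=spec.localization,
                    lesion_kernel_width=spec.lesion_kernel_width,
                    diffuse_kernel_width=spec.diffuse_kernel_width,
                    noise_amplitude=spec.noise_amplitude,
                    seed=derive_seed(seed, f"saliency:{name}:{image_id}"),
                ),
            )
            iof.write_saliency(smap, sys_dir / "saliency" / f"{image_id}{saliency_format}")

    return DatasetInfo(
        root=out,
        n_images=len(manifest_rows),
        n_lesion_images=len(lesion_images),
        n_missing_masks=n_missing_masks,
    )
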