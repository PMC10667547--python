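"""On-disk formats: masks, saliency maps, score tables, cohort tables, reports, config.

Layout of a dataset directory (produced by the synthetic fixture-writer and
consumed by the pipeline):

    dataset/
      manifest.csv                 image_id,woman_id,laterality,view,height,width,mask
      cohort.csv                   woman_id,status,birth_year,screening_year,system,cancer_type
      masks/<image_id>.png         8- or 16-bit single-channel; any value > 0 is lesion
      systems/<name>/scores.csv    image_id,woman_id,label,score
      systems/<name>/saliency/<image_id>.png|.npy

Pixel conventions: row-major, origin top-left, 0-based indices.  Integer saliency
images are mapped to reals by dividing by the format's maximum representable value
(255 or 65535); ``.npy`` arrays are read as-is.  Report CSVs mirror the standard
System / AUC / 95% CI / DSC (IQR) column order, with the CI rendered with an
en-dash ("0.655–0.719") and DSC as a proportion at 3 decimals; the JSON report
carries raw floats.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detection import Label, ScoredImage
from .exceptions import ConsistencyError, FormatError, ValidationError
from .matching import CohortRecord
from .overlap import LesionMask, SaliencyMap

__all__ = [
    "ImageRecord",
    "DatasetManifest",
    "read_mask",
    "write_mask",
    "read_saliency",
    "write_saliency",
    "read_scores",
    "write_scores",
    "read_cohort",
    "write_cohort",
    "write_report",
    "read_report_json",
    "read_config",
    "setup_logging",
]

logger = logging.getLogger("salovlap")

LATERALITIES = ("left", "right")
VIEWS = ("CC", "MLO")


@dataclass(frozen=True)
class ImageRecord:
    image_id: str
    woman_id: str
    laterality: str
    view: str
    height: int
    width: int
    mask_path: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise ValidationError(f"{self.image_id}: laterality {self.laterality!r}")
        if self.view not in VIEWS:
            raise ValidationError(f"{self.image_id}: view {self.view!r}")
        if self.height < 1 or self.width < 1:
            raise ValidationError(f"{self.image_id}: non-positive image dimensions")


@dataclass
class DatasetManifest:
    """Image inventory with resolved per-system resource paths.

    ``validate`` is fail-fast: every referenced mask, saliency and score resource
    must resolve (and shapes must agree) before any analysis starts.
    """

    root: Path
    records: List[ImageRecord]
    systems: Dict[str, Path] = field(default_factory=dict)

    @classmethod
    def load(cls, root) -> "DatasetManifest":
        root = Path(root)
        df = pd.read_csv(root / "manifest.csv", dtype=str, keep_default_na=False)
        records = []
        seen = set()
        for r in df.itertuples(index=False):
            if r.image_id in seen:
                raise ValidationError(f"duplicate image_id {r.image_id!r} in manifest")
            seen.add(r.image_id)
            records.append(
                ImageRecord(
                    image_id=r.image_id,
                    woman_id=r.woman_id,
                    laterality=r.laterality,
                    view=r.view,
                    height=int(r.height),
                    width=int(r.width),
                    mask_path=(root / r.mask) if r.mask else None,
                )
            )
        systems_dir = root / "systems"
        systems = (
            {p.name: p for p in sorted(systems_dir.iterdir()) if p.is_dir()}
            if systems_dir.is_dir()
            else {}
        )
        return cls(root=root, records=records, systems=systems)

    def saliency_path(self, system: str, image_id: str) -> Optional[Path]:
        base = self.systems[system] / "saliency"
        for ext in (".png", ".tif", ".tiff", ".npy"):
            p = base / f"{image_id}{ext}"
            if p.exists():
                return p
        return None

    def scores_path(self, system: str) -> Path:
        return self.systems[system] / "scores.csv"

    def validate(self) -> None:
        for rec in self.records:
            if rec.mask_path is not None and not rec.mask_path.exists():
                raise ValidationError(f"{rec.image_id}: mask file missing: {rec.mask_path}")
        for name in self.systems:
            if not self.scores_path(name).exists():
                raise ValidationError(f"system {name}: scores.csv missing")
            scored = {s.image_id for s in read_scores(self.scores_path(name))}
            missing = [r.image_id for r in self.records if r.image_id not in scored]
            if missing:
                raise ValidationError(
                    f"system {name}: no score for images {missing[:5]}"
                    + ("..." if len(missing) > 5 else "")
                )
        # shape agreement between declared size, mask and saliency
        for rec in self.records:
            if rec.mask_path is None:
                continue
            mask = read_mask(rec.mask_path)
            if mask.shape != (rec.height, rec.width):
                raise ConsistencyError(
                    f"{rec.image_id}: mask shape {mask.shape} vs declared "
                    f"({rec.height}, {rec.width})"
                )
            for name in self.systems:
                p = self.saliency_path(name, rec.image_id)
                if p is None:
                    raise ValidationError(
                        f"system {name}: saliency missing for lesion image {rec.image_id}"
                    )
                smap = read_saliency(p, expected_shape=(rec.height, rec.width))
                if smap.shape != mask.shape:
                    raise ConsistencyError(
                        f"{rec.image_id}/{name}: saliency {smap.shape} vs mask {mask.shape}"
                    )


# ---------------------------------------------------------------------------
# masks and saliency


def read_mask(path) -> LesionMask:
    """Read a binary lesion mask from a single-channel grayscale image.

    Any pixel value > 0 is lesion — robust to 8- vs 16-bit exports of binary
    contours.
    """
    try:
        arr = iio.imread(Path(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable / corrupt
        raise FormatError(f"cannot read mask image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"mask {path} is not single-channel (shape {arr.shape})")
    return LesionMask(arr > 0)


def write_mask(mask: LesionMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
    return path


def read_saliency(path, expected_shape=None) -> SaliencyMap:
    """Read a saliency map from a grayscale image (8/16-bit) or a ``.npy`` array.

    Integer pixels are divided by the dtype's maximum so 8- and 16-bit encodings
    of the same relative intensities agree after normalization.
    """
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        try:
            arr = iio.imread(path)
        except FileNotFoundError:
            raise
        except Exception as exc:
            raise FormatError(f"cannot read saliency image {path}: {exc}") from exc
        if arr.ndim != 2:
            raise FormatError(f"saliency {path} is not single-channel (shape {arr.shape})")
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / np.iinfo(arr.dtype).max
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise FormatError(f"saliency {path} must be 2-D (shape {arr.shape})")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"saliency {path} contains NaN/Inf")
    if expected_shape is not None and arr.shape != tuple(expected_shape):
        raise ConsistencyError(
            f"saliency {path} shape {arr.shape} != declared {tuple(expected_shape)}"
        )
    in_unit = bool(arr.min() >= 0.0 and arr.max() <= 1.0)
    return SaliencyMap(arr, normalized=in_unit)


def write_saliency(smap: SaliencyMap, path) -> Path:
    """Write saliency as 16-bit PNG (values clipped to [0,1]) or raw ``.npy``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".npy":
        np.save(path, smap.values)
    else:
        v = np.clip(smap.values, 0.0, 1.0)
        iio.imwrite(path, np.round(v * 65535).astype(np.uint16))
    return path


# ---------------------------------------------------------------------------
# tables


def read_scores(path) -> List[ScoredImage]:
    """Per-image detection scores: CSV with image_id, woman_id, label, score.

    Labels are matched case-insensitively after trimming; duplicate image ids
    are rejected.
    """
    df = pd.read_csv(path, dtype={"image_id": str, "woman_id": str})
    required = {"image_id", "woman_id", "label", "score"}
    if not required.issubset(df.columns):
        raise FormatError(f"scores CSV {path} missing columns {required - set(df.columns)}")
    if df["image_id"].duplicated().any():
        dups = df.loc[df["image_id"].duplicated(), "image_id"].tolist()
        raise ValidationError(f"duplicate image_id in {path}: {dups[:5]}")
    out = []
    for r in df.itertuples(index=False):
        token = str(r.label).strip().lower()
        try:
            label = Label(token)
        except ValueError:
            raise ValidationError(f"unknown label token {r.label!r} in {path}") from None
        out.append(
            ScoredImage(
                image_id=str(r.image_id),
                woman_id=str(r.woman_id),
                score=float(r.score),
                label=label,
            )
        )
    return out


def write_scores(scores: Sequence[ScoredImage], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "image_id": [s.image_id for s in scores],
            "woman_id": [s.woman_id for s in scores],
            "label": [s.label.value for s in scores],
            "score": [s.score for s in scores],
        }
    ).to_csv(path, index=False)
    return path


def read_cohort(path) -> List[CohortRecord]:
    df = pd.read_csv(path, dtype={"woman_id": str}, keep_default_na=False)
    recs = []
    ids = set()
    for r in df.itertuples(index=False):
        if r.woman_id in ids:
            raise ValidationError(f"duplicate woman_id {r.woman_id!r} in {path}")
        ids.add(r.woman_id)
        recs.append(
            CohortRecord(
                woman_id=str(r.woman_id),
                status=str(r.status).strip().lower(),
                birth_year=int(r.birth_year),
                screening_year=int(r.screening_year),
                system=str(r.system),
                cancer_type=(str(r.cancer_type) or None) if r.cancer_type != "" else None,
            )
        )
    return recs


def write_cohort(records: Sequence[CohortRecord], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "woman_id": [r.woman_id for r in records],
            "status": [r.status for r in records],
            "birth_year": [r.birth_year for r in records],
            "screening_year": [r.screening_year for r in records],
            "system": [r.system for r in records],
            "cancer_type": [r.cancer_type or "" for r in records],
        }
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# reports

REPORT_CSV_HEADER = "System,AUC,95% CI,DSC (IQR)"


def format_ci(lo: float, hi: float) -> str:
    return f"{lo:.3f}–{hi:.3f}"


def write_report(rows: Sequence[dict], csv_path, json_path) -> None:
    """Emit the per-system report as CSV (System/AUC/95% CI/DSC (IQR) column
    order, 3-decimal fixed precision) and JSON (raw floats plus counts)."""
    csv_path, json_path = Path(csv_path), Path(json_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    json_path.parent.mkdir(parents=True, exist_ok=True)
    lines = [REPORT_CSV_HEADER]
    for row in rows:
        lines.append(
            f"{row['system']},{row['auc']:.3f},"
            f"{format_ci(row['ci_low'], row['ci_high'])},"
            f"{row['median_dsc']:.3f} ({row['iqr_dsc']:.3f})"
        )
    csv_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    json_path.write_text(
        json.dumps({"systems": list(rows)}, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_report_json(path) -> List[dict]:
    return json.loads(Path(path).read_text(encoding="utf-8"))["systems"]


# ---------------------------------------------------------------------------
# config and logging


def read_config(path) -> Dict[str, str]:
    """Plain-text key = value config; '#' starts a comment; keys lowercase."""
    out: Dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"config line without '=': {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip().lower()] = value.strip()
    return out


def setup_logging(log_path=None, verbosity: str = "info") -> logging.Logger:
    level = getattr(logging, verbosity.upper(), logging.INFO)
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    handler = logging.StreamHandler()
    handler.setFormatter(fmt)
    logger.addHandler(handler)
    if log_path is not None:
        Path(log_path).parent.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(log_path)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger
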