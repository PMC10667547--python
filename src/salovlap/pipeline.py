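"""End-to-end experiment orchestration.

The full analysis runs in four stages, each writing plain files the next stage
reads, so the staged subcommands compose to exactly what :func:`run_experiment`
produces:

1. **match** — assemble the 1:1 matched case–control cohort; women outside the
   matched set leave the analysis here.
2. **score-eval** — per system, ROC AUC with a stratified percentile-bootstrap
   CI and the significance call vs 0.5, over all matched women's images.
3. **overlap** — per system, optimal-threshold Dice overlap on case-side
   lesion-bearing images (both views of the affected breast); images without a
   usable mask are excluded and counted, never silently dropped.
4. **report** — the System / AUC / 95% CI / DSC (IQR) table as CSV + JSON, plus
   a run-metadata record of the seed, replicate count and every methodological
   convention (threshold rule, quantile rule, bootstrap type).

All randomness derives from one master seed via named sub-seeds; outputs are
byte-identical across reruns of the same config and fixture.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import io_formats as iof
from .detection import DetectionPerformance
from .exceptions import DegenerateInputError, ValidationError
from .matching import match_cases
from .overlap import SaliencyLocalization
from .seeding import derive_seed

__all__ = ["RunConfig", "run_experiment", "stage_match", "stage_score_eval",
           "stage_overlap", "stage_report"]

logger = logging.getLogger("salovlap")

METHOD_CONVENTIONS = {
    "threshold_rule": "pixels with saliency >= tau; tie-break to largest tau (smallest AOI)",
    "threshold_search": "exact search over all distinct saliency values (sorted sweep)",
    "normalization": "per-image min-max to [0,1]",
    "quantile_rule": "linear interpolation between order statistics",
    "bootstrap": "percentile, stratified by class (class counts preserved)",
    "significance": "95% CI strictly excludes 0.5",
    "dice": "2|A&B|/(|A|+|B|)",
}


@dataclass(frozen=True)
class RunConfig:
    """Everything one experiment run needs; the seed is mandatory."""

    dataset: Path
    out_dir: Path
    seed: int
    n_boot: int = 2000
    level: float = 0.95
    systems: Optional[Sequence[str]] = None  # None = all systems in the dataset
    aggregate_by_woman: bool = False
    cluster_by_woman: bool = False

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        raw = iof.read_config(path)
        merged = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
        if "seed" not in merged:
            raise ValidationError("config must set a seed (no silent nondeterminism)")
        systems = merged.get("systems")
        if isinstance(systems, str):
            systems = [s.strip() for s in systems.split(",") if s.strip()] or None
        return cls(
            dataset=Path(merged["dataset"]),
            out_dir=Path(merged.get("out_dir", "results")),
            seed=int(merged["seed"]),
            n_boot=int(merged.get("n_boot", 2000)),
            level=float(merged.get("level", 0.95)),
            systems=systems,
            aggregate_by_woman=_truthy(merged.get("aggregate_by_woman", False)),
            cluster_by_woman=_truthy(merged.get("cluster_by_woman", False)),
        )


def _truthy(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("1", "true", "yes", "on")


def _system_names(manifest: iof.DatasetManifest, config: RunConfig) -> List[str]:
    names = sorted(manifest.systems)
    if config.systems:
        unknown = set(config.systems) - set(names)
        if unknown:
            raise ValidationError(f"unknown systems requested: {sorted(unknown)}")
        names = sorted(config.systems)
    return names


# ---------------------------------------------------------------------------
# stage 1: matching


def stage_match(config: RunConfig) -> Optional[pd.DataFrame]:
    """Match cases to controls; write pairs and unmatched ids under out/matching.

    Returns None when the dataset has no cohort table (all images analyzed).
    """
    cohort_path = Path(config.dataset) / "cohort.csv"
    if not cohort_path.exists():
        return None
    cohort = iof.read_cohort(cohort_path)
    cases = [r for r in cohort if r.status == "case"]
    pool = [r for r in cohort if r.status == "control"]
    pairs, unmatched = match_cases(cases, pool, seed=derive_seed(config.seed, "matching"))
    out = Path(config.out_dir) / "matching"
    out.mkdir(parents=True, exist_ok=True)
    pairs_df = pd.DataFrame(
        {
            "case_id": [p.case_id for p in pairs],
            "control_id": [p.control_id for p in pairs],
            "birth_year": [p.key[0] for p in pairs],
            "screening_year": [p.key[1] for p in pairs],
            "system": [p.key[2] for p in pairs],
        }
    )
    pairs_df.to_csv(out / "pairs.csv", index=False)
    (out / "unmatched.csv").write_text(
        "case_id\n" + "".join(f"{u}\n" for u in unmatched), encoding="utf-8"
    )
    logger.info("matching: %d pairs, %d unmatched cases", len(pairs), len(unmatched))
    return pairs_df


def _matched_women(config: RunConfig) -> Optional[set]:
    pairs_path = Path(config.out_dir) / "matching" / "pairs.csv"
    if not pairs_path.exists():
        return None
    df = pd.read_csv(pairs_path, dtype=str)
    return set(df["case_id"]) | set(df["control_id"])


# ---------------------------------------------------------------------------
# stage 2: detection evaluation


def stage_score_eval(config: RunConfig, manifest: Optional[iof.DatasetManifest] = None) -> Dict[str, dict]:
    """Per-system AUC/CI/significance over images of matched women."""
    manifest = manifest or iof.DatasetManifest.load(config.dataset)
    women = _matched_women(config)
    out = Path(config.out_dir) / "detection"
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, dict] = {}
    for name in _system_names(manifest, config):
        scores = iof.read_scores(manifest.scores_path(name))
        if women is not None:
            scores = [s for s in scores if s.woman_id in women]
        model = DetectionPerformance(scores, aggregate_by_woman=config.aggregate_by_woman)
        fit = model.fit(
            n_boot=config.n_boot,
            level=config.level,
            seed=derive_seed(config.seed, f"bootstrap:{name}"),
            cluster_by_woman=config.cluster_by_woman,
        )
        row = fit.table_row()
        row["n_boot"] = config.n_boot
        row["level"] = config.level
        (out / f"{name}.json").write_text(
            json.dumps(row, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        logger.info("detection %s: %s", name, fit.summary_text())
        results[name] = row
    return results


# ---------------------------------------------------------------------------
# stage 3: saliency overlap


def stage_overlap(config: RunConfig, manifest: Optional[iof.DatasetManifest] = None) -> Dict[str, dict]:
    """Per-system optimal-threshold DSC on case-side lesion images.

    The submitted set is both views of each matched case's affected breast
    (identified by at least one segmented view); views without a usable mask
    are excluded and counted.
    """
    manifest = manifest or iof.DatasetManifest.load(config.dataset)
    women = _matched_women(config)
    pairs_path = Path(config.out_dir) / "matching" / "pairs.csv"
    case_women = (
        set(pd.read_csv(pairs_path, dtype=str)["case_id"]) if pairs_path.exists() else None
    )

    masked = [r for r in manifest.records if r.mask_path is not None]
    if case_women is not None:
        masked = [r for r in masked if r.woman_id in case_women]
    affected = {(r.woman_id, r.laterality) for r in masked}
    submitted = [
        r
        for r in manifest.records
        if (r.woman_id, r.laterality) in affected
        and (women is None or r.woman_id in women)
    ]

    out = Path(config.out_dir) / "overlap"
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, dict] = {}
    for name in _system_names(manifest, config):
        smaps, masks, ids, missing = [], [], [], []
        for rec in submitted:
            mask = iof.read_mask(rec.mask_path) if rec.mask_path is not None else None
            if mask is not None and not mask.empty:
                p = manifest.saliency_path(name, rec.image_id)
                if p is None:
                    missing.append(rec.image_id)
                    continue
                smaps.append(iof.read_saliency(p, expected_shape=mask.shape))
            else:
                smaps.append(None)
            masks.append(mask)
            ids.append(rec.image_id)
        if missing:
            raise ValidationError(
                f"system {name}: saliency missing for lesion images {missing}"
            )
        loc = _fit_localization(smaps, masks, ids)
        if loc is None:
            raise DegenerateInputError(
                f"system {name}: no images with usable masks; see the exclusion log"
            )
        loc.per_image.to_csv(out / f"{name}_per_image.csv", index=False)
        summary = loc.table_row()
        (out / f"{name}_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        (out / f"{name}_excluded.csv").write_text(
            "image_id\n" + "".join(f"{i}\n" for i in loc.excluded_ids), encoding="utf-8"
        )
        logger.info("overlap %s: %s", name, loc.summary_text())
        results[name] = summary
    return results


def _fit_localization(smaps, masks, ids):
    # saliency is only loaded for usable masks; feed a placeholder for excluded
    # images so the model counts them
    try:
        return SaliencyLocalization(smaps, masks, image_ids=ids).fit()
    except DegenerateInputError:
        return None


# ---------------------------------------------------------------------------
# stage 4: report


def stage_report(config: RunConfig) -> List[dict]:
    """Merge detection and overlap stage outputs into the final report files."""
    out = Path(config.out_dir)
    det_dir, ovl_dir = out / "detection", out / "overlap"
    rows = []
    for det_file in sorted(det_dir.glob("*.json")):
        name = det_file.stem
        det = json.loads(det_file.read_text(encoding="utf-8"))
        ovl_file = ovl_dir / f"{name}_summary.json"
        if not ovl_file.exists():
            raise ValidationError(
                f"system {name}: overlap summary missing; run the overlap stage "
                "(and check its exclusion log)"
            )
        ovl = json.loads(ovl_file.read_text(encoding="utf-8"))
        if ovl["n_overlap_images"] == 0:
            raise DegenerateInputError(
                f"system {name}: zero included overlap images; see the exclusion log"
            )
        rows.append(
            {
                "system": name,
                "auc": det["auc"],
                "ci_low": det["ci_low"],
                "ci_high": det["ci_high"],
                "significant": det["significant"],
                "n_cases": det["n_cases"],
                "n_controls": det["n_controls"],
                "median_dsc": ovl["median_dsc"],
                "median_dsc_percent": 100.0 * ovl["median_dsc"],
                "iqr_dsc": ovl["iqr_dsc"],
                "iqr_dsc_percent": 100.0 * ovl["iqr_dsc"],
                "n_overlap_images": ovl["n_overlap_images"],
                "n_excluded_images": ovl["n_excluded_images"],
            }
        )
    iof.write_report(rows, out / "report.csv", out / "report.json")
    metadata = {
        "seed": config.seed,
        "n_boot": config.n_boot,
        "level": config.level,
        "aggregate_by_woman": config.aggregate_by_woman,
        "cluster_by_woman": config.cluster_by_woman,
        "stage_seeds": {
            "matching": derive_seed(config.seed, "matching"),
            **{
                f"bootstrap:{r['system']}": derive_seed(config.seed, f"bootstrap:{r['system']}")
                for r in rows
            },
        },
        "conventions": METHOD_CONVENTIONS,
    }
    (out / "run_metadata.json").write_text(
        json.dumps(metadata, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return rows


# ---------------------------------------------------------------------------


def run_experiment(config: RunConfig) -> List[dict]:
    """Validate the dataset, run all four stages, return the report rows."""
    manifest = iof.DatasetManifest.load(config.dataset)
    manifest.validate()
    stage_match(config)
    stage_score_eval(config, manifest)
    stage_overlap(config, manifest)
    return stage_report(config)
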