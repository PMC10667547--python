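"""Per-image cancer-detection performance: ROC AUC with bootstrap confidence intervals.

Detection scores from a classifier are evaluated as a binary case/control problem.
The AUC is computed as the Mann–Whitney rank statistic — the fraction of
case–control pairs where the case scores higher, ties counting 1/2 — which equals
the trapezoidal area under the empirical ROC curve.  Uncertainty comes from a
stratified percentile bootstrap: cases and controls are resampled separately with
replacement (the case–control design fixes the class sizes), the AUC is recomputed
per replicate, and the central percentile interval is reported.  A system is called
significant at the 5% level when the 95% interval strictly excludes 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ValidationError

__all__ = [
    "Label",
    "ScoredImage",
    "AUCResult",
    "auc",
    "bootstrap_ci",
    "significance",
    "roc_points",
    "DetectionPerformance",
    "DetectionResults",
]

DEFAULT_N_BOOT = 2000


class Label(str, Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass(frozen=True)
class ScoredImage:
    """One image's detection score with its case/control label."""

    image_id: str
    score: float
    label: Label
    woman_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValidationError(f"non-finite score for image {self.image_id!r}")


@dataclass(frozen=True)
class AUCResult:
    """Point AUC with a percentile-bootstrap confidence interval.

    ``ci_low <= ci_high`` always holds; the point estimate is not guaranteed to
    lie inside a percentile interval in pathological cases, so that is not
    asserted.
    """

    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    level: float
    seed: int
    n_cases: int
    n_controls: int

    @property
    def significant(self) -> bool:
        return significance(self)


def _split(scores: Sequence) -> tuple:
    """Case and control score vectors from ScoredImage records or (score,label) pairs."""
    cases, controls = [], []
    for s in scores:
        if isinstance(s, ScoredImage):
            (cases if s.label == Label.CASE else controls).append(s.score)
        else:
            score, label = s
            (cases if str(label).strip().lower() == "case" else controls).append(score)
    return np.asarray(cases, dtype=float), np.asarray(controls, dtype=float)


def _rank_auc(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    n1, n0 = case_scores.size, control_scores.size
    ranks = rankdata(np.concatenate([case_scores, control_scores]))
    return (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def auc(scores: Sequence) -> float:
    """Mann–Whitney AUC over all case–control score pairs (ties count 1/2)."""
    case_scores, control_scores = _split(scores)
    if case_scores.size == 0 or control_scores.size == 0:
        raise ValidationError("AUC requires at least one case and one control")
    if not (np.all(np.isfinite(case_scores)) and np.all(np.isfinite(control_scores))):
        raise ValidationError("scores must be finite")
    return float(_rank_auc(case_scores, control_scores))


def bootstrap_ci(
    scores: Sequence,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = 0.95,
    seed: int = 0,
    clusters: Optional[Sequence] = None,
) -> AUCResult:
    """Stratified percentile-bootstrap confidence interval for the AUC.

    Cases and controls are resampled separately with replacement, preserving the
    class counts, so no replicate can lose a class.  With ``clusters`` given
    (e.g. woman ids), whole clusters are resampled within each class instead of
    individual images, accounting for within-woman correlation.
    Deterministic given ``seed``.
    """
    case_scores, control_scores = _split(scores)
    if case_scores.size == 0 or control_scores.size == 0:
        raise ValidationError("AUC requires at least one case and one control")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    point = float(_rank_auc(case_scores, control_scores))

    if clusters is None:
        boot_aucs = _bootstrap_images(case_scores, control_scores, n_boot, rng)
    else:
        boot_aucs = _bootstrap_clusters(scores, clusters, n_boot, rng)

    alpha = 1.0 - level
    lo, hi = np.quantile(boot_aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return AUCResult(
        auc=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=int(n_boot),
        level=float(level),
        seed=int(seed),
        n_cases=int(case_scores.size),
        n_controls=int(control_scores.size),
    )


def _bootstrap_images(case_scores, control_scores, n_boot, rng) -> np.ndarray:
    """Vectorized replicate AUCs: rank each resampled row in one pass."""
    n1, n0 = case_scores.size, control_scores.size
    rep_cases = case_scores[rng.integers(0, n1, size=(n_boot, n1))]
    rep_controls = control_scores[rng.integers(0, n0, size=(n_boot, n0))]
    combined = np.concatenate([rep_cases, rep_controls], axis=1)
    ranks = rankdata(combined, axis=1)
    return (ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _bootstrap_clusters(scores, clusters, n_boot, rng) -> np.ndarray:
    recs = list(scores)
    clusters = list(clusters)
    if len(clusters) != len(recs):
        raise ValidationError("clusters must parallel scores")
    by_cluster: dict = {}
    is_case: dict = {}
    for rec, cl in zip(recs, clusters):
        s, lab = (
            (rec.score, rec.label.value) if isinstance(rec, ScoredImage) else rec
        )
        by_cluster.setdefault(cl, []).append(float(s))
        is_case[cl] = str(lab).strip().lower() == "case"
    case_cl = sorted(cl for cl in by_cluster if is_case[cl])
    ctrl_cl = sorted(cl for cl in by_cluster if not is_case[cl])
    out = np.empty(n_boot)
    for b in range(n_boot):
        cs = np.concatenate(
            [by_cluster[case_cl[i]] for i in rng.integers(0, len(case_cl), len(case_cl))]
        )
        ct = np.concatenate(
            [by_cluster[ctrl_cl[i]] for i in rng.integers(0, len(ctrl_cl), len(ctrl_cl))]
        )
        out[b] = _rank_auc(cs, ct)
    return out


def significance(result: AUCResult) -> bool:
    """Two-sided 5% significance call: the 95% CI strictly excludes 0.5."""
    return bool(result.ci_low > 0.5 or result.ci_high < 0.5)


def roc_points(scores: Sequence) -> pd.DataFrame:
    """Empirical ROC coordinates (FPR, TPR) at every distinct score cut."""
    case_scores, control_scores = _split(scores)
    thresholds = np.unique(np.concatenate([case_scores, control_scores]))[::-1]
    tpr = [(case_scores >= t).mean() for t in thresholds]
    fpr = [(control_scores >= t).mean() for t in thresholds]
    return pd.DataFrame(
        {"threshold": np.concatenate([[np.inf], thresholds]),
         "fpr": [0.0] + fpr,
         "tpr": [0.0] + tpr}
    )


class DetectionPerformance:
    """Detection-performance model for one system's per-image scores.

    Parameters
    ----------
    scores : sequence of ScoredImage (or (score, label) pairs)
    aggregate_by_woman : take the maximum score over each woman's images and
        evaluate per woman instead of per image (off by default; the per-image
        analysis is the primary unit).
    """

    def __init__(self, scores: Sequence, aggregate_by_woman: bool = False):
        self.scores = list(scores)
        self.aggregate_by_woman = aggregate_by_woman

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DetectionPerformance":
        """Build from a table with columns image_id, woman_id, label, score."""
        recs = [
            ScoredImage(
                image_id=str(r.image_id),
                woman_id=str(getattr(r, "woman_id", "")),
                score=float(r.score),
                label=Label(str(r.label).strip().lower()),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(recs, **kwargs)

    def _analysis_units(self):
        if not self.aggregate_by_woman:
            return self.scores
        best: dict = {}
        for s in self.scores:
            key = (s.woman_id, s.label)
            if key not in best or s.score > best[key].score:
                best[key] = s
        return list(best.values())

    def fit(
        self,
        n_boot: int = DEFAULT_N_BOOT,
        level: float = 0.95,
        seed: int = 0,
        cluster_by_woman: bool = False,
    ) -> "DetectionResults":
        units = self._analysis_units()
        clusters = None
        if cluster_by_woman:
            clusters = [s.woman_id for s in units]
        result = bootstrap_ci(units, n_boot=n_boot, level=level, seed=seed, clusters=clusters)
        return DetectionResults(result=result, roc=roc_points(units))


@dataclass(frozen=True)
class DetectionResults:
    """Fitted detection performance: AUC, CI, significance and ROC coordinates."""

    result: AUCResult
    roc: pd.DataFrame

    @property
    def auc(self) -> float:
        return self.result.auc

    @property
    def ci(self) -> tuple:
        return (self.result.ci_low, self.result.ci_high)

    @property
    def significant(self) -> bool:
        return self.result.significant

    def table_row(self) -> dict:
        r = self.result
        return {
            "auc": r.auc,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "significant": r.significant,
            "n_cases": r.n_cases,
            "n_controls": r.n_controls,
        }

    def summary_text(self) -> str:
        r = self.result
        star = "significant" if r.significant else "not significant"
        return (
            f"AUC {r.auc:.3f} (95% CI {r.ci_low:.3f}–{r.ci_high:.3f}), "
            f"{r.n_cases} cases / {r.n_controls} controls, "
            f"{r.n_boot} bootstrap replicates — {star} vs 0.5"
        )
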