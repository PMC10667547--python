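"""Case–control matching on exact covariate keys.

Each screen-detected cancer case is paired 1:1 with a healthy control sharing the
exact key (birth year, screening year, mammographic system).  No caliper is
applied: the keys are matched exactly.  When several control candidates share a
key, the selection is a seeded random permutation so results are deterministic
and invariant to input ordering.  Unmatched cases are reported, never dropped
silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["CohortRecord", "MatchedPair", "match_cases", "cohort_summary", "AGE_BANDS"]

# Age bands used for cohort description; lower bound inclusive.
AGE_BANDS = ("<55", "55–59", "60–64", ">64")


@dataclass(frozen=True)
class CohortRecord:
    """One woman: matching keys plus case/control status.

    ``cancer_type`` is present iff the woman is a case; ``system`` is the
    mammographic vendor (free string, conventionally "PH" or "GE").
    """

    woman_id: str
    status: str  # "case" | "control"
    birth_year: int
    screening_year: int
    system: str
    cancer_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValidationError(f"unknown status {self.status!r}")
        if self.screening_year < self.birth_year:
            raise ValidationError(
                f"{self.woman_id}: screening_year {self.screening_year} precedes "
                f"birth_year {self.birth_year}"
            )
        if (self.cancer_type is not None) != (self.status == "case"):
            raise ValidationError(
                f"{self.woman_id}: cancer_type must be present iff status is case"
            )

    @property
    def key(self) -> Tuple[int, int, str]:
        return (self.birth_year, self.screening_year, self.system)

    @property
    def age(self) -> int:
        return self.screening_year - self.birth_year


@dataclass(frozen=True)
class MatchedPair:
    case_id: str
    control_id: str
    key: Tuple[int, int, str]


def match_cases(
    cases: Sequence[CohortRecord],
    pool: Sequence[CohortRecord],
    seed: int,
) -> Tuple[List[MatchedPair], List[str]]:
    """1:1 exact matching of cases to control candidates on (birth year,
    screening year, system).

    Candidates within a key are consumed in seeded-random-permutation order;
    cases are processed in sorted woman_id order, so the output depends only on
    the record *sets* and the seed, not on input ordering.  Returns the pairs
    and the ids of cases with no remaining candidate at their key.
    """
    ids = [r.woman_id for r in cases] + [r.woman_id for r in pool]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate woman_id across cases/pool")
    for r in pool:
        if r.status != "control":
            raise ValidationError(f"pool record {r.woman_id} is not a control candidate")

    rng = np.random.default_rng(seed)
    by_key: dict = {}
    for r in sorted(pool, key=lambda r: r.woman_id):
        by_key.setdefault(r.key, []).append(r.woman_id)
    # permute each key's canonical candidate list; iterate keys in sorted order
    # so the rng stream is independent of dict insertion order
    queues = {k: list(rng.permutation(by_key[k])) for k in sorted(by_key)}

    pairs: List[MatchedPair] = []
    unmatched: List[str] = []
    for case in sorted(cases, key=lambda r: r.woman_id):
        q = queues.get(case.key)
        if q:
            pairs.append(MatchedPair(case.woman_id, q.pop(0), case.key))
        else:
            unmatched.append(case.woman_id)
    return pairs, unmatched


def _age_band(age: int) -> str:
    if age < 55:
        return AGE_BANDS[0]
    if age <= 59:
        return AGE_BANDS[1]
    if age <= 64:
        return AGE_BANDS[2]
    return AGE_BANDS[3]


def cohort_summary(records: Iterable[CohortRecord]) -> pd.DataFrame:
    """Tidy count table by age band, mammographic system and cancer type.

    Age is screening_year − birth_year.  Percentages are within status group,
    rounded to the nearest integer (cancer-type percentages among cases only).
    """
    recs = list(records)
    rows = []
    for status in ("case", "control"):
        group = [r for r in recs if r.status == status]
        n = len(group)
        if n == 0:
            continue
        for band in AGE_BANDS:
            c = sum(1 for r in group if _age_band(r.age) == band)
            rows.append((status, "age", band, c, round(100.0 * c / n)))
        for system in sorted({r.system for r in recs}):
            c = sum(1 for r in group if r.system == system)
            rows.append((status, "system", system, c, round(100.0 * c / n)))
        if status == "case":
            for ct in sorted({r.cancer_type for r in group}):
                c = sum(1 for r in group if r.cancer_type == ct)
                rows.append((status, "cancer_type", ct, c, round(100.0 * c / n)))
    return pd.DataFrame(
        rows, columns=["status", "characteristic", "level", "count", "percent"]
    )
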