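"""Cut-off derivation and modified nuclear scoring.

The modified grading system scores each case 1–3 on two calibrated
variables — largest nuclear size (LNS) and nuclear size difference (NSD) —
using cut-offs anchored to the moderate-pleomorphism (grade-2) reference
group: ``lower/upper = mean ∓ sd_multiplier·SD`` of the reference group's
variable.  A value below ``lower`` scores 1, inside the closed interval
``[lower, upper]`` scores 2, above ``upper`` scores 3.  The two per-variable
scores are then combined into the final modified nuclear grade.

Cut-offs are derived once on a training cohort and serialized; validation
cohorts are scored with the frozen cut-offs, never re-derived.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateStatisticsError, InputError
from .measurement import CaseRecord

VARIABLES = ("lns", "nsd")
COMBINATION_RULES = ("rounded_mean_up", "max", "lns_priority")


@dataclass(frozen=True)
class CutoffSet:
    """Three-class thresholds for one variable, with derivation provenance."""

    variable: str
    lower: float
    upper: float
    reference_grade: int
    reference_mean: float
    reference_sd: float
    sd_multiplier: float
    n_reference: int = 0
    cohort_hash: str = ""

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise InputError(f"variable must be one of {VARIABLES}, got {self.variable!r}")
        if not self.lower < self.upper:
            raise DegenerateStatisticsError(
                f"{self.variable}: lower ({self.lower}) must be < upper ({self.upper})"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "CutoffSet":
        return cls(**payload)


def cohort_hash(cases: Sequence[CaseRecord]) -> str:
    """Stable sha256 digest of a cohort, for cut-off provenance."""
    digest = hashlib.sha256()
    for c in cases:
        digest.update(
            f"{c.case_id},{c.sns!r},{c.lns!r},{c.original_score}\n".encode()
        )
    return digest.hexdigest()[:16]


def derive_cutoffs(
    cases: Sequence[CaseRecord],
    variable: str,
    reference_grade: int = 2,
    sd_multiplier: float = 1.0,
) -> CutoffSet:
    """Derive mean ± sd_multiplier·SD cut-offs from the reference-grade cases.

    SD is the sample SD (n−1 denominator).  Raises
    :class:`DegenerateStatisticsError` with fewer than 2 reference cases,
    zero variance, or a non-positive multiplier (lower = upper).
    """
    if variable not in VARIABLES:
        raise InputError(f"variable must be one of {VARIABLES}, got {variable!r}")
    values = np.array(
        [getattr(c, variable) for c in cases if c.original_score == reference_grade]
    )
    if len(values) < 2:
        raise DegenerateStatisticsError(
            f"need >= 2 cases with original_score == {reference_grade}, "
            f"found {len(values)}"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise DegenerateStatisticsError(
            f"{variable}: reference grade {reference_grade} has zero variance"
        )
    return CutoffSet(
        variable=variable,
        lower=mean - sd_multiplier * sd,
        upper=mean + sd_multiplier * sd,
        reference_grade=reference_grade,
        reference_mean=mean,
        reference_sd=sd,
        sd_multiplier=sd_multiplier,
        n_reference=len(values),
        cohort_hash=cohort_hash(cases),
    )


def score_variable(value: float, cutoffs: CutoffSet) -> int:
    """Score one value against a cut-off set (closed middle interval)."""
    if not (math.isfinite(value) and value >= 0):
        raise InputError(f"value must be finite and non-negative, got {value!r}")
    if value < cutoffs.lower:
        return 1
    if value > cutoffs.upper:
        return 3
    return 2


def combine_scores(score_lns: int, score_nsd: int, rule: str = "rounded_mean_up") -> int:
    """Combine the two per-variable scores into the modified nuclear grade.

    Rules: ``rounded_mean_up`` (mean, .5 ties toward the higher grade —
    clinically conservative), ``max`` (worst of the two), ``lns_priority``
    (the LNS-based score decides).
    """
    for s in (score_lns, score_nsd):
        if s not in (1, 2, 3):
            raise InputError(f"scores must be in {{1,2,3}}, got {s!r}")
    if rule == "rounded_mean_up":
        return int(math.floor((score_lns + score_nsd) / 2 + 0.5))
    if rule == "max":
        return max(score_lns, score_nsd)
    if rule == "lns_priority":
        return score_lns
    raise InputError(f"unknown combination rule {rule!r}; use one of {COMBINATION_RULES}")


@dataclass(frozen=True)
class GradeAssignment:
    """Per-case modified scores."""

    case_id: str
    score_lns: int
    score_nsd: int
    score_combined: int
    original_score: int | None = None

    def __post_init__(self) -> None:
        for s in (self.score_lns, self.score_nsd, self.score_combined):
            if s not in (1, 2, 3):
                raise InputError(f"scores must be in {{1,2,3}}, got {s!r}")


def apply_grading(
    cases: Sequence[CaseRecord],
    cutoffs_lns: CutoffSet,
    cutoffs_nsd: CutoffSet,
    rule: str = "rounded_mean_up",
) -> tuple[list[GradeAssignment], pd.DataFrame]:
    """Score every case and tabulate the grade distribution.

    Returns the per-case assignments and a distribution table with one row
    per grade 1–3 and count/percentage columns for the LNS-based, NSD-based
    and combined scorings (plus the original grading when present).
    """
    if cutoffs_lns.variable != "lns" or cutoffs_nsd.variable != "nsd":
        raise InputError("cutoff sets passed in the wrong order (want lns, nsd)")
    assignments = []
    for c in cases:
        s_lns = score_variable(c.lns, cutoffs_lns)
        s_nsd = score_variable(c.nsd, cutoffs_nsd)
        assignments.append(
            GradeAssignment(
                case_id=c.case_id,
                score_lns=s_lns,
                score_nsd=s_nsd,
                score_combined=combine_scores(s_lns, s_nsd, rule),
                original_score=c.original_score,
            )
        )

    n = len(assignments)
    table = {"grade": [1, 2, 3]}
    columns = {
        "lns": [a.score_lns for a in assignments],
        "nsd": [a.score_nsd for a in assignments],
        "combined": [a.score_combined for a in assignments],
    }
    originals = [a.original_score for a in assignments if a.original_score is not None]
    if originals:
        columns["original"] = originals
    for name, scores in columns.items():
        counts = [scores.count(g) for g in (1, 2, 3)]
        table[f"{name}_n"] = counts
        table[f"{name}_pct"] = [100 * c / len(scores) if scores else 0.0 for c in counts]
    frame = pd.DataFrame(table)
    assert n == 0 or frame["combined_n"].sum() == n
    return assignments, frame


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_cutoffs_json(
    cutoffs: Iterable[CutoffSet], path: str | Path
) -> None:
    payload = {c.variable: c.to_dict() for c in cutoffs}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_cutoffs_json(path: str | Path) -> dict[str, CutoffSet]:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        return {var: CutoffSet.from_dict(d) for var, d in payload.items()}
    except TypeError as exc:
        raise InputError(f"{path}: malformed cutoff JSON ({exc})") from exc


GRADED_COLUMNS = ("case_id", "score_lns", "score_nsd", "score_combined", "original_score")


def write_graded_csv(assignments: Iterable[GradeAssignment], path: str | Path) -> None:
    rows = [
        {
            "case_id": a.case_id,
            "score_lns": a.score_lns,
            "score_nsd": a.score_nsd,
            "score_combined": a.score_combined,
            "original_score": a.original_score,
        }
        for a in assignments
    ]
    frame = pd.DataFrame(rows, columns=list(GRADED_COLUMNS))
    frame["original_score"] = frame["original_score"].astype("Int64")
    frame.to_csv(path, index=False)


def read_graded_csv(path: str | Path) -> list[GradeAssignment]:
    frame = pd.read_csv(path)
    missing = set(GRADED_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"{path}: graded CSV missing columns {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        score = None if pd.isna(row.original_score) else int(row.original_score)
        out.append(
            GradeAssignment(
                case_id=str(row.case_id),
                score_lns=int(row.score_lns),
                score_nsd=int(row.score_nsd),
                score_combined=int(row.score_combined),
                original_score=score,
            )
        )
    return out
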