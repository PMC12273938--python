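"""Two-phase study orchestration.

Phase 1 (training): per-variable descriptives, normality tests and one-way
ANOVA across the original nuclear grades; derivation of the LNS and NSD
cut-offs from the grade-2 reference group; regrading of the training cohort
with distribution tables and training agreement.  The cut-offs are frozen
(serialized) at the end of phase 1.

Phase 2 (validation): the frozen cut-offs are applied to an independent
cohort — no statistic of the validation set feeds back into the cut-offs —
and agreement with the pathologists' original scores is reported for the
LNS-based, NSD-based and combined scorings.

Reports embed the raw confusion matrices so every headline number can be
recomputed downstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

from . import __version__
from .agreement import cohen_kappa, confusion_matrix, fisher_exact_rxc
from .errors import InputError
from .grading import (
    COMBINATION_RULES,
    CutoffSet,
    GradeAssignment,
    apply_grading,
    derive_cutoffs,
)
from .measurement import CaseRecord
from .stats import anova_oneway_raw, describe, ks_lilliefors, shapiro_wilk

logger = logging.getLogger(__name__)

VARIABLES = ("sns", "lns", "nsd")
SCORINGS = ("lns", "nsd", "combined")


@dataclass(frozen=True)
class RunConfig:
    """Knobs of the full pipeline, with the defaults the method was built on."""

    calibration: float = 6.5        # µm per pixel
    k_extreme: int = 3              # nuclei averaged into LNS / SNS
    sd_multiplier: float = 1.0      # half-width of the grade-2 band, in SDs
    combination_rule: str = "rounded_mean_up"
    reference_grade: int = 2
    seed: int = 0
    lilliefors_reps: int = 2000
    report_formats: tuple[str, ...] = ("json",)

    def __post_init__(self) -> None:
        if self.calibration <= 0:
            raise InputError("calibration must be > 0")
        if not 1 <= self.k_extreme <= 10:
            raise InputError("k_extreme must be in 1..10")
        if self.sd_multiplier <= 0:
            raise InputError("sd_multiplier must be > 0")
        if self.combination_rule not in COMBINATION_RULES:
            raise InputError(
                f"combination_rule must be one of {COMBINATION_RULES}"
            )
        if self.reference_grade not in (1, 2, 3):
            raise InputError("reference_grade must be in {1,2,3}")
        unknown = set(self.report_formats) - {"json", "markdown"}
        if unknown:
            raise InputError(f"unknown report formats {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["report_formats"] = list(self.report_formats)
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise InputError(f"{path}: unknown config keys {sorted(unknown)}")
        if "report_formats" in payload:
            payload["report_formats"] = tuple(payload["report_formats"])
        return cls(**payload)

    def content_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:16]


@dataclass(frozen=True)
class StudyReport:
    """Machine-readable results of one phase; JSON-native throughout."""

    phase: str
    n_cases: int
    descriptives: dict
    normality: dict
    anova: dict
    cutoffs: dict
    distribution: list
    agreement: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "StudyReport":
        return cls(**payload)


def _summary_block(cases: Sequence[CaseRecord], seed: int, mc_reps: int) -> tuple[dict, dict]:
    descriptives: dict = {}
    normality: dict = {}
    for i, var in enumerate(VARIABLES):
        values = [getattr(c, var) for c in cases]
        lo, hi, mean, sd = describe(values)
        descriptives[var] = {"n": len(values), "min": lo, "max": hi, "mean": mean, "sd": sd}
        w, p_sw = shapiro_wilk(values)
        d, p_ks = ks_lilliefors(values, mc_reps=mc_reps, seed=seed + 7919 * (i + 1))
        normality[var] = {
            "shapiro_w": w,
            "shapiro_p": p_sw,
            "lilliefors_d": d,
            "lilliefors_p": p_ks,
        }
    return descriptives, normality


def _anova_block(cases: Sequence[CaseRecord]) -> dict:
    out: dict = {}
    grades = sorted({c.original_score for c in cases})
    for var in VARIABLES:
        groups = [
            [getattr(c, var) for c in cases if c.original_score == g] for g in grades
        ]
        res = anova_oneway_raw(groups, labels=grades)
        out[var] = {
            "f_stat": res.f_stat,
            "df_between": res.df_between,
            "df_within": res.df_within,
            "p_value": res.p_value,
            "groups": [dataclasses.asdict(s) for s in res.group_summaries],
            "pairwise": [
                {
                    "pair": list(pc.pair),
                    "mean_difference": pc.mean_difference,
                    "t_stat": pc.t_stat,
                    "raw_p": pc.raw_p,
                    "bonferroni_p": pc.bonferroni_p,
                }
                for pc in res.pairwise
            ],
        }
    return out


def _agreement_block(
    assignments: Sequence[GradeAssignment], config: RunConfig
) -> dict:
    out: dict = {}
    for i, scoring in enumerate(SCORINGS):
        m = confusion_matrix(assignments, score=scoring)
        result = cohen_kappa(m)
        fisher_p, fisher_se = fisher_exact_rxc(
            m, method="auto", seed=config.seed + 104729 * (i + 1)
        )
        block = result.to_dict()
        block["fisher_p"] = fisher_p
        if fisher_se is not None:
            block["fisher_mc_se"] = fisher_se
        out[scoring] = block
    return out


def _provenance(config: RunConfig, phase: str) -> dict:
    return {
        "phase": phase,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def _require_scored(cases: Sequence[CaseRecord], phase: str) -> None:
    unscored = [c.case_id for c in cases if c.original_score is None]
    if unscored:
        raise InputError(
            f"{phase}: {len(unscored)} cases lack an original score "
            f"(first: {unscored[:3]})"
        )


def run_phase1(
    train_cases: Sequence[CaseRecord], config: RunConfig = RunConfig()
) -> tuple[dict[str, CutoffSet], StudyReport]:
    """Training phase: analyse, derive cut-offs, regrade, report."""
    if not train_cases:
        raise InputError("phase 1: empty training cohort")
    _require_scored(train_cases, "phase 1")
    logger.info("phase 1: %d training cases", len(train_cases))

    descriptives, normality = _summary_block(
        train_cases, config.seed, config.lilliefors_reps
    )
    anova = _anova_block(train_cases)
    cutoffs = {
        var: derive_cutoffs(
            train_cases,
            variable=var,
            reference_grade=config.reference_grade,
            sd_multiplier=config.sd_multiplier,
        )
        for var in ("lns", "nsd")
    }
    logger.info(
        "cut-offs: LNS [%.2f, %.2f] µm, NSD [%.2f, %.2f] µm",
        cutoffs["lns"].lower, cutoffs["lns"].upper,
        cutoffs["nsd"].lower, cutoffs["nsd"].upper,
    )
    assignments, dist = apply_grading(
        train_cases, cutoffs["lns"], cutoffs["nsd"], rule=config.combination_rule
    )
    agreement = _agreement_block(assignments, config)
    report = StudyReport(
        phase="phase1",
        n_cases=len(train_cases),
        descriptives=descriptives,
        normality=normality,
        anova=anova,
        cutoffs={var: c.to_dict() for var, c in cutoffs.items()},
        distribution=dist.to_dict(orient="records"),
        agreement=agreement,
        provenance=_provenance(config, "phase1"),
    )
    return cutoffs, report


def run_phase2(
    validation_cases: Sequence[CaseRecord],
    cutoffs: dict[str, CutoffSet],
    config: RunConfig = RunConfig(),
) -> StudyReport:
    """Validation phase: apply frozen cut-offs, report agreement.

    Performs no statistic that depends on the validation set's reference
    group; the cut-offs are used exactly as supplied.
    """
    if not validation_cases:
        raise InputError("phase 2: empty validation cohort")
    if set(cutoffs) != {"lns", "nsd"} or not all(
        isinstance(c, CutoffSet) for c in cutoffs.values()
    ):
        raise InputError("phase 2: expected frozen cutoffs {'lns': ..., 'nsd': ...}")
    _require_scored(validation_cases, "phase 2")
    logger.info("phase 2: %d validation cases", len(validation_cases))

    descriptives, normality = _summary_block(
        validation_cases, config.seed, config.lilliefors_reps
    )
    assignments, dist = apply_grading(
        validation_cases, cutoffs["lns"], cutoffs["nsd"], rule=config.combination_rule
    )
    agreement = _agreement_block(assignments, config)
    return StudyReport(
        phase="phase2",
        n_cases=len(validation_cases),
        descriptives=descriptives,
        normality=normality,
        anova={},
        cutoffs={var: c.to_dict() for var, c in cutoffs.items()},
        distribution=dist.to_dict(orient="records"),
        agreement=agreement,
        provenance=_provenance(config, "phase2"),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _markdown_matrix(name: str, block: dict) -> list[str]:
    lines = [
        f"### {name.upper()} scoring",
        "",
        "| modified \\ original | 1 | 2 | 3 |",
        "|---|---|---|---|",
    ]
    for i, row in enumerate(block["matrix"], start=1):
        lines.append("| " + " | ".join([str(i)] + [str(v) for v in row]) + " |")
    lines += [
        "",
        f"kappa = {block['kappa']:.3f} ({block['interpretation']}), "
        f"p = {block['p_value']:.4g}; concordant {block['concordant_pct']:.1f}%, "
        f"adjacent discordant {block['adjacent_discordant']}, "
        f"critical discordant {block['critical_discordant']}.",
        "",
    ]
    return lines


def render_report(
    report: StudyReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("json",),
) -> list[Path]:
    """Write the report as JSON (always available) and optional Markdown."""
    unknown = set(formats) - {"json", "markdown"}
    if unknown:
        raise InputError(f"unknown report formats {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        path = out_dir / f"report_{report.phase}.json"
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    if "markdown" in formats:
        lines = [f"# Study report — {report.phase}", "", f"Cases: {report.n_cases}", ""]
        if report.cutoffs:
            lines.append("## Cut-offs")
            lines.append("")
            for var, c in sorted(report.cutoffs.items()):
                lines.append(
                    f"- {var.upper()}: [{c['lower']:.2f}, {c['upper']:.2f}] µm "
                    f"(grade-{c['reference_grade']} mean {c['reference_mean']:.2f} "
                    f"± {c['sd_multiplier']:g} × SD {c['reference_sd']:.2f})"
                )
            lines.append("")
        lines.append("## Agreement with the original scores")
        lines.append("")
        for scoring in SCORINGS:
            if scoring in report.agreement:
                lines += _markdown_matrix(scoring, report.agreement[scoring])
        path = out_dir / f"report_{report.phase}.md"
        path.write_text("\n".join(lines))
        written.append(path)
    return written


def load_report(path: str | Path) -> StudyReport:
    with open(path) as fh:
        return StudyReport.from_dict(json.load(fh))
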