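"""Nuclear diameter measurement from outlines or label masks.

A nucleus is represented by its boundary polygon in pixel coordinates
(origin top-left, x rightward, y downward, pixel-center convention).  Its
size is the *geometric diameter* of that polygon: the maximum Euclidean
distance between any two boundary points, mirroring a pathologist dragging
a ruler from one pole of the nuclear membrane to the opposite pole.

Per tumor case the nuclei are reduced to three calibrated variables:

LNS (largest nuclear size)
    mean of the ``k_extreme`` largest diameters, in µm;
SNS (smallest nuclear size)
    mean of the ``k_extreme`` smallest diameters, in µm;
NSD (nuclear size difference)
    LNS − SNS, the per-case spread of nuclear size.

Nuclei flagged as crushed/obscured, multinucleated or with an incomplete
membrane are excluded before the reduction.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString

from .errors import InputError

logger = logging.getLogger(__name__)

#: Quality flags that exclude a nucleus from measurement.
EXCLUSION_FLAGS = frozenset(
    {"incomplete_membrane", "multinucleated", "crushed_or_obscured"}
)

#: Columns of the cohort CSV schema, in order.
COHORT_COLUMNS = ("case_id", "sns_um", "lns_um", "nsd_um", "original_score")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Pixel-to-micron conversion factor.

    The default of 6.5 µm per pixel follows the imaging setup the grading
    thresholds were developed on; it is deliberately a free parameter
    because calibrations differ between microscope/camera installations.
    """

    microns_per_pixel: float = 6.5

    def __post_init__(self) -> None:
        if not (self.microns_per_pixel > 0 and math.isfinite(self.microns_per_pixel)):
            raise InputError(
                f"microns_per_pixel must be positive and finite, "
                f"got {self.microns_per_pixel!r}"
            )


@dataclass(frozen=True)
class NucleusOutline:
    """Ordered boundary points of one nucleus in continuous pixel coordinates."""

    nucleus_id: str
    points: tuple[tuple[float, float], ...]
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple((float(x), float(y)) for x, y in self.points))
        object.__setattr__(self, "flags", frozenset(self.flags))
        unknown = self.flags - EXCLUSION_FLAGS
        if unknown:
            raise InputError(f"unknown quality flags {sorted(unknown)}")

    @property
    def excluded(self) -> bool:
        return bool(self.flags & EXCLUSION_FLAGS)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


@dataclass(frozen=True)
class CaseRecord:
    """One tumor case: the pipeline's atomic row.

    ``original_score`` is the nuclear pleomorphism score (1 mild, 2 moderate,
    3 marked) assigned by the reporting pathologist; ``None`` for unscored
    cases.
    """

    case_id: str
    sns: float
    lns: float
    nsd: float
    original_score: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.sns <= self.lns):
            raise InputError(
                f"case {self.case_id!r}: need 0 < SNS <= LNS, "
                f"got SNS={self.sns}, LNS={self.lns}"
            )
        if self.nsd != self.lns - self.sns:
            raise InputError(
                f"case {self.case_id!r}: NSD must equal LNS - SNS exactly "
                f"({self.nsd} != {self.lns - self.sns})"
            )
        if self.original_score is not None and self.original_score not in (1, 2, 3):
            raise InputError(
                f"case {self.case_id!r}: original_score must be in {{1,2,3}}, "
                f"got {self.original_score!r}"
            )

    @classmethod
    def from_sizes(
        cls, case_id: str, sns: float, lns: float, original_score: int | None = None
    ) -> "CaseRecord":
        """Build a record with NSD set to LNS − SNS exactly."""
        return cls(case_id=case_id, sns=sns, lns=lns, nsd=lns - sns,
                   original_score=original_score)


# ---------------------------------------------------------------------------
# Diameter geometry
# ---------------------------------------------------------------------------

def validate_outline(outline: NucleusOutline) -> None:
    """Raise :class:`InputError` if the outline is not a simple polygon.

    Consecutive duplicate vertices are tolerated (they cannot change the
    diameter); genuine self-intersections (bow-ties etc.) are rejected.
    """
    pts = outline.as_array()
    if len(pts) < 3:
        raise InputError(
            f"nucleus {outline.nucleus_id!r}: outline needs >= 3 points, has {len(pts)}"
        )
    # collapse consecutive duplicates before the simplicity check
    keep = np.ones(len(pts), bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    dedup = pts[keep]
    if len(dedup) < 3:
        raise InputError(
            f"nucleus {outline.nucleus_id!r}: fewer than 3 distinct points"
        )
    ring = LineString(np.vstack([dedup, dedup[:1]]))
    if not ring.is_simple:
        raise InputError(
            f"nucleus {outline.nucleus_id!r}: outline polygon self-intersects"
        )


def longest_axis(outline: NucleusOutline, *, validate: bool = True) -> float:
    """Polygon diameter in pixels: max pairwise distance between boundary points.

    Uses the convex hull to prune candidates (the diameter of a point set is
    attained between hull vertices), so the result is identical to the
    O(n²) brute-force maximum over all vertex pairs.
    """
    if validate:
        validate_outline(outline)
    pts = np.unique(outline.as_array(), axis=0)
    if len(pts) < 2:
        raise InputError(f"nucleus {outline.nucleus_id!r}: degenerate outline")
    if len(pts) > 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # collinear-ish input: fall through to all-pairs
    diffs = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diffs**2).sum(axis=-1)).max())


# ---------------------------------------------------------------------------
# Mask -> outlines (Moore-neighbor boundary tracing)
# ---------------------------------------------------------------------------

# clockwise Moore neighborhood as (dr, dc), starting west
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _trace_boundary(binary: np.ndarray) -> np.ndarray:
    """Ordered boundary pixel centers of the True region, as (row, col).

    Moore-neighbor tracing with Jacob's stopping criterion.  The region is
    assumed 8-connected; a single-pixel region yields a single point.
    """
    rows, cols = np.nonzero(binary)
    start = (int(rows[0]), int(cols[0]))  # first foreground pixel, raster order
    padded = np.zeros((binary.shape[0] + 2, binary.shape[1] + 2), bool)
    padded[1:-1, 1:-1] = binary
    sr, sc = start[0] + 1, start[1] + 1

    boundary = [(sr, sc)]
    # entered the start pixel from the west (raster scan guarantees the
    # pixel west of start is background)
    prev_dir = 0
    cur = (sr, sc)
    first_move: tuple[int, int] | None = None
    while True:
        found = False
        for i in range(8):
            d = (prev_dir + i) % 8
            dr, dc = _MOORE[d]
            nxt = (cur[0] + dr, cur[1] + dc)
            if padded[nxt]:
                if cur == (sr, sc):
                    if first_move is None:
                        first_move = nxt
                    elif nxt == first_move:
                        # re-entered start the same way: contour closed
                        pts = np.array(boundary[:-1]) - 1
                        return pts
                boundary.append(nxt)
                cur = nxt
                # back up: next search starts from the direction we came from
                prev_dir = (d + 5) % 8
                found = True
                break
        if not found:  # isolated pixel
            return np.array([start])
        if len(boundary) > 8 * binary.sum() + 8:  # safety net, unreachable
            raise RuntimeError("boundary trace failed to close")


def outlines_from_mask(label_mask: np.ndarray) -> list[NucleusOutline]:
    """Trace one outline per positive label of an integer label image.

    Points are pixel centers in (x, y) = (col, row) order.  Labels whose
    boundary has fewer than 3 pixels cannot form a polygon and are dropped
    with a warning.
    """
    mask = np.asarray(label_mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise InputError(f"label mask must be integer-typed, got {mask.dtype}")
    if mask.min() < 0:
        raise InputError("label mask contains negative labels")

    outlines: list[NucleusOutline] = []
    for label in np.unique(mask):
        if label == 0:
            continue
        trace_rc = _trace_boundary(mask == label)
        # consecutive duplicates can occur on single-pixel spurs
        keep = np.ones(len(trace_rc), bool)
        if len(trace_rc) > 1:
            keep[1:] = np.any(np.diff(trace_rc, axis=0) != 0, axis=1)
        trace_rc = trace_rc[keep]
        if len(np.unique(trace_rc, axis=0)) < 3:
            logger.warning("label %d: boundary has < 3 pixels, dropped", label)
            continue
        points = tuple((float(c), float(r)) for r, c in trace_rc)
        outlines.append(NucleusOutline(nucleus_id=str(int(label)), points=points))
    return outlines


# ---------------------------------------------------------------------------
# Case reduction
# ---------------------------------------------------------------------------

def measure_case(
    case_id: str,
    outlines: Sequence[NucleusOutline],
    calibration: Calibration,
    k_extreme: int = 3,
    original_score: int | None = None,
    *,
    validate: bool = True,
) -> CaseRecord:
    """Reduce a case's nuclei to (SNS, LNS, NSD) in µm.

    Flagged nuclei are excluded; the remaining diameters are calibrated and
    LNS/SNS are the means of the ``k_extreme`` largest/smallest.  Outlines
    from several images of the same tumor should be pooled before calling.
    ``k_extreme`` is truncated (with a warning) when fewer nuclei survive;
    with a single admissible nucleus LNS = SNS and NSD = 0.
    """
    if k_extreme < 1:
        raise InputError(f"k_extreme must be >= 1, got {k_extreme}")
    admissible = [o for o in outlines if not o.excluded]
    n_excluded = len(outlines) - len(admissible)
    if n_excluded:
        logger.info("case %s: excluded %d flagged nuclei", case_id, n_excluded)
    if not admissible:
        raise InputError(f"case {case_id!r}: no admissible nuclei after exclusion")

    diam_um = np.sort(
        [longest_axis(o, validate=validate) * calibration.microns_per_pixel
         for o in admissible]
    )
    k = min(k_extreme, len(diam_um))
    if k < k_extreme:
        warnings.warn(
            f"case {case_id!r}: only {len(diam_um)} nuclei available, "
            f"k_extreme truncated from {k_extreme} to {k}",
            stacklevel=2,
        )
    sns = float(diam_um[:k].mean())
    lns = float(diam_um[-k:].mean())
    return CaseRecord.from_sizes(case_id, sns=sns, lns=lns, original_score=original_score)


# ---------------------------------------------------------------------------
# IO: cohort CSV and outline JSON
# ---------------------------------------------------------------------------

def cases_to_frame(cases: Iterable[CaseRecord]) -> pd.DataFrame:
    rows = [
        {
            "case_id": c.case_id,
            "sns_um": c.sns,
            "lns_um": c.lns,
            "nsd_um": c.nsd,
            "original_score": c.original_score,
        }
        for c in cases
    ]
    frame = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    frame["original_score"] = frame["original_score"].astype("Int64")
    return frame


def write_cases_csv(cases: Iterable[CaseRecord], path: str | Path) -> None:
    cases_to_frame(cases).to_csv(path, index=False)


def read_cases_csv(path: str | Path) -> list[CaseRecord]:
    """Load a cohort CSV (schema ``case_id,sns_um,lns_um,nsd_um,original_score``)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"{path}: cohort CSV missing columns {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        score = None if pd.isna(row.original_score) else int(row.original_score)
        nsd = float(row.lns_um) - float(row.sns_um)
        if not math.isclose(nsd, float(row.nsd_um), rel_tol=0, abs_tol=1e-6):
            raise InputError(
                f"{path}: case {row.case_id!r} violates NSD = LNS - SNS "
                f"({row.nsd_um} vs {nsd})"
            )
        records.append(
            CaseRecord(
                case_id=str(row.case_id),
                sns=float(row.sns_um),
                lns=float(row.lns_um),
                nsd=nsd,
                original_score=score,
            )
        )
    return records


def read_outlines_json(path: str | Path) -> list[NucleusOutline]:
    """Load outlines from JSON: a list of {nucleus_id, points, flags} objects."""
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, list):
        raise InputError(f"{path}: expected a JSON list of outline objects")
    outlines = []
    for obj in payload:
        try:
            outlines.append(
                NucleusOutline(
                    nucleus_id=str(obj["nucleus_id"]),
                    points=tuple((float(p[0]), float(p[1])) for p in obj["points"]),
                    flags=frozenset(obj.get("flags", [])),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise InputError(f"{path}: malformed outline object ({exc})") from exc
    return outlines


def write_outlines_json(outlines: Iterable[NucleusOutline], path: str | Path) -> None:
    payload = [
        {
            "nucleus_id": o.nucleus_id,
            "points": [[x, y] for x, y in o.points],
            "flags": sorted(o.flags),
        }
        for o in outlines
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
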