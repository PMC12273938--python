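"""Agreement between modified and original nuclear scores.

Provides the 3×3 confusion matrix, unweighted (optionally weighted) Cohen's
kappa with a large-sample z-test, concordant/discordant pair analysis
distinguishing adjacent (|Δgrade| = 1) from critical (|Δgrade| = 2)
discordance, and an exact Fisher test for r×c contingency tables by full
enumeration over fixed margins with a Monte-Carlo fallback.

Kappa magnitudes are labelled with the Landis–Koch bands (≤0 poor,
0–0.20 slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial,
>0.80 almost perfect); values ≥ 0.6 are conventionally read as good
reliability between two scales.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .errors import DegenerateStatisticsError, InputError
from .grading import GradeAssignment

logger = logging.getLogger(__name__)

GOOD_RELIABILITY_THRESHOLD = 0.6

_LANDIS_KOCH = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (math.inf, "almost perfect"),
)


def interpret_kappa(kappa: float) -> str:
    """Landis–Koch qualitative band for a kappa value."""
    for bound, label in _LANDIS_KOCH:
        if kappa <= bound:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class ConfusionMatrix:
    """k×k score cross-tabulation; rows = modified grade, columns = original."""

    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise InputError(f"confusion matrix must be square, got shape {arr.shape}")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise InputError("confusion matrix entries must be non-negative integers")
        object.__setattr__(
            self, "counts", tuple(tuple(int(v) for v in row) for row in arr)
        )

    @property
    def n(self) -> int:
        return int(np.sum(self.counts))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class AgreementResult:
    """Kappa and pair-analysis summary for one confusion matrix."""

    matrix: ConfusionMatrix
    po: float
    pe: float
    kappa: float
    se: float
    z: float
    p_value: float
    concordant: int
    adjacent_discordant: int
    critical_discordant: int
    interpretation: str
    weights: str | None = None

    @property
    def n(self) -> int:
        return self.matrix.n

    @property
    def concordant_pct(self) -> float:
        return 100.0 * self.concordant / self.n

    @property
    def good_reliability(self) -> bool:
        return self.kappa >= GOOD_RELIABILITY_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "matrix": [list(r) for r in self.matrix.counts],
            "n": self.n,
            "po": self.po,
            "pe": self.pe,
            "kappa": self.kappa,
            "se": self.se,
            "z": self.z,
            "p_value": self.p_value,
            "concordant": self.concordant,
            "concordant_pct": self.concordant_pct,
            "adjacent_discordant": self.adjacent_discordant,
            "critical_discordant": self.critical_discordant,
            "interpretation": self.interpretation,
            "good_reliability": self.good_reliability,
            "weights": self.weights,
        }


def confusion_matrix(
    assignments: Sequence[GradeAssignment],
    score: str = "combined",
    n_grades: int = 3,
) -> ConfusionMatrix:
    """Cross-tabulate a modified scoring against the original scores.

    ``score`` selects the modified scoring: "lns", "nsd" or "combined".
    Assignments lacking an original score are excluded with a logged count.
    """
    if score not in ("lns", "nsd", "combined"):
        raise InputError(f"score must be lns|nsd|combined, got {score!r}")
    attr = f"score_{score}"
    counts = np.zeros((n_grades, n_grades), dtype=np.int64)
    n_missing = 0
    for a in assignments:
        if a.original_score is None:
            n_missing += 1
            continue
        counts[getattr(a, attr) - 1, a.original_score - 1] += 1
    if n_missing:
        logger.info("excluded %d assignments without an original score", n_missing)
    if counts.sum() == 0:
        raise InputError("no assignments with both a modified and an original score")
    return ConfusionMatrix(tuple(map(tuple, counts)))


def pair_analysis(m: ConfusionMatrix) -> tuple[float, int, int]:
    """(concordant %, adjacent-discordant count, critical-discordant count)."""
    arr = m.as_array()
    n = arr.sum()
    if n < 1:
        raise InputError("empty confusion matrix")
    i, j = np.indices(arr.shape)
    concordant = int(arr[i == j].sum())
    adjacent = int(arr[np.abs(i - j) == 1].sum())
    critical = int(arr[np.abs(i - j) >= 2].sum())
    assert concordant + adjacent + critical == n
    return 100.0 * concordant / n, adjacent, critical


def _kappa_weights(k: int, weights: str | None) -> np.ndarray:
    """Agreement-weight matrix w_ij in [0,1]; 1 on the diagonal."""
    i, j = np.indices((k, k))
    if weights is None:
        return (i == j).astype(float)
    if weights == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    if weights == "quadratic":
        return 1.0 - ((i - j) / (k - 1)) ** 2
    raise InputError(f"weights must be None|'linear'|'quadratic', got {weights!r}")


def cohen_kappa(m: ConfusionMatrix, weights: str | None = None) -> AgreementResult:
    """Cohen's kappa with its H₀ z-test and pair analysis.

    po = trace/n, pe = Σ rowᵢ·colᵢ/n², kappa = (po − pe)/(1 − pe).  The
    standard error is the large-sample SE of unweighted kappa under
    H₀: kappa = 0,

        se₀² = [pe + pe² − Σᵢ pᵢ₊ p₊ᵢ (pᵢ₊ + p₊ᵢ)] / [n (1 − pe)²],

    with a two-sided p from the normal approximation (the weighted variant
    uses the analogous weighted-variance formula).  A matrix with all mass
    in one row and the matching column has pe = 1 and kappa undefined.
    """
    arr = m.as_array().astype(float)
    n = arr.sum()
    if n < 2:
        raise InputError(f"need n >= 2 paired scores, got {n:.0f}")
    k = arr.shape[0]
    p = arr / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    w = _kappa_weights(k, weights)
    po = float((w * p).sum())
    pe = float((w * np.outer(row, col)).sum())
    if pe >= 1.0 - 1e-15:
        raise DegenerateStatisticsError(
            "chance agreement pe = 1 (all mass in one matching row/column); "
            "kappa is undefined"
        )
    kappa = (po - pe) / (1 - pe)

    # H0 variance (Fleiss–Cohen–Everitt); reduces to the classic unweighted
    # formula when w is the identity.
    wbar_i = (w * col[None, :]).sum(axis=1)  # E[w | modified grade i]
    wbar_j = (w * row[:, None]).sum(axis=0)  # E[w | original grade j]
    var0 = (
        (np.outer(row, col) * (w - (wbar_i[:, None] + wbar_j[None, :])) ** 2).sum()
        - pe**2
    ) / (n * (1 - pe) ** 2)
    se = math.sqrt(max(var0, 0.0))
    if se == 0:
        z = math.inf if kappa > 0 else (-math.inf if kappa < 0 else 0.0)
    else:
        z = kappa / se
    p_value = float(2 * stats.norm.sf(abs(z)))

    concordant_pct, adjacent, critical = pair_analysis(m)
    concordant = int(np.trace(m.as_array()))
    return AgreementResult(
        matrix=m,
        po=po,
        pe=pe,
        kappa=float(kappa),
        se=se,
        z=float(z),
        p_value=p_value,
        concordant=concordant,
        adjacent_discordant=adjacent,
        critical_discordant=critical,
        interpretation=interpret_kappa(float(kappa)),
        weights=weights,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test for r×c tables
# ---------------------------------------------------------------------------

def _table_log_prob(table: np.ndarray, log_norm: float) -> float:
    """Log multivariate hypergeometric probability of a table given margins.

    log_norm = Σ log rᵢ! + Σ log cⱼ! − log n! is shared across tables.
    """
    return log_norm - gammaln(table + 1).sum()


def _iter_tables(row_margins: np.ndarray, col_margins: np.ndarray) -> Iterator[np.ndarray]:
    """Yield every non-negative integer table with the given margins."""
    r = len(row_margins)

    def fill(row_idx: int, remaining_cols: np.ndarray, rows_acc: list[np.ndarray]):
        if row_idx == r - 1:
            if np.all(remaining_cols >= 0):
                yield np.array(rows_acc + [remaining_cols.copy()])
            return
        target = row_margins[row_idx]

        def fill_row(col_idx: int, left: int, row_acc: list[int]):
            if col_idx == len(remaining_cols) - 1:
                if 0 <= left <= remaining_cols[col_idx]:
                    yield row_acc + [left]
                return
            hi = min(left, remaining_cols[col_idx])
            for v in range(hi + 1):
                yield from fill_row(col_idx + 1, left - v, row_acc + [v])

        for row_vals in fill_row(0, int(target), []):
            row_arr = np.array(row_vals)
            yield from fill(row_idx + 1, remaining_cols - row_arr, rows_acc + [row_arr])

    yield from fill(0, col_margins.astype(int).copy(), [])


def _strip_empty(arr: np.ndarray) -> np.ndarray:
    arr = arr[arr.sum(axis=1) > 0]
    return arr[:, arr.sum(axis=0) > 0]


def fisher_exact_rxc(
    m: ConfusionMatrix | np.ndarray,
    method: str = "enumerate",
    mc_draws: int = 100_000,
    seed: int = 0,
    table_budget: int = 10_000_000,
) -> tuple[float, float | None]:
    """Two-sided Fisher exact test for an r×c table.

    Generalizes the 2×2 test: p is the total multivariate-hypergeometric
    probability, over all tables with the observed margins, of tables no
    more probable than the observed one (relative tie tolerance 1e-12).
    Empty rows/columns are dropped first (they carry probability 1).

    ``method``: "enumerate" (exact; fails past ``table_budget`` tables),
    "monte_carlo" (estimate over ``mc_draws`` permutation-sampled tables),
    or "auto" (enumerate, falling back to Monte-Carlo).

    Returns (p, se): se is None for the exact method, the binomial standard
    error of the Monte-Carlo estimate otherwise.
    """
    arr = m.as_array() if isinstance(m, ConfusionMatrix) else np.asarray(m, dtype=np.int64)
    if np.any(arr < 0):
        raise InputError("table entries must be non-negative")
    arr = _strip_empty(arr)
    if arr.size == 0 or min(arr.shape) < 2:
        return 1.0, None  # at most one non-empty row/col: margins fix the table

    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = int(arr.sum())
    log_norm = float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1))
    log_p_obs = _table_log_prob(arr, log_norm)
    cutoff = log_p_obs + 1e-12  # accept ties within relative tolerance

    if method in ("enumerate", "auto"):
        total = 0.0
        p_sum = 0.0
        count = 0
        exceeded = False
        for table in _iter_tables(rows, cols):
            count += 1
            if count > table_budget:
                exceeded = True
                break
            lp = _table_log_prob(table, log_norm)
            prob = math.exp(lp)
            total += prob
            if lp <= cutoff:
                p_sum += prob
        if not exceeded:
            if abs(total - 1.0) > 1e-9:
                raise AssertionError(
                    f"enumeration probabilities sum to {total}, not 1"
                )
            return min(p_sum, 1.0), None
        if method == "enumerate":
            raise InputError(
                f"more than {table_budget} tables share these margins; "
                "use method='monte_carlo' or 'auto'"
            )

    if method not in ("monte_carlo", "auto"):
        raise InputError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    flat_index = row_labels * len(cols)
    hits = 0
    block = 2000  # permutations per vectorized batch
    done = 0
    while done < mc_draws:
        b = min(block, mc_draws - done)
        keys = rng.random((b, n))
        perms = np.argsort(keys, axis=1)
        sampled_cols = col_labels[perms]
        idx = flat_index[None, :] + sampled_cols
        tables = np.zeros((b, len(rows) * len(cols)), dtype=np.int64)
        np.add.at(tables, (np.repeat(np.arange(b), n), idx.ravel()), 1)
        lps = log_norm - gammaln(tables + 1).sum(axis=1)
        hits += int((lps <= cutoff).sum())
        done += b
    p_hat = hits / mc_draws
    se = math.sqrt(p_hat * (1 - p_hat) / mc_draws)
    return p_hat, se


def enumeration_probability_total(
    row_margins: Sequence[int], col_margins: Sequence[int]
) -> float:
    """Sum of hypergeometric probabilities over all tables with these margins.

    Diagnostic for the enumeration machinery; mathematically 1.
    """
    rows = np.asarray(row_margins, dtype=np.int64)
    cols = np.asarray(col_margins, dtype=np.int64)
    if rows.sum() != cols.sum():
        raise InputError("row and column margins must have equal totals")
    n = int(rows.sum())
    log_norm = float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1))
    return float(
        sum(math.exp(_table_log_prob(t, log_norm)) for t in _iter_tables(rows, cols))
    )
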