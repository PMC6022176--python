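"""Agreement and reliability statistics.

Validation of the electrostatic method against the foot-pressure
reference rests on four quantities:

* signed event-timing errors between matched same-kind events and
  their summary statistics / histogram,
* per-cycle gait-cycle (Tg) error and the accuracy
  ``100 - mean(|% error|)``,
* the Pearson product–moment correlation of paired parameter series,
  graded excellent (> 0.90) / good (0.80–0.89) / fair (0.70–0.79) /
  poor (< 0.70),
* the intraclass correlation coefficient ICC(2,1) — two-way random
  effects, absolute agreement, single measures (Shrout–Fleiss) — for
  test–retest reliability, graded excellent (> 0.90) / good
  (0.75–0.90) / moderate (0.50–0.75) / poor (< 0.50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .events import GaitEvents, IC

__all__ = [
    "MatchResult",
    "EventErrorStats",
    "AgreementReport",
    "CycleAccuracy",
    "match_events",
    "error_stats",
    "cycle_accuracy",
    "pearson",
    "icc_2_1",
    "grade_pearson",
    "grade_icc",
    "pair_gait_cycles",
    "agreement_report",
]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of pairing estimated events to reference events."""

    deltas_ms: np.ndarray      # signed est - ref, ms, one per matched pair
    n_unmatched_est: int
    n_unmatched_ref: int

    @property
    def n_matched(self) -> int:
        return int(self.deltas_ms.size)


def match_events(
    est: GaitEvents, ref: GaitEvents, kind: str, window_ms: float = 100.0
) -> MatchResult:
    """Greedy nearest-neighbour pairing of same-kind events.

    Pairs are formed in order of increasing |est - ref|; each event on
    either side is used at most once and pairs farther apart than
    ``window_ms`` are never formed.  Returns the signed timing errors
    (est - ref) in milliseconds plus unmatched counts on both sides.
    """
    te = est.times[est.kinds == kind]
    tr = ref.times[ref.kinds == kind]
    if te.size == 0 or tr.size == 0:
        return MatchResult(np.empty(0), int(te.size), int(tr.size))
    d = (te[:, None] - tr[None, :]) * 1000.0
    cand = np.argwhere(np.abs(d) <= window_ms)
    order = np.argsort(np.abs(d[cand[:, 0], cand[:, 1]]), kind="stable")
    used_e = np.zeros(te.size, dtype=bool)
    used_r = np.zeros(tr.size, dtype=bool)
    pairs = []
    for i, j in cand[order]:
        if not used_e[i] and not used_r[j]:
            used_e[i] = used_r[j] = True
            pairs.append((i, j))
    pairs.sort(key=lambda p: p[1])
    deltas = np.array([d[i, j] for i, j in pairs])
    return MatchResult(deltas, int((~used_e).sum()), int((~used_r).sum()))


@dataclass(frozen=True)
class EventErrorStats:
    """Summary statistics and histogram of signed event-timing errors (ms)."""

    n_matched: int
    n_unmatched: int
    mean: float
    sd: float
    min: float
    max: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def as_dict(self) -> dict:
        return {
            "n_matched": self.n_matched,
            "n_unmatched": self.n_unmatched,
            "mean_ms": self.mean,
            "sd_ms": self.sd,
            "min_ms": self.min,
            "max_ms": self.max,
            "bin_edges_ms": np.asarray(self.bin_edges, dtype=float).tolist(),
            "counts": np.asarray(self.counts, dtype=int).tolist(),
        }


def error_stats(
    deltas_ms,
    bin_width_ms: float = 5.0,
    hist_range_ms: tuple[float, float] = (-50.0, 50.0),
    n_unmatched: int = 0,
) -> EventErrorStats:
    """Mean, sample sd, range and a fixed-width histogram of timing errors.

    Histogram bins cover ``hist_range_ms``; errors outside the range are
    absorbed into the outermost bins so counts always sum to the number
    of matched events.  Empty input yields a degenerate all-NaN report.
    """
    deltas = np.asarray(deltas_ms, dtype=float)
    lo, hi = hist_range_ms
    if bin_width_ms <= 0 or hi <= lo:
        raise ValueError("need bin_width_ms > 0 and a non-empty histogram range")
    edges = np.arange(lo, hi + bin_width_ms / 2, bin_width_ms)
    if deltas.size == 0:
        return EventErrorStats(0, int(n_unmatched), np.nan, np.nan, np.nan, np.nan,
                               edges, np.zeros(edges.size - 1, dtype=int))
    eps = bin_width_ms * 1e-9
    clipped = np.clip(deltas, lo + eps, hi - eps)
    counts, _ = np.histogram(clipped, bins=edges)
    sd = float(np.std(deltas, ddof=1)) if deltas.size > 1 else 0.0
    return EventErrorStats(
        n_matched=int(deltas.size),
        n_unmatched=int(n_unmatched),
        mean=float(deltas.mean()),
        sd=sd,
        min=float(deltas.min()),
        max=float(deltas.max()),
        bin_edges=edges,
        counts=counts,
    )


@dataclass(frozen=True)
class CycleAccuracy:
    """Per-cycle Tg errors against a reference and the pooled accuracy."""

    errors_ms: np.ndarray
    pct_errors: np.ndarray
    accuracy_pct: float


def cycle_accuracy(est_tg_ms, ref_tg_ms) -> CycleAccuracy:
    """Per-cycle error, percentage error, and accuracy of Tg estimates.

    ``error = est - ref``; ``% error = 100 * error / ref``;
    ``accuracy = 100 - mean(|% error|)``.  Inputs must be paired,
    equal-length cycle series.
    """
    est = np.asarray(est_tg_ms, dtype=float)
    ref = np.asarray(ref_tg_ms, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("est and ref must be equal-length 1-D cycle series")
    if est.size == 0:
        raise ValueError("need at least one paired cycle")
    if np.any(ref <= 0):
        raise ValueError("reference cycle durations must be positive")
    err = est - ref
    pct = 100.0 * err / ref
    return CycleAccuracy(err, pct, float(100.0 - np.mean(np.abs(pct))))


def grade_pearson(r: float) -> str:
    """Qualitative grade of a Pearson correlation."""
    if r > 0.90:
        return "excellent"
    if r >= 0.80:
        return "good"
    if r >= 0.70:
        return "fair"
    return "poor"


def grade_icc(icc: float) -> str:
    """Qualitative grade of an intraclass correlation."""
    if icc > 0.90:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.50:
        return "moderate"
    return "poor"


def pearson(x, y) -> tuple[float, float, str]:
    """Pearson r with a two-sided p (t transform, n-2 df) and its grade."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D series with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a zero-variance input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, float(res.pvalue), grade_pearson(r)


def icc_2_1(data) -> tuple[float, float, str]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``data`` is an ``n_subjects x k_sessions`` matrix with no missing
    cells.  The two-way ANOVA decomposition (rows = subjects, columns =
    sessions) gives

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with the significance taken from ``F = MSR/MSE`` on
    ``(n-1, (n-1)(k-1))`` degrees of freedom.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D matrix (subjects x sessions)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    if not np.isfinite(x).all():
        raise ValueError("data must not contain missing cells")

    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - gm) ** 2).sum())
    ssc = n * float(((col_means - gm) ** 2).sum())
    sst = float(((x - gm) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("ICC undefined: zero between- and within-subject variance")
    icc = (msr - mse) / denom
    if mse > 0:
        p = float(stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0 if msr > 0 else 1.0
    return float(icc), p, grade_icc(icc)


@dataclass(frozen=True)
class AgreementReport:
    """Concurrent-validity summary of two paired parameter series."""

    pearson_r: float
    pearson_p: float
    pearson_grade: str
    icc: float
    icc_p: float
    icc_grade: str
    n: int

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "pearson_grade": self.pearson_grade,
            "icc": self.icc,
            "icc_p": self.icc_p,
            "icc_grade": self.icc_grade,
            "n": self.n,
        }


def agreement_report(est, ref) -> AgreementReport:
    """Pearson and ICC(2,1) agreement between two paired series.

    The ICC treats the paired cycles as subjects and the two methods as
    sessions (absolute agreement between methods).
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    r, rp, rg = pearson(est, ref)
    icc, ip, ig = icc_2_1(np.column_stack([est, ref]))
    return AgreementReport(r, rp, rg, icc, ip, ig, int(est.size))


def pair_gait_cycles(
    est: GaitEvents, ref: GaitEvents, window_ms: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pair per-cycle Tg between two event sequences via matched ICs.

    IC events are matched greedily within ``window_ms``; a Tg pair is
    formed wherever two matched IC pairs are consecutive in *both*
    sequences (no skipped IC on either side).  Returns
    ``(tg_est_ms, tg_ref_ms)``.
    """
    te = est.ic_times
    tr = ref.ic_times
    if te.size < 2 or tr.size < 2:
        return np.empty(0), np.empty(0)
    d = (te[:, None] - tr[None, :]) * 1000.0
    cand = np.argwhere(np.abs(d) <= window_ms)
    order = np.argsort(np.abs(d[cand[:, 0], cand[:, 1]]), kind="stable")
    used_e = np.zeros(te.size, dtype=bool)
    used_r = np.zeros(tr.size, dtype=bool)
    pairs = []
    for i, j in cand[order]:
        if not used_e[i] and not used_r[j]:
            used_e[i] = used_r[j] = True
            pairs.append((i, j))
    pairs.sort(key=lambda p: p[1])
    tg_e, tg_r = [], []
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 == i1 + 1 and j2 == j1 + 1:
            tg_e.append((te[i2] - te[i1]) * 1000.0)
            tg_r.append((tr[j2] - tr[j1]) * 1000.0)
    return np.array(tg_e), np.array(tg_r)
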