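"""Knockoff selection filter and Q-values, for single and multiple knockoffs.

Window importance scores are T = -log10 p for the original cohort and
T^1..T^M for the M knockoff copies.  With a single knockoff the feature
statistic is W = T - T^1 and the data-adaptive threshold is

    tau_hat = min{ t > 0 : (1 + #{W <= -t}) / max(1, #{W >= t}) <= q }.

With multiple knockoffs, kappa indexes which of (T, T^1..T^M) is largest
(0 = original) and tau is the gap between the largest score and the median
of the remaining M scores; W = (T - median(T^1..T^M)) when the original
wins, else 0.  Using the median rather than the maximum of the knockoff
scores reduces the run-to-run variability introduced by knockoff sampling.
The threshold becomes

    tau_hat = min{ t : (1/M + (1/M) #{kappa >= 1, tau >= t})
                        / max(1, #{kappa = 0, tau >= t}) <= q },

which reduces exactly to the single-knockoff rule at M = 1.  The knockoff
Q-value of a window is the smallest target FDR at which it would be
selected; selection at level q is equivalent to qvalue <= q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WindowStats",
    "feature_stats",
    "threshold_single",
    "threshold_multiple",
    "qvalues_single",
    "qvalues_multiple",
    "filter_windows",
]


@dataclass
class WindowStats:
    """Per-window filter statistics."""

    T0: float
    Tm: np.ndarray
    W: float
    kappa: int
    tau: float
    qvalue: float = 1.0


def _median(x: np.ndarray) -> float:
    return float(np.median(x))


def feature_stats(p0: float, p_knockoffs, statistic: str = "median") -> WindowStats:
    """Feature statistic, kappa and tau from original + knockoff p-values.

    ``statistic`` picks the reference summary of the non-winning scores:
    the default "median" (more stable under knockoff resampling) or "max"
    (the original multiple-knockoff proposal).  Ties at the maximum favor
    the original (kappa = 0 when T0 >= max Tm), which is mildly
    anti-conservative; see module docs.
    """
    pk = np.asarray(p_knockoffs, dtype=float)
    if not (0 < p0 <= 1) or np.any((pk <= 0) | (pk > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    summarize = _median if statistic == "median" else (lambda x: float(np.max(x)))
    T0 = -np.log10(p0)
    Tm = -np.log10(pk)
    M = Tm.size
    if T0 >= Tm.max():
        kappa = 0
        tau = T0 - summarize(Tm)
        W = tau
    else:
        kappa = int(np.argmax(Tm)) + 1
        rest = np.concatenate([[T0], np.delete(Tm, kappa - 1)])
        tau = float(Tm.max() - summarize(rest))
        W = 0.0
    if M == 1:
        W = float(T0 - Tm[0])  # signed statistic for the single-knockoff filter
    return WindowStats(float(T0), Tm, float(W), kappa, float(tau))


def _fdr_hat_single(W: np.ndarray, t: float) -> float:
    return (1.0 + np.sum(W <= -t)) / max(1, int(np.sum(W >= t)))


def threshold_single(W, q: float) -> float:
    """Single-knockoff selection threshold; +inf if nothing qualifies."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0,1)")
    W = np.asarray(W, dtype=float)
    cands = np.unique(np.abs(W[np.abs(W) > 0]))
    ok = [t for t in cands if _fdr_hat_single(W, t) <= q]
    return float(min(ok)) if ok else np.inf


def _fdr_hat_multiple(kappa: np.ndarray, tau: np.ndarray, M: int, t: float) -> float:
    num = 1.0 / M + np.sum((kappa >= 1) & (tau >= t)) / M
    den = max(1, int(np.sum((kappa == 0) & (tau >= t))))
    return num / den


def threshold_multiple(stats: list[WindowStats], M: int, q: float) -> float:
    """Multiple-knockoff selection threshold over per-window (kappa, tau)."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0,1)")
    kappa = np.array([s.kappa for s in stats])
    tau = np.array([s.tau for s in stats])
    cands = np.unique(tau[(kappa == 0) & (tau > 0)])
    ok = [t for t in cands if _fdr_hat_multiple(kappa, tau, M, t) <= q]
    return float(min(ok)) if ok else np.inf


def qvalues_single(W) -> np.ndarray:
    """Knockoff Q-value per window for a single knockoff.

    q_i = min over candidate t <= W_i of the knockoff FDR estimate at t,
    capped at 1; windows with W <= 0 get q = 1.
    """
    W = np.asarray(W, dtype=float)
    cands = np.unique(np.abs(W[np.abs(W) > 0]))
    fdr = np.array([_fdr_hat_single(W, t) for t in cands])
    # min over candidate thresholds t' <= t, i.e. prefix minima in t order
    prefix_min = np.minimum.accumulate(fdr)
    q = np.ones_like(W)
    pos = W > 0
    if cands.size:
        ix = np.searchsorted(cands, W[pos], side="right") - 1
        q[pos] = np.minimum(prefix_min[ix], 1.0)
    return q


def qvalues_multiple(stats: list[WindowStats], M: int) -> np.ndarray:
    """Knockoff Q-value per window for M knockoffs (kappa != 0 gives q = 1)."""
    kappa = np.array([s.kappa for s in stats])
    tau = np.array([s.tau for s in stats])
    cands = np.unique(tau[(kappa == 0) & (tau > 0)])
    fdr = np.array([_fdr_hat_multiple(kappa, tau, M, t) for t in cands])
    prefix_min = np.minimum.accumulate(fdr)
    q = np.ones(len(stats))
    sel = (kappa == 0) & (tau > 0)
    if cands.size:
        ix = np.searchsorted(cands, tau[sel], side="right") - 1
        valid = ix >= 0
        qs = np.ones(int(sel.sum()))
        qs[valid] = np.minimum(prefix_min[ix[valid]], 1.0)
        q[sel] = qs
    return q


def filter_windows(
    p_original, p_knockoffs, q: float = 0.1, statistic: str = "median"
) -> tuple[list[WindowStats], float, np.ndarray]:
    """Run the full filter: stats, threshold, Q-values, selection mask.

    ``p_original`` is length-N; ``p_knockoffs`` is N x M.  Returns the
    per-window stats (with Q-values filled in), the threshold, and a
    boolean selection mask (kappa = 0 and tau >= tau_hat).
    """
    p0 = np.asarray(p_original, dtype=float)
    pk = np.atleast_2d(np.asarray(p_knockoffs, dtype=float))
    if pk.shape[0] != p0.size:
        pk = pk.T
    M = pk.shape[1]
    stats = [feature_stats(p0[i], pk[i], statistic=statistic) for i in range(p0.size)]
    tau_hat = threshold_multiple(stats, M, q)
    qv = qvalues_multiple(stats, M)
    for s, qi in zip(stats, qv):
        s.qvalue = float(qi)
    kappa = np.array([s.kappa for s in stats])
    tau = np.array([s.tau for s in stats])
    selected = (kappa == 0) & (tau >= tau_hat)
    return stats, tau_hat, selected
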