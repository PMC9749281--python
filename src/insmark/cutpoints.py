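"""Optimal stratification: maximally selected log-rank cutpoints.

A continuous biomarker is dichotomized at the threshold that maximizes the
two-group log-rank chi-square over every admissible observed split. The scan
is exhaustive — every distinct observed value inside a quantile search
window whose split leaves both groups large enough is a candidate — and is
vectorized over candidates via 2D cumulative risk-set counts, so cohorts of
several thousand patients scan in well under a second.

The naive 1-df chi-square p-value at the selected threshold is
anti-conservative (the maximum of many correlated statistics); an optional
permutation-corrected p-value is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

__all__ = ["LogrankResult", "CutpointResult", "logrank_statistic", "optimal_cutpoint"]


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float


@dataclass(frozen=True)
class CutpointResult:
    """An optimal threshold with its maximal log-rank statistic."""

    threshold: float
    max_statistic: float
    p_value: float
    search_range: tuple[float, float]
    n_candidates: int
    direction: Literal["below", "at_or_above"]
    corrected_p_value: float | None = None


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have the same length")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    if not np.all(np.isin(events, [0, 1])):
        raise ValueError("events must be 0/1")
    return times, events


def logrank_statistic(group, times, events) -> LogrankResult:
    """Two-group log-rank chi-square (1 df), hypergeometric tie handling.

    ``group`` is a binary label vector; both groups must be non-empty.
    All-censored input yields statistic 0 with a warning.
    """
    group = np.asarray(group).astype(bool)
    times, events = _check_surv(times, events)
    if group.shape != times.shape:
        raise ValueError("group labels must match times in length")
    if group.all() or (~group).all():
        raise ValueError("both groups must be non-empty")
    if events.sum() == 0:
        warnings.warn("no events observed; log-rank statistic is 0", stacklevel=2)
        return LogrankResult(0.0, 1.0)

    te = np.unique(times[events == 1])
    # at risk / events overall and in group-1, per event time
    n_at = (times[None, :] >= te[:, None]).sum(axis=1).astype(float)
    d = ((times[None, :] == te[:, None]) & (events == 1)).sum(axis=1).astype(float)
    n1 = ((times[None, :] >= te[:, None]) & group).sum(axis=1).astype(float)
    d1 = ((times[None, :] == te[:, None]) & (events == 1) & group).sum(axis=1).astype(float)

    frac = n1 / n_at
    u = float(np.sum(d1 - d * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d * (n_at - d) / (n_at - 1.0) * frac * (1.0 - frac)
    v = float(np.nansum(np.where(n_at > 1, v_terms, 0.0)))
    if v <= 0:
        return LogrankResult(0.0, 1.0)
    chi2 = u * u / v
    return LogrankResult(chi2, float(stats.chi2.sf(chi2, df=1)))


def _scan_statistics(values, times, events, candidates):
    """Log-rank chi-square and low-group (O-E) for every candidate threshold.

    The low group at threshold c is {value < c}. Vectorized: patients are
    binned by (event-time index, candidate index) and risk-set counts come
    from double cumulative sums.
    """
    te = np.unique(times[events == 1])
    k, m = len(te), len(candidates)
    # t_bin[p]: largest i with te[i] <= time[p]; -1 if time < first event time
    t_bin = np.searchsorted(te, times, side="right") - 1
    # patient is in the low group of candidate j iff v_bin[p] <= j
    v_bin = np.searchsorted(candidates, values, side="right")

    n_at = (times[None, :] >= te[:, None]).sum(axis=1).astype(float)
    d = np.bincount(t_bin[(events == 1)], minlength=k).astype(float)

    # H[i, j]: count of patients with t_bin == i and v_bin == j
    H = np.zeros((k + 1, m + 1))
    np.add.at(H, (np.clip(t_bin, -1, k - 1) + 1, np.minimum(v_bin, m)), 1.0)
    H = H[1:, :]  # drop never-at-risk row
    # n1[i, j] = sum_{i' >= i, j' <= j} H
    n1 = np.cumsum(H[::-1].cumsum(axis=1)[:, :m], axis=0)[::-1]

    Hev = np.zeros((k, m + 1))
    ev = events == 1
    np.add.at(Hev, (t_bin[ev], np.minimum(v_bin[ev], m)), 1.0)
    d1 = Hev.cumsum(axis=1)[:, :m]

    frac = n1 / n_at[:, None]
    u = (d1 - d[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vt = (d * (n_at - d) / (n_at - 1.0))[:, None] * frac * (1.0 - frac)
    v = np.where(n_at[:, None] > 1, vt, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(v > 0, u * u / v, 0.0)
    return chi2, u


def _admissible_candidates(values, search_range, min_group_frac):
    n = len(values)
    lo_q, hi_q = search_range
    lo, hi = np.quantile(values, [lo_q, hi_q])
    uniq = np.unique(values)
    cands = uniq[(uniq >= lo) & (uniq <= hi)]
    if len(cands) > 0:
        n_low = np.searchsorted(np.sort(values), cands, side="left")
        ok = (n_low >= min_group_frac * n) & ((n - n_low) >= min_group_frac * n)
        cands = cands[ok]
    return cands, (float(lo), float(hi))


def optimal_cutpoint(
    values,
    times,
    events,
    search_range: tuple[float, float] = (0.10, 0.90),
    min_group_frac: float = 0.10,
    corrected_p: bool = False,
    n_permutations: int = 500,
    seed: int | None = None,
) -> CutpointResult:
    """Exhaustive maximally-selected log-rank scan over observed values.

    Ties in the maximal statistic break toward the smaller threshold. The
    adverse direction is the side of the threshold with excess observed
    deaths. With ``corrected_p=True`` a permutation p-value for the maximal
    statistic (biomarker labels permuted, seeded) is also reported.
    """
    values = np.asarray(values, dtype=float)
    times, events = _check_surv(times, events)
    mask = ~np.isnan(values)
    values, times, events = values[mask], times[mask], events[mask]
    if len(values) < 20:
        raise ValueError("need at least 20 usable observations")
    if np.ptp(values) == 0:
        raise ValueError("no admissible cutpoint: values are constant")

    cands, qrange = _admissible_candidates(values, search_range, min_group_frac)
    if len(cands) == 0:
        raise ValueError(
            "no admissible cutpoint: every candidate violates the minimum "
            f"group fraction {min_group_frac} inside quantile range {search_range}"
        )
    chi2, u = _scan_statistics(values, times, events, cands)
    best = int(np.argmax(chi2))
    stat = float(chi2[best])
    direction = "below" if u[best] > 0 else "at_or_above"

    corrected = None
    if corrected_p:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(values)
            pc, _ = _admissible_candidates(perm, search_range, min_group_frac)
            if len(pc) == 0:
                continue
            c2, _u = _scan_statistics(perm, times, events, pc)
            if c2.max() >= stat:
                exceed += 1
        corrected = (exceed + 1) / (n_permutations + 1)

    return CutpointResult(
        threshold=float(cands[best]),
        max_statistic=stat,
        p_value=float(stats.chi2.sf(stat, df=1)),
        search_range=qrange,
        n_candidates=len(cands),
        direction=direction,
        corrected_p_value=corrected,
    )
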