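"""NSS-quartile survival comparison: Kaplan–Meier and log-rank.

Patients are scored with their factor stratum's NSS curve at their own
examined-node count, split into four groups at the empirical quartiles of
the scores, and overall survival is compared across the groups with the
standard log-rank test (hypergeometric observed-minus-expected events at
each distinct event time, chi-square reference with groups − 1 degrees of
freedom).  Both the product-limit estimator and the test are implemented
directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .nss import NSSCurve

__all__ = [
    "SurvivalGroup",
    "KMCurve",
    "LogrankResult",
    "assign_nss_groups",
    "km_estimate",
    "logrank_test",
]


@dataclass(frozen=True)
class SurvivalGroup:
    """One NSS-quartile group's follow-up data."""

    label: str
    members: tuple[int, ...]  # indices into the source cohort
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=bool)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be aligned 1-d arrays")
        if np.any(t < 0):
            raise ValueError("negative follow-up time")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class KMCurve:
    """Right-continuous product-limit survival estimate.

    ``times`` are the distinct event times; ``survival[i]`` is S(t) just
    after ``times[i]``.  ``at_risk`` and ``n_events`` give the risk set and
    event count at each of those times.
    """

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t) -> np.ndarray | float:
        """S(t), right-continuous (S(0) = 1 before any event)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return float(out) if np.ndim(t) == 0 else out


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    pvalue: float


def assign_nss_groups(
    records: Sequence,
    curves: dict[str, NSSCurve],
    factor: str,
    *,
    include_ln_positive: bool = True,
) -> list[SurvivalGroup]:
    """Split a cohort into quartile groups of per-patient NSS.

    Each patient's score is the NSS of their ``factor`` level's curve
    evaluated at their own examined-node count.  Quartile cut points are
    the empirical 25/50/75 percentiles; a score tied with a cut point goes
    to the lower group.  ``include_ln_positive=False`` restricts the
    comparison to pathologically node-negative patients.
    """
    from .synth import _factor_level  # local import to avoid cycle

    idx = [
        i
        for i, r in enumerate(records)
        if include_ln_positive or r.nodes_positive == 0
    ]
    if not idx:
        raise ValueError("no patients to group")
    scores = np.array(
        [
            curves[_factor_level(records[i], factor)](records[i].nodes_examined)
            for i in idx
        ]
    )
    if np.unique(scores).size < 4:
        raise ValueError(
            "fewer than 4 distinct NSS values: quartile grouping degenerate"
        )
    cuts = np.quantile(scores, [0.25, 0.5, 0.75])
    # ties at a cut point go to the lower group
    group_of = np.searchsorted(cuts, scores, side="left")
    groups = []
    for g in range(4):
        sel = [idx[j] for j in np.flatnonzero(group_of == g)]
        groups.append(
            SurvivalGroup(
                label=f"Q{g + 1}",
                members=tuple(sel),
                times=np.array([records[i].followup_months for i in sel]),
                events=np.array([records[i].event for i in sel]),
            )
        )
    return groups


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    At each distinct event time t_j with d_j events and n_j at risk,
    S(t) = prod_{t_j <= t} (1 - d_j / n_j).  Censoring times only shrink
    the risk set.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival data")
    if t.shape != e.shape:
        raise ValueError("times and events must be aligned")
    if np.any(t < 0):
        raise ValueError("negative follow-up time")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n_total = t.size
    at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    for j, tj in enumerate(event_times):
        at_risk[j] = np.sum(t >= tj)
        n_events[j] = np.sum(e & (t == tj))
    surv = np.cumprod(1.0 - n_events / at_risk) if event_times.size else np.array([])
    return KMCurve(
        times=event_times,
        at_risk=at_risk,
        n_events=n_events,
        survival=surv,
    )


def logrank_test(groups: Sequence[SurvivalGroup]) -> LogrankResult:
    """k-sample log-rank test.

    At every distinct event time, the events in each group are compared
    with their expectation under the hypergeometric null given the risk
    sets; the statistic is the quadratic form of the summed O − E vector
    in its estimated covariance (first k − 1 groups), referred to
    chi-square with k − 1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    k = len(groups)
    times = np.concatenate([g.times for g in groups])
    events = np.concatenate([g.events for g in groups])
    labels = np.concatenate(
        [np.full(len(g), j, dtype=int) for j, g in enumerate(groups)]
    )
    if not np.any(events):
        raise ValueError("no events in any group: log-rank undefined")

    event_times = np.unique(times[events])
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for tj in event_times:
        at_risk_mask = times >= tj
        n_j = np.array(
            [np.sum(at_risk_mask & (labels == g)) for g in range(k)],
            dtype=float,
        )
        N = n_j.sum()
        d_j = np.array(
            [
                np.sum(events & (times == tj) & (labels == g))
                for g in range(k)
            ],
            dtype=float,
        )
        D = d_j.sum()
        if N <= 1:
            continue
        expected = D * n_j / N
        o_minus_e += d_j - expected
        factor = D * (N - D) / (N - 1.0)
        cov += factor * (np.diag(n_j) * N - np.outer(n_j, n_j)) / N**2

    v = o_minus_e[: k - 1]
    V = cov[: k - 1, : k - 1]
    stat = float(v @ np.linalg.pinv(V) @ v)
    df = k - 1
    return LogrankResult(
        statistic=stat, df=df, pvalue=float(stats.chi2.sf(stat, df))
    )
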