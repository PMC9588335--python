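"""Nodal staging score: prevalence correction, NSS, and table building.

Limited node sampling misclassifies some truly node-positive patients as
negative, so the observed metastasis prevalence understates the truth.
With the false-negative staging probability ``p0(n)`` from the
beta-binomial model, the moment estimator

    pi_hat = (# observed positive) / sum_i (1 - p0(n_i))

(sum over every patient in the stratum) corrects the prevalence upward:
it solves E[# positive] = pi * sum_i (1 - p0(n_i)).

The nodal staging score is then the posterior probability that a patient
whose ``n`` examined nodes are all negative is truly node-negative:

    NSS(n) = (1 - pi) / ((1 - pi) + pi * p0(n)),

non-decreasing in ``n``, equal to the prior 1 - pi at n = 0, and tending
to 1 as sampling becomes exhaustive.  Inverting NSS gives the smallest
number of nodes to examine for a target negative predictive value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .betabin import BetaBinParams, staging_fn_prob

__all__ = [
    "StratumEstimate",
    "NSSCurve",
    "UNREACHABLE",
    "corrected_prevalence",
    "estimate_stratum",
    "nss_value",
    "nss_curve",
    "nodes_needed",
    "build_nss_table",
    "round_half_up",
]

#: Sentinel for a negative-predictive-value threshold not reachable within
#: the node-count search range; rendered as an em-dash in tables.
UNREACHABLE = None
_DASH = "—"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), as result tables use."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StratumEstimate:
    """Observed and corrected metastasis prevalence for one subgroup."""

    label: str
    n_patients: int
    n_observed_positive: int
    observed_prevalence: float
    corrected_prevalence: float
    node_counts: tuple[int, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.n_observed_positive > self.n_patients:
            raise ValueError("observed-positive count exceeds patient count")
        if not (
            0.0
            <= self.observed_prevalence
            <= self.corrected_prevalence
            <= 1.0
        ):
            raise ValueError(
                "require 0 <= observed <= corrected prevalence <= 1, got "
                f"{self.observed_prevalence!r} / {self.corrected_prevalence!r}"
            )


@dataclass(frozen=True)
class NSSCurve:
    """NSS as a function of examined-node count for one stratum."""

    stratum: StratumEstimate
    params: BetaBinParams
    values: Mapping[int, float]

    def __call__(self, n: int) -> float:
        try:
            return self.values[int(n)]
        except KeyError:
            return nss_value(
                int(n), self.stratum.corrected_prevalence, self.params
            )


def corrected_prevalence(
    observed_positive: Sequence[bool] | np.ndarray,
    nodes_examined: Sequence[int] | np.ndarray,
    params: BetaBinParams,
) -> float:
    """Occult-metastasis-corrected prevalence for one stratum.

    ``observed_positive`` and ``nodes_examined`` run over ALL patients in
    the stratum (positive and negative alike).  Clipped to 1 with a warning
    if the moment estimator exceeds 1, which can happen by sampling noise
    in small strata.
    """
    pos = np.asarray(observed_positive, dtype=bool)
    n = np.asarray(nodes_examined, dtype=int)
    if pos.shape != n.shape or pos.ndim != 1:
        raise ValueError("flags and node counts must be aligned 1-d arrays")
    if pos.size == 0:
        raise ValueError("stratum has no patients")
    if np.any(n < 0):
        raise ValueError("negative examined-node count")
    denom = float(np.sum(1.0 - staging_fn_prob(n, params)))
    if denom <= 0.0:
        raise ValueError(
            "sum of detection probabilities is zero (all patients have "
            "n=0 examined nodes); corrected prevalence undefined"
        )
    pi_hat = float(np.sum(pos)) / denom
    if pi_hat > 1.0:
        warnings.warn(
            f"moment estimator {pi_hat:.4f} exceeds 1; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        pi_hat = 1.0
    return pi_hat


def estimate_stratum(
    label: str,
    observed_positive,
    nodes_examined,
    params: BetaBinParams,
) -> StratumEstimate:
    """Bundle observed and corrected prevalence into a StratumEstimate."""
    pos = np.asarray(observed_positive, dtype=bool)
    n = np.asarray(nodes_examined, dtype=int)
    corrected = corrected_prevalence(pos, n, params)
    observed = float(np.mean(pos))
    return StratumEstimate(
        label=label,
        n_patients=int(pos.size),
        n_observed_positive=int(np.sum(pos)),
        observed_prevalence=observed,
        corrected_prevalence=max(observed, corrected),
        node_counts=tuple(int(x) for x in n),
    )


def nss_value(n: int, corrected_prev: float, params: BetaBinParams) -> float:
    """Posterior probability of true node-negativity after ``n`` negative nodes.

    ``NSS(n) = (1 - pi) / ((1 - pi) + pi * p0(n))`` with ``pi`` the
    corrected prevalence.  ``NSS(0) = 1 - pi`` (prior risk); degenerate
    priors give 1 (pi = 0) and 0 (pi = 1) for all n >= 1.
    """
    if not 0.0 <= corrected_prev <= 1.0:
        raise ValueError("corrected prevalence must lie in [0, 1]")
    if n < 0:
        raise ValueError("examined-node count must be >= 0")
    pi = float(corrected_prev)
    if pi == 0.0:
        return 1.0
    if pi == 1.0:
        return 0.0
    p0 = staging_fn_prob(int(n), params)
    return (1.0 - pi) / ((1.0 - pi) + pi * p0)


def nss_curve(
    stratum: StratumEstimate, params: BetaBinParams, n_max: int = 100
) -> NSSCurve:
    """Tabulate NSS(0..n_max) for a stratum."""
    values = {
        n: nss_value(n, stratum.corrected_prevalence, params)
        for n in range(n_max + 1)
    }
    return NSSCurve(stratum=stratum, params=params, values=values)


def nodes_needed(
    threshold: float,
    corrected_prev: float,
    params: BetaBinParams,
    n_max: int = 100,
) -> int | None:
    """Smallest n >= 1 with NSS(n) >= threshold, or UNREACHABLE.

    A threshold already met at the prior still requires one examined node
    (the score is defined for staged patients).  Returns ``UNREACHABLE``
    (None) when no n <= n_max qualifies — rendered as an em-dash in the
    nodes-needed table.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    # p0 is monotone decreasing, so NSS is monotone increasing: binary
    # search would work, but n_max is small — linear scan is clearer.
    for n in range(1, n_max + 1):
        if nss_value(n, corrected_prev, params) >= threshold:
            return n
    return UNREACHABLE


def build_nss_table(
    strata: Sequence[StratumEstimate],
    params: BetaBinParams,
    node_grid: Sequence[int] = (1, 5, 10, 15, 20, 25),
    threshold_grid: Sequence[float] = (0.80, 0.85, 0.90, 0.95),
    n_max: int = 100,
) -> dict[str, pd.DataFrame]:
    """Result tables: NSS by node count, nodes needed by threshold.

    Returns a dict with

    * ``"nss"`` — one row per stratum, NSS as percentages rounded half-up
      to one decimal, columns the node grid;
    * ``"nodes_needed"`` — one row per stratum, smallest node count per
      threshold, unreachable cells rendered as an em-dash;
    * ``"records"`` — tidy machine-readable long table with unrounded
      values (one row per stratum x grid point).
    """
    if len(strata) == 0:
        raise ValueError("no strata supplied")
    node_grid = list(node_grid)
    threshold_grid = list(threshold_grid)

    nss_rows, needed_rows, records = {}, {}, []
    for s in strata:
        pi = s.corrected_prevalence
        raw = [nss_value(n, pi, params) for n in node_grid]
        nss_rows[s.label] = [round_half_up(100 * v, 1) for v in raw]
        for n, v in zip(node_grid, raw):
            records.append(
                {"stratum": s.label, "kind": "nss", "grid": n, "value": v}
            )
        needed = [nodes_needed(t, pi, params, n_max=n_max) for t in threshold_grid]
        needed_rows[s.label] = [
            _DASH if m is UNREACHABLE else int(m) for m in needed
        ]
        for t, m in zip(threshold_grid, needed):
            records.append(
                {
                    "stratum": s.label,
                    "kind": "nodes_needed",
                    "grid": t,
                    "value": np.nan if m is UNREACHABLE else m,
                }
            )

    nss_df = pd.DataFrame.from_dict(
        nss_rows, orient="index", columns=node_grid
    )
    nss_df.index.name = "stratum"
    needed_df = pd.DataFrame.from_dict(
        needed_rows,
        orient="index",
        columns=[f"{round_half_up(100 * t, 0):.0f}%" for t in threshold_grid],
    )
    needed_df.index.name = "stratum"
    return {
        "nss": nss_df,
        "nodes_needed": needed_df,
        "records": pd.DataFrame.from_records(records),
    }
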