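"""Synthetic SEER-like PTC cohort generator.

Emulates the structure the staging analysis assumes, with ground-truth
occult-metastasis labels that real pathology data cannot provide:

1. a latent true nodal status per patient (Bernoulli at the adjusted
   prevalence),
2. clinicopathological factor levels (gender, age group, extrathyroidal
   invasion, multifocality, tumor-size category, T stage) drawn
   conditionally on that status so every factor's marginal prevalence
   matches its configured adjusted incidence,
3. an examined-node count from a zero-truncated negative binomial drawn
   independently of the latent status (observed LN+ patients still show
   systematically more examined nodes, because detection conditions on
   k >= 1 and so favors larger dissections),
4. positive-node counts beta-binomial(n, alpha, beta) for truly positive
   patients — a draw of k = 0 IS an occult false negative — and zero for
   truly negative ones (no false-positive nodes),
5. exponential survival with a configurable hazard ratio for true
   node-positive status and uniform administrative censoring.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .betabin import BetaBinParams

__all__ = [
    "PatientRecord",
    "SyntheticConfig",
    "FACTORS",
    "MISSING_SIZE",
    "generate_cohort",
    "simulate_ln_positive",
    "cohort_summary",
    "occult_rate",
]

MISSING_SIZE = "missing"

#: Factor -> level order used across the package (summary/table row order).
FACTORS: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "age_group": ("<=45", ">45"),
    "ete": ("negative", "positive"),
    "multifocal": ("no", "yes"),
    "size_cat": ("<=1cm", "1-2cm", "2-4cm", ">4cm"),
    "t_stage": ("T1", "T2", "T3", "T4"),
}

# Marginal level frequencies of the emulated registry cohort (exact count
# ratios; tumor size over patients with size recorded).
_DEFAULT_FREQS: dict[str, dict[str, float]] = {
    "gender": {"male": 2886 / 12431, "female": 9545 / 12431},
    "age_group": {"<=45": 7127 / 12431, ">45": 5304 / 12431},
    "ete": {"negative": 9496 / 12431, "positive": 2935 / 12431},
    "multifocal": {"no": 8431 / 12431, "yes": 4000 / 12431},
    "size_cat": {
        "<=1cm": 3517 / 11572,
        "1-2cm": 3803 / 11572,
        "2-4cm": 3190 / 11572,
        ">4cm": 1062 / 11572,
    },
    "t_stage": {
        "T1": 6121 / 12431,
        "T2": 2237 / 12431,
        "T3": 3146 / 12431,
        "T4": 927 / 12431,
    },
}

# True (occult-corrected) metastasis prevalence per factor level.
_DEFAULT_PREVALENCES: dict[str, dict[str, float]] = {
    "gender": {"male": 0.776, "female": 0.538},
    "age_group": {"<=45": 0.632, ">45": 0.538},
    "ete": {"negative": 0.495, "positive": 0.905},
    "multifocal": {"no": 0.606, "yes": 0.563},
    "size_cat": {"<=1cm": 0.402, "1-2cm": 0.591, "2-4cm": 0.688, ">4cm": 0.760},
    "t_stage": {"T1": 0.424, "T2": 0.583, "T3": 0.815, "T4": 0.957},
}


@dataclass(frozen=True)
class PatientRecord:
    """One patient: covariates, node counts, follow-up.

    ``true_positive`` is simulation-only ground truth; ``None`` stands for
    real data where the latent status is unobservable.
    """

    gender: str
    age_group: str
    ete: bool
    multifocal: bool
    size_cat: str
    t_stage: str
    nodes_examined: int
    nodes_positive: int
    followup_months: float
    event: bool
    true_positive: bool | None = None

    def __post_init__(self) -> None:
        if self.nodes_examined < 1:
            raise ValueError("nodes_examined must be >= 1")
        if not 0 <= self.nodes_positive <= self.nodes_examined:
            raise ValueError("require 0 <= nodes_positive <= nodes_examined")
        if self.followup_months < 0:
            raise ValueError("followup_months must be nonnegative")
        if self.true_positive is False and self.nodes_positive > 0:
            raise ValueError(
                "truly node-negative patient cannot have positive nodes "
                "(no false-positive nodes)"
            )

    @property
    def observed_positive(self) -> bool:
        """Pathological LN+ status: at least one positive node found."""
        return self.nodes_positive >= 1


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification of a synthetic cohort.

    ``node_count_law`` maps latent LN status ("negative" / "positive") to
    (mean, dispersion) of the negative binomial that is zero-truncated to
    give examined-node counts.  The default uses the SAME law for both
    (median ~2, upper quartile ~5, tail into the twenties): the prevalence
    correction assumes examined-node counts carry no information about the
    latent status, and a status-dependent law would bias it.  Distinct
    entries are allowed for sensitivity analyses of exactly that bias.
    ``survival`` holds the baseline exponential hazard per month, the
    hazard ratio for true node-positive status, and the administrative
    censoring horizon in months.
    """

    n_patients: int = 12_431
    stratum_prevalences: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_PREVALENCES
    )
    level_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_FREQS
    )
    params: BetaBinParams = BetaBinParams(1.51, 1.15)
    node_count_law: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"negative": (3.0, 0.5), "positive": (3.0, 0.5)}
    )
    survival: Mapping[str, float] = field(
        default_factory=lambda: {
            "baseline_hazard": 0.002,
            "hr_positive": 2.0,
            "censor_months": 120.0,
        }
    )
    missing_size_frac: float = 0.069
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.missing_size_frac < 1.0:
            raise ValueError("missing_size_frac must lie in [0, 1)")
        for factor, levels in self.stratum_prevalences.items():
            for level, p in levels.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"prevalence for {factor}={level} outside [0, 1]: {p}"
                    )
        for factor, levels in self.level_freqs.items():
            total = sum(levels.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(
                    f"level frequencies for {factor} sum to {total}, not 1"
                )
            if any(f < 0 for f in levels.values()):
                raise ValueError(f"negative level frequency in {factor}")

    def overall_prevalence(self) -> float:
        """Mean over factors of the frequency-weighted true prevalence."""
        totals = [
            sum(
                self.level_freqs[factor][lvl] * pi
                for lvl, pi in levels.items()
            )
            for factor, levels in self.stratum_prevalences.items()
        ]
        return float(np.mean(totals))


def _ztnb_sample(rng: np.random.Generator, mean: float, disp: float, size: int):
    """Zero-truncated negative binomial via inverse-cdf rejection of zero.

    ``disp`` is the NB shape (smaller = more overdispersed); parameterized
    by the untruncated mean.
    """
    n_shape = disp
    p = n_shape / (n_shape + mean)
    p0 = stats.nbinom.pmf(0, n_shape, p)
    # inverse cdf conditioned on X >= 1
    u = rng.uniform(p0, 1.0, size=size)
    return stats.nbinom.ppf(u, n_shape, p).astype(int)


def _conditional_level_probs(
    freqs: Mapping[str, float], prevs: Mapping[str, float]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """P(level | true status) by Bayes inversion of marginal freqs and
    per-level prevalences."""
    levels = list(freqs)
    f = np.array([freqs[l] for l in levels])
    pi = np.array([prevs[l] for l in levels])
    pos = f * pi
    neg = f * (1.0 - pi)
    # degenerate priors: the status never occurs, fall back to marginals
    p_pos = pos / pos.sum() if pos.sum() > 0 else f / f.sum()
    p_neg = neg / neg.sum() if neg.sum() > 0 else f / f.sum()
    return levels, p_pos, p_neg


def generate_cohort(config: SyntheticConfig) -> list[PatientRecord]:
    """Draw a fully synthetic cohort under the configured generative law."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pi_overall = config.overall_prevalence()

    true_pos = rng.uniform(size=n) < pi_overall

    levels_by_factor: dict[str, np.ndarray] = {}
    for factor in FACTORS:
        levels, p_pos, p_neg = _conditional_level_probs(
            config.level_freqs[factor], config.stratum_prevalences[factor]
        )
        idx_pos = rng.choice(len(levels), size=n, p=p_pos)
        idx_neg = rng.choice(len(levels), size=n, p=p_neg)
        idx = np.where(true_pos, idx_pos, idx_neg)
        levels_by_factor[factor] = np.array(levels, dtype=object)[idx]

    mean_neg, disp_neg = config.node_count_law["negative"]
    mean_pos, disp_pos = config.node_count_law["positive"]
    nodes = np.where(
        true_pos,
        _ztnb_sample(rng, mean_pos, disp_pos, n),
        _ztnb_sample(rng, mean_neg, disp_neg, n),
    )

    k = np.zeros(n, dtype=int)
    if np.any(true_pos):
        a, b = config.params.alpha, config.params.beta
        k[true_pos] = stats.betabinom.rvs(
            nodes[true_pos], a, b, random_state=rng
        )

    h0 = config.survival["baseline_hazard"]
    hr = config.survival["hr_positive"]
    horizon = config.survival["censor_months"]
    hazard = h0 * np.where(true_pos, hr, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0.0, horizon, size=n)
    followup = np.minimum(t_event, t_censor)
    event = t_event <= t_censor

    missing = rng.uniform(size=n) < config.missing_size_frac
    size_cat = levels_by_factor["size_cat"].copy()
    size_cat[missing] = MISSING_SIZE

    return [
        PatientRecord(
            gender=levels_by_factor["gender"][i],
            age_group=levels_by_factor["age_group"][i],
            ete=levels_by_factor["ete"][i] == "positive",
            multifocal=levels_by_factor["multifocal"][i] == "yes",
            size_cat=size_cat[i],
            t_stage=levels_by_factor["t_stage"][i],
            nodes_examined=int(nodes[i]),
            nodes_positive=int(k[i]),
            followup_months=float(followup[i]),
            event=bool(event[i]),
            true_positive=bool(true_pos[i]),
        )
        for i in range(n)
    ]


def simulate_ln_positive(
    n_patients: int,
    params: BetaBinParams,
    node_law: tuple[float, float] = (3.0, 0.5),
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Simulate (k, n) pairs for node-positive patients only.

    Examined-node counts come from the zero-truncated negative binomial
    ``node_law``; positive counts are beta-binomial draws conditioned on
    k >= 1 by rejection — the refitting experiment's sampling scheme.
    """
    rng = np.random.default_rng(seed)
    a, b = params.alpha, params.beta
    out: list[tuple[int, int]] = []
    while len(out) < n_patients:
        m = max(2 * (n_patients - len(out)), 64)
        n = _ztnb_sample(rng, node_law[0], node_law[1], m)
        k = stats.betabinom.rvs(n, a, b, random_state=rng)
        keep = k >= 1
        out.extend(zip(k[keep].tolist(), n[keep].tolist()))
    return out[:n_patients]


def _factor_level(rec: PatientRecord, factor: str) -> str:
    v = getattr(rec, factor)
    if factor == "ete":
        return "positive" if v else "negative"
    if factor == "multifocal":
        return "yes" if v else "no"
    return v


def cohort_summary(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Baseline table: per factor level, counts, LN+/LN− split, and the
    median/IQR of examined-node counts."""
    if len(records) == 0:
        raise ValueError("empty cohort")
    rows = []
    total = len(records)
    for factor, order in FACTORS.items():
        order = list(order) + ([MISSING_SIZE] if factor == "size_cat" else [])
        for level in order:
            sub = [r for r in records if _factor_level(r, factor) == level]
            if not sub:
                continue
            nodes = np.array([r.nodes_examined for r in sub])
            ln_pos = sum(r.observed_positive for r in sub)
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "n": len(sub),
                    "percent": 100.0 * len(sub) / total,
                    "ln_positive": ln_pos,
                    "ln_negative": len(sub) - ln_pos,
                    "nodes_median": float(np.median(nodes)),
                    "nodes_q1": float(np.percentile(nodes, 25)),
                    "nodes_q3": float(np.percentile(nodes, 75)),
                }
            )
    return pd.DataFrame.from_records(rows)


def occult_rate(records: Sequence[PatientRecord]) -> float:
    """Ground-truth occult-metastasis rate among observed-negative patients.

    Fraction with ``true_positive`` and zero positive nodes among all
    patients whose examined nodes were all negative — the complement of
    what the staging score estimates.  Requires simulated records.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    if any(r.true_positive is None for r in records):
        raise ValueError("occult_rate requires ground-truth labels")
    observed_neg = [r for r in records if not r.observed_positive]
    if not observed_neg:
        raise ValueError("no observed-negative patients")
    return float(np.mean([r.true_positive for r in observed_neg]))
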