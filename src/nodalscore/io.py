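"""Cohort file schema, pipeline configuration and orchestration.

The cohort is a delimited text table (comma or tab, auto-detected from
the header) with one row per patient:

    gender, age_group, ete, multifocal, size_cat, t_stage,
    nodes_examined, nodes_positive, followup_months, event
    [, true_positive]

``run_pipeline`` chains the full analysis: fit the beta-binomial shapes on
node-positive patients (zero-truncated ML), correct the per-factor
prevalences, export the false-negative probability curve, build NSS and
nodes-needed tables per factor, and compare overall survival across NSS
quartiles.  All outputs are delimited tables plus a JSON summary and a
plain-text log; runs are deterministic given the input and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .betabin import BetaBinParams, FitResult, fit_truncated, staging_fn_prob
from .nss import (
    NSSCurve,
    StratumEstimate,
    build_nss_table,
    estimate_stratum,
    nss_curve,
)
from .survival import assign_nss_groups, km_estimate, logrank_test
from .synth import (
    FACTORS,
    MISSING_SIZE,
    PatientRecord,
    SyntheticConfig,
    _factor_level,
    generate_cohort,
)

__all__ = [
    "COHORT_COLUMNS",
    "PipelineConfig",
    "PipelineResult",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
]

log = logging.getLogger("nodalscore")

COHORT_COLUMNS = (
    "gender",
    "age_group",
    "ete",
    "multifocal",
    "size_cat",
    "t_stage",
    "nodes_examined",
    "nodes_positive",
    "followup_months",
    "event",
)
_OPTIONAL_COLUMNS = ("true_positive",)

_BOOL_MAP = {
    "1": True, "0": False, "true": True, "false": False,
    "yes": True, "no": False,
}


def _parse_bool(value, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s not in _BOOL_MAP:
        raise ValueError(f"row {row}: cannot parse {column}={value!r} as flag")
    return _BOOL_MAP[s]


def read_cohort(path) -> list[PatientRecord]:
    """Read and validate a cohort table.

    The delimiter (comma or tab) is sniffed from the header line.  Rows
    violating the record invariants (k > n, negative counts, unparseable
    flags) raise with the offending row number; missing mandatory columns
    raise a schema error listing the absentees.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing mandatory columns: {missing}")
    has_truth = "true_positive" in df.columns

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        d = dict(zip(df.columns, row))
        try:
            truth = None
            if has_truth and str(d["true_positive"]).strip() != "":
                truth = _parse_bool(d["true_positive"], "true_positive", i)
            rec = PatientRecord(
                gender=d["gender"].strip(),
                age_group=d["age_group"].strip(),
                ete=_parse_bool(d["ete"], "ete", i),
                multifocal=_parse_bool(d["multifocal"], "multifocal", i),
                size_cat=d["size_cat"].strip() or MISSING_SIZE,
                t_stage=d["t_stage"].strip(),
                nodes_examined=int(d["nodes_examined"]),
                nodes_positive=int(d["nodes_positive"]),
                followup_months=float(d["followup_months"]),
                event=_parse_bool(d["event"], "event", i),
                true_positive=truth,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {i}: invalid record ({exc})") from exc
        records.append(rec)
    return records


def write_cohort(records: Sequence[PatientRecord], path, sep: str = ",") -> None:
    """Write a cohort in the delimited schema (round-trips read_cohort)."""
    rows = []
    for r in records:
        row = {
            "gender": r.gender,
            "age_group": r.age_group,
            "ete": int(r.ete),
            "multifocal": int(r.multifocal),
            "size_cat": r.size_cat,
            "t_stage": r.t_stage,
            "nodes_examined": r.nodes_examined,
            "nodes_positive": r.nodes_positive,
            "followup_months": repr(r.followup_months),
            "event": int(r.event),
        }
        if r.true_positive is not None:
            row["true_positive"] = int(r.true_positive)
        rows.append(row)
    pd.DataFrame.from_records(rows).to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings.

    Exactly one of ``input_path`` (a cohort file) or ``synthetic`` (a
    generator config) supplies the cohort.  ``inject_params`` /
    ``inject_prevalences`` bypass fitting/correction with externally given
    shapes and per-stratum prevalences, for reproducing published tables
    from printed inputs.
    """

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    factors: tuple[str, ...] = tuple(FACTORS)
    node_grid: tuple[int, ...] = (1, 5, 10, 15, 20, 25)
    threshold_grid: tuple[float, ...] = (0.80, 0.85, 0.90, 0.95)
    n_max: int = 100
    output_dir: str | None = None
    seed: int = 0
    # Quartile survival comparison: score pathologically node-negative
    # patients (the population the NSS is defined for) with the T-stage
    # curves by default — the factor with the widest prevalence contrast.
    survival_factor: str = "t_stage"
    include_ln_positive_in_survival: bool = False
    inject_params: BetaBinParams | None = None
    inject_prevalences: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.input_path is not None and self.synthetic is not None:
            raise ValueError("give input_path or synthetic, not both")
        if self.input_path is None and self.synthetic is None:
            if self.inject_params is None or self.inject_prevalences is None:
                raise ValueError(
                    "need a cohort (input_path or synthetic) unless both "
                    "params and prevalences are injected"
                )
        t = self.threshold_grid
        if any(not 0 < x < 1 for x in t) or list(t) != sorted(set(t)):
            raise ValueError("thresholds must be strictly increasing in (0,1)")
        g = self.node_grid
        if any(int(x) != x or x < 1 for x in g) or list(g) != sorted(set(g)):
            raise ValueError("node grid must be strictly increasing positive ints")
        unknown = set(self.factors) - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown factors: {sorted(unknown)}")


@dataclass(frozen=True)
class PipelineResult:
    """Bundle of everything the pipeline computed."""

    fit: FitResult | None
    params: BetaBinParams
    strata: dict[str, list[StratumEstimate]]
    curves: dict[str, dict[str, NSSCurve]]
    fn_curve: pd.DataFrame
    tables: dict[str, dict[str, pd.DataFrame]]
    survival: dict[str, dict]
    summary: dict


def _stratum_inputs(records, factor):
    """Per-level (observed-positive flags, node counts) for one factor."""
    out = {}
    for r in records:
        lvl = _factor_level(r, factor)
        if factor == "size_cat" and lvl == MISSING_SIZE:
            continue  # missing size excluded from size-stratified estimates
        out.setdefault(lvl, ([], []))
        out[lvl][0].append(r.observed_positive)
        out[lvl][1].append(r.nodes_examined)
    order = list(FACTORS[factor])
    return {lvl: out[lvl] for lvl in order if lvl in out}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run fit → prevalence correction → NSS tables → survival."""
    records: list[PatientRecord] = []
    if config.synthetic is not None:
        synth_cfg = replace(config.synthetic, seed=config.seed)
        log.info("generating synthetic cohort: n=%d seed=%d",
                 synth_cfg.n_patients, synth_cfg.seed)
        records = generate_cohort(synth_cfg)
    elif config.input_path is not None:
        log.info("reading cohort from %s", config.input_path)
        records = read_cohort(config.input_path)
        if not records:
            raise ValueError("cohort file contains no patient rows")

    # --- stage 1: beta-binomial shapes -------------------------------
    fit: FitResult | None = None
    if config.inject_params is not None:
        params = config.inject_params
        log.info("using injected shapes alpha=%.4g beta=%.4g",
                 params.alpha, params.beta)
    else:
        ln_pos = [
            (r.nodes_positive, r.nodes_examined)
            for r in records
            if r.nodes_positive >= 1
        ]
        if len(ln_pos) < 2:
            raise ValueError("fit stage: fewer than 2 node-positive patients")
        fit = fit_truncated(ln_pos)
        params = fit.params
        log.info(
            "fitted zero-truncated beta-binomial on %d LN+ patients: "
            "alpha=%.4f beta=%.4f (converged=%s)",
            fit.n_patients, params.alpha, params.beta, fit.converged,
        )

    # --- stage 2: per-factor strata ----------------------------------
    factors = tuple(
        f
        for f in config.factors
        if config.inject_prevalences is None or f in config.inject_prevalences
    )
    strata: dict[str, list[StratumEstimate]] = {}
    for factor in factors:
        if config.inject_prevalences is not None:
            levels = config.inject_prevalences[factor]
            strata[factor] = [
                StratumEstimate(
                    label=lvl,
                    n_patients=0,
                    n_observed_positive=0,
                    observed_prevalence=0.0,
                    corrected_prevalence=pi,
                )
                for lvl, pi in levels.items()
            ]
        else:
            strata[factor] = [
                estimate_stratum(lvl, pos, nodes, params)
                for lvl, (pos, nodes) in _stratum_inputs(records, factor).items()
            ]
        for s in strata[factor]:
            log.info(
                "stratum %s/%s: observed %.3f corrected %.3f",
                factor, s.label, s.observed_prevalence, s.corrected_prevalence,
            )

    # --- stage 3: FN-probability curve and NSS tables ----------------
    n_grid = np.arange(0, config.n_max + 1)
    fn_curve = pd.DataFrame(
        {"nodes_examined": n_grid, "fn_prob": staging_fn_prob(n_grid, params)}
    )
    curves = {
        factor: {
            s.label: nss_curve(s, params, n_max=config.n_max)
            for s in strata[factor]
        }
        for factor in factors
    }
    tables = {
        factor: build_nss_table(
            strata[factor],
            params,
            node_grid=config.node_grid,
            threshold_grid=config.threshold_grid,
            n_max=config.n_max,
        )
        for factor in factors
    }

    # --- stage 4: survival across NSS quartiles ----------------------
    survival: dict[str, dict] = {}
    if records and config.survival_factor in curves:
        try:
            groups = assign_nss_groups(
                records,
                curves[config.survival_factor],
                config.survival_factor,
                include_ln_positive=config.include_ln_positive_in_survival,
            )
            lr = logrank_test(groups)
            survival[config.survival_factor] = {
                "groups": groups,
                "km": {g.label: km_estimate(g.times, g.events) for g in groups},
                "logrank": lr,
                "group_sizes": {g.label: len(g) for g in groups},
            }
            log.info(
                "log-rank across NSS quartiles (%s): chi2=%.3f df=%d p=%.3g",
                config.survival_factor, lr.statistic, lr.df, lr.pvalue,
            )
        except ValueError as exc:
            raise ValueError(f"survival stage: {exc}") from exc

    summary = {
        "n_patients": len(records),
        "alpha": params.alpha,
        "beta": params.beta,
        "fit": None
        if fit is None
        else {
            "loglik": fit.loglik,
            "converged": fit.converged,
            "n_patients": fit.n_patients,
            "stderr_alpha": fit.stderr_alpha,
            "stderr_beta": fit.stderr_beta,
        },
        "strata": {
            factor: {
                s.label: {
                    "n": s.n_patients,
                    "observed_prevalence": s.observed_prevalence,
                    "corrected_prevalence": s.corrected_prevalence,
                }
                for s in strata[factor]
            }
            for factor in factors
        },
        "logrank": {
            factor: {
                "statistic": d["logrank"].statistic,
                "df": d["logrank"].df,
                "pvalue": d["logrank"].pvalue,
                "group_sizes": d["group_sizes"],
            }
            for factor, d in survival.items()
        },
        "seed": config.seed,
    }

    result = PipelineResult(
        fit=fit,
        params=params,
        strata=strata,
        curves=curves,
        fn_curve=fn_curve,
        tables=tables,
        survival=survival,
        summary=summary,
    )
    if config.output_dir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.fn_curve.to_csv(out / "fn_probability_curve.csv", index=False)
    for factor, tabs in result.tables.items():
        tabs["nss"].to_csv(out / f"nss_table_{factor}.csv")
        tabs["nodes_needed"].to_csv(out / f"nodes_needed_{factor}.csv")
        tabs["records"].to_csv(out / f"nss_records_{factor}.csv", index=False)
    for factor, d in result.survival.items():
        frames = []
        for label, km in d["km"].items():
            frames.append(
                pd.DataFrame(
                    {
                        "group": label,
                        "time": km.times,
                        "at_risk": km.at_risk,
                        "events": km.n_events,
                        "survival": km.survival,
                    }
                )
            )
        if frames:
            pd.concat(frames).to_csv(
                out / f"km_curves_{factor}.csv", index=False
            )
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
    with open(out / "run.log", "w") as fh:
        s = result.summary
        fh.write(
            f"n_patients={s['n_patients']} alpha={s['alpha']:.6f} "
            f"beta={s['beta']:.6f} seed={s['seed']}\n"
        )
        if s["fit"]:
            fh.write(
                f"fit: loglik={s['fit']['loglik']:.4f} "
                f"converged={s['fit']['converged']} "
                f"n={s['fit']['n_patients']}\n"
            )
    log.info("wrote outputs to %s", out)
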