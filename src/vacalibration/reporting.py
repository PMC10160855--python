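"""End-to-end orchestration: preprocess -> misclassification -> calibration
-> model comparison, with all report tables written as CSV/JSON.

Outputs per run: the raw-CSMF table, per-algorithm misclassification
matrices with fit reports, single- vs multi-cause sensitivity deltas, the
calibrated-vs-uncalibrated CSMF table with credible intervals, posterior
draws in columnar CSV, a WAIC comparison table, and a run-metadata JSON
(seed, package versions, timings).  Plotting is intentionally kept out of
the pipeline; all outputs are plain text.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import GBConfig, sample_posterior, summarize_posterior
from .fixtures import load_fixture
from .io import read_records, write_csmf, write_matrix
from .misclassification import (
    fit_multicause_M,
    fit_singlecause_M,
    sensitivity_delta,
)
from .model_eval import uncalibrated_q_draws, waic, waic_uncalibrated
from .preprocess import (
    PreprocessConfig,
    exclude_sites,
    impute_paired_inconclusive,
    impute_survey_inconclusive,
    plurality_rule,
    raw_csmf,
)
from .types import CauseList, children_causes, neonates_causes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    stratum: str
    algorithms: list[str]
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    gb: GBConfig = field(default_factory=GBConfig)
    output_dir: str | Path = "results"
    causes: list[str] | None = None  # required for non-canonical strata
    ensemble: bool = True
    resume: bool = False

    def cause_list(self) -> CauseList:
        if self.stratum == "children":
            return children_causes(self.preprocess.grouping)
        if self.stratum == "neonates":
            return neonates_causes(self.preprocess.grouping)
        if not self.causes:
            raise ValueError(
                f"stratum {self.stratum!r} is not canonical; supply 'causes'"
            )
        return CauseList(self.stratum, tuple(self.causes),
                         self.preprocess.grouping)


def _prepare(config: RunConfig, paired_path, survey_path):
    """Read, exclude and impute; returns (cause_list, paired, survey)."""
    cl = config.cause_list()
    paired = read_records(paired_path, cl, "paired")
    survey = read_records(survey_path, cl, "survey")
    paired = exclude_sites(paired, config.preprocess.exclude_sites)
    for algo in config.algorithms:
        if any(r.inconclusive.get(algo, False) for r in paired):
            paired = impute_paired_inconclusive(paired, algo, cl)
        if any(r.inconclusive.get(algo, False) for r in survey):
            survey = impute_survey_inconclusive(survey, algo)
    return cl, paired, survey


def _calibration_models(config: RunConfig) -> dict[str, list[str]]:
    models = {a: [a] for a in config.algorithms}
    if config.ensemble and len(config.algorithms) > 1:
        models["ensemble"] = list(config.algorithms)
    return models


def run_pipeline(config: RunConfig, paired_path, survey_path) -> dict:
    """Run the full analysis; returns a bundle of output paths and the
    in-memory results."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}
    bundle: dict = {"output_dir": str(out)}

    cl, paired, survey = _prepare(config, paired_path, survey_path)
    timings["prepare"] = time.time() - t0

    # raw CSMF table (survey side)
    rows = []
    for algo in config.algorithms:
        agg, q = raw_csmf(survey, algo)
        for cause, a_j, q_j in zip(cl.causes, agg, q):
            rows.append({"algorithm": algo, "cause": cause,
                         "aggregate_score": a_j, "pct": 100.0 * q_j})
    raw_tab = pd.DataFrame(rows)
    raw_tab.rename(columns={"cause": "cause"}).pipe(
        write_csmf, out / "raw_csmf.csv")
    bundle["raw_csmf"] = raw_tab

    # misclassification matrices, multi- and single-cause
    m_fits, fit_report = {}, {}
    sens_rows = []
    xs = np.stack([r.x for r in paired])
    for algo in config.algorithms:
        ys = np.stack([r.va[algo] for r in paired])
        fit = fit_multicause_M(xs, ys, cause_labels=list(cl.causes))
        m_fits[algo] = fit.m
        write_matrix(fit.m, cl, out / f"M_{algo}.csv")
        fit_report[algo] = {
            "converged": bool(fit.converged),
            "iterations": int(fit.iterations),
            "final_loss": float(fit.final_loss),
            "n_effective": fit.n_effective.tolist(),
        }
        # single-cause comparison on non-imputed records only
        pairs = [(cl.index(r.underlying),
                  plurality_rule(r.va[algo], config.preprocess.tie_break))
                 for r in paired if not r.imputed.get(algo, False)]
        try:
            m_single = fit_singlecause_M(pairs, C=len(cl))
            single, delta = sensitivity_delta(m_single, fit.m)
            for cause, s, d in zip(cl.causes, single, delta):
                sens_rows.append({"algorithm": algo, "cause": cause,
                                  "single_sensitivity": s,
                                  "multi_minus_single": d})
        except ValueError as exc:
            logger.warning("single-cause comparison skipped for %s: %s",
                           algo, exc)
    (out / "fit_report.json").write_text(json.dumps(fit_report, indent=1))
    if sens_rows:
        pd.DataFrame(sens_rows).pipe(write_csmf, out / "sensitivity.csv")
    bundle["m_fits"] = m_fits
    timings["misclassification"] = time.time() - t0 - sum(timings.values())

    # calibration: per algorithm and ensemble
    csmf_rows, draw_frames, diag = [], [], {}
    waic_rows = []
    all_draws = {}
    for model, algos in _calibration_models(config).items():
        gb = copy.deepcopy(config.gb)
        draws = sample_posterior(paired, survey, gb, algos,
                                 cause_labels=list(cl.causes),
                                 m_init={a: m_fits[a] for a in algos})
        all_draws[model] = draws
        summ = summarize_posterior(draws)["p"]
        for _, r in summ.iterrows():
            csmf_rows.append({"model": model, "cause": r["cause"],
                              "mean": r["mean"], "lower": r["lower"],
                              "upper": r["upper"]})
        pdf = pd.DataFrame(draws.p_draws, columns=list(cl.causes))
        pdf.insert(0, "model", model)
        draw_frames.append(pdf)
        diag[model] = {
            "rhat_p": np.asarray(
                draws.diagnostics.get("rhat_p", [])).tolist(),
            "ess_p": np.asarray(draws.diagnostics.get("ess_p", [])).tolist(),
            "warnings": draws.diagnostics.get("warnings", []),
        }
        cal = waic(draws.pointwise_loss)
        waic_rows.append({"model": model, "fit": "calibrated",
                          "lppd": cal.lppd, "p_waic": cal.p_waic,
                          "waic": cal.waic})
        if len(algos) == 1:
            q_draws = uncalibrated_q_draws(
                survey, algos[0], n_draws=draws.p_draws.shape[0],
                seed=config.gb.seed + 1)
            unc = waic_uncalibrated(survey, algos[0], q_draws,
                                    paired_data=paired)
            waic_rows.append({"model": model, "fit": "uncalibrated",
                              "lppd": unc.lppd, "p_waic": unc.p_waic,
                              "waic": unc.waic})
    pd.DataFrame(csmf_rows).pipe(write_csmf, out / "csmf_calibrated.csv")
    pd.concat(draw_frames).to_csv(out / "p_draws.csv", index=False)
    pd.DataFrame(waic_rows).to_csv(out / "waic.csv", index=False)
    (out / "diagnostics.json").write_text(json.dumps(diag, indent=1))
    bundle["csmf"] = pd.DataFrame(csmf_rows)
    bundle["waic"] = pd.DataFrame(waic_rows)
    bundle["draws"] = all_draws
    timings["calibration"] = time.time() - t0 - sum(timings.values())

    meta = {
        "seed": config.gb.seed,
        "algorithms": config.algorithms,
        "stratum": config.stratum,
        "n_paired": len(paired),
        "n_survey": len(survey),
        "vacalibration_version": __version__,
        "numpy_version": np.__version__,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=1))
    bundle["metadata"] = meta
    return bundle


def _reweight_rank_scores(records, algorithm: str, w: float):
    """Reassign the top/runner-up weights of two-cause rank-algorithm
    scores (non-imputed records with exactly two nonzero entries)."""
    out = []
    for r in records:
        y = r.va.get(algorithm)
        if (y is not None and not r.imputed.get(algorithm, False)
                and np.count_nonzero(y) == 2):
            r = copy.deepcopy(r)
            order = np.argsort(-y)
            y_new = np.zeros_like(y)
            y_new[order[0]] = w
            y_new[order[1]] = 1.0 - w
            r.va[algorithm] = y_new
        out.append(r)
    return out


def weight_sensitivity(config: RunConfig, paired_path, survey_path,
                       weights: list[float], rank_algorithm: str = "eava",
                       ) -> pd.DataFrame:
    """Re-run the calibration of the rank-based algorithm across top-cause
    weights (same seed), tabulating CSMF point estimates and intervals."""
    for w in weights:
        if not 0.5 < w <= 1.0:
            raise ValueError(f"weight {w} outside (0.5, 1]")
    cl, paired0, survey0 = _prepare(config, paired_path, survey_path)
    rows = []
    for w in weights:
        paired = _reweight_rank_scores(paired0, rank_algorithm, w)
        survey = _reweight_rank_scores(survey0, rank_algorithm, w)
        gb = copy.deepcopy(config.gb)
        draws = sample_posterior(paired, survey, gb, [rank_algorithm],
                                 cause_labels=list(cl.causes),
                                 pointwise=False)
        summ = summarize_posterior(draws)["p"]
        for _, r in summ.iterrows():
            rows.append({"weight": w, "cause": r["cause"], "mean": r["mean"],
                         "lower": r["lower"], "upper": r["upper"]})
    tab = pd.DataFrame(rows)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tab.to_csv(out / "weight_sensitivity.csv", index=False)
    return tab


def fixtures_report(output_dir) -> dict:
    """Degraded fixtures-only mode: raw CSMFs recomputed from the packaged
    aggregate-score tables and summaries of the reference contingency
    tables.  No calibration is possible (the fixtures carry no paired VA
    scores)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, stratum in (("table1", "children"), ("table2", "neonates")):
        tab = load_fixture(name)
        for algo in sorted(tab.scores):
            q = tab.csmf(algo)
            for cause, s, q_j, printed in zip(
                    tab.cause_list.causes, tab.scores[algo], q,
                    tab.printed_pct[algo]):
                rows.append({"stratum": stratum, "algorithm": algo,
                             "cause": cause, "aggregate_score": s,
                             "pct": 100.0 * q_j, "printed_pct": printed})
    raw = pd.DataFrame(rows)
    raw.to_csv(out / "fixtures_raw_csmf.csv", index=False)

    ct_rows = []
    for name, stratum in (("table3", "children"), ("table4", "neonates")):
        tab = load_fixture(name)
        for i, cause in enumerate(tab.cause_list.causes):
            ct_rows.append({
                "stratum": stratum, "cause": cause,
                "underlying_total": int(tab.counts[i].sum()),
                "immediate_total": int(tab.counts[:, i].sum()),
                "single_cause": int(tab.counts[i, i]),
            })
        ct_rows.append({"stratum": stratum, "cause": "TOTAL",
                        "underlying_total": tab.total,
                        "immediate_total": tab.total,
                        "single_cause": int(np.trace(tab.counts))})
    ct = pd.DataFrame(ct_rows)
    ct.to_csv(out / "fixtures_contingency_summary.csv", index=False)
    return {"raw_csmf": raw, "contingency": ct}
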