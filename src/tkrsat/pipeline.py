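"""End-to-end orchestration: generate -> exclude -> compare -> impute -> select
-> validate -> transport, from one :class:`~tkrsat.config.RunConfig`.

Every stage writes its artifacts to the output directory as it finishes,
so a failing stage leaves prior outputs on disk; the run report records
parameters, seeds, per-stage timing and SHA-256 hashes of every artifact,
and re-running the same configuration reproduces all outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare as compare_mod
from .cohort import code_predictors, apply_exclusions, write_cohort_csv, read_cohort_csv
from .config import RunConfig
from .errors import StageError
from .impute import ImputedStack, impute, rubin_pool
from .select import bootstrap_select
from .synth import generate_cohort, generate_raw_cohort, inject_missingness
from .transport import assess_transport
from .validate import fit_logistic, optimism_corrected_auc, predict_probability

log = logging.getLogger("tkrsat")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


def _prepare_cohort(cfg: RunConfig, which: str, outdir: Path):
    """Generate (or load) one cohort, run exclusions, inject missingness, code."""
    spec = getattr(cfg, which)
    cascade = getattr(cfg, f"{which}_cascade")
    if isinstance(spec, str):
        records = read_cohort_csv(spec)
        exclusion_log = None
    elif cascade is not None:
        raw = generate_raw_cohort(spec, cascade, seed=cfg.seeds[f"generate_{which}"])
        records, exclusion_log = apply_exclusions(raw)
        write_cohort_csv(raw, outdir / f"{which}_raw.csv")
        _write_csv(exclusion_log, outdir / f"{which}_exclusion_log.csv")
    else:
        records = generate_cohort(spec, seed=cfg.seeds[f"generate_{which}"])
        exclusion_log = None
    if not isinstance(spec, str) and spec.missingness_rates:
        records = inject_missingness(
            records, spec.missingness_rates, mechanism=cfg.missingness_mechanism,
            seed=cfg.seeds[f"missingness_{which}"])
    write_cohort_csv(records, outdir / f"{which}_cohort.csv")
    coded = code_predictors(records)
    return records, coded, exclusion_log


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the run report (also written as JSON).

    Any stage error is re-raised as :class:`StageError` naming the stage;
    artifacts of completed stages persist in ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_dict(), "stages": {}}
    t_all = time.time()

    def stage(name):
        class _Ctx:
            def __enter__(self):
                log.info("stage %s ...", name)
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, str(exc)) from exc
                report["stages"][name] = {"seconds": round(time.time() - self.t0, 3)}
                log.info("stage %s done in %.1fs", name, time.time() - self.t0)
        return _Ctx()

    with stage("cohorts"):
        dev_records, dev_coded, dev_log = _prepare_cohort(cfg, "development", outdir)
        ext_records, ext_coded, ext_log = _prepare_cohort(cfg, "external", outdir)
        ev_d, n_d, pct_d = compare_mod.outcome_prevalence(dev_coded)
        ev_e, n_e, pct_e = compare_mod.outcome_prevalence(ext_coded)
        report["development_n"] = n_d
        report["external_n"] = n_e
        report["development_nonsatisfied_percent"] = pct_d
        report["external_nonsatisfied_percent"] = pct_e

    with stage("compare"):
        table1 = compare_mod.compare_cohorts(dev_coded, ext_coded)
        _write_csv(table1, outdir / "case_mix_comparison.csv")

    with stage("impute"):
        dev_stack = impute(dev_coded, m=cfg.m, n_cycles=cfg.n_cycles,
                           seed=cfg.seeds["impute_development"],
                           auxiliary=("hospital",))
        # single-centre external registry: no auxiliary variable
        ext_stack = impute(ext_coded, m=cfg.m, n_cycles=cfg.n_cycles,
                           seed=cfg.seeds["impute_external"], auxiliary=())
        _write_csv(dev_stack.to_long(), outdir / "development_imputed_long.csv")
        _write_csv(ext_stack.to_long(), outdir / "external_imputed_long.csv")

    with stage("select"):
        selection = bootstrap_select(
            dev_stack, B=cfg.B_select, alpha=cfg.alpha, threshold=cfg.threshold,
            forced=cfg.forced, seed=cfg.seeds["select"])
        _write_csv(selection.to_frame(), outdir / "selection_report.csv")
        report["retained_predictors"] = selection.retained

    with stage("validate"):
        predictors = selection.retained
        vrep = optimism_corrected_auc(
            dev_stack, predictors, B=cfg.B_validate, seed=cfg.seeds["validate"],
            candidates=(list(selection.inclusion_frequency.index)
                        if cfg.reselect_in_validation else None),
            alpha=cfg.alpha, forced=cfg.forced, bins=cfg.bins)
        fits = [fit_logistic(d, predictors) for d in dev_stack]
        pooled = rubin_pool(fits)
        pooled.to_json(outdir / "development_model.json")
        _write_csv(pooled.summary().reset_index(names="term"),
                   outdir / "development_coefficients.csv")
        _write_csv(vrep.calibration, outdir / "development_calibration.csv")
        with open(outdir / "validation_report.json", "w") as fh:
            json.dump(vrep.to_dict(), fh, indent=1)
        report["auc_apparent"] = vrep.auc_apparent
        report["optimism"] = vrep.optimism
        report["auc_corrected"] = vrep.auc_corrected

    with stage("transport"):
        trep = assess_transport(pooled, ext_stack, bins=cfg.bins)
        _write_csv(trep.calibration_transported, outdir / "transport_calibration.csv")
        _write_csv(trep.coefficient_table().reset_index(names="term"),
                   outdir / "coefficients_side_by_side.csv")
        with open(outdir / "transport_report.json", "w") as fh:
            json.dump(trep.to_dict(), fh, indent=1)
        report["auc_transported"] = trep.auc_transported
        report["auc_reestimated"] = trep.auc_reestimated

    with stage("plots"):
        from . import plots
        d0 = dev_stack.datasets[0]
        p_dev = predict_probability(pooled, d0)
        ax = plots.plot_roc(p_dev, d0["outcome_nonsatisfied"], label="development")
        plots.save(ax, outdir / "roc_development.svg")
        plots.save(plots.plot_calibration(vrep.calibration, title="Development"),
                   outdir / "calibration_development.svg")
        plots.save(plots.plot_calibration(trep.calibration_transported,
                                          title="Transported"),
                   outdir / "calibration_transported.svg")

    report["seconds_total"] = round(time.time() - t_all, 3)
    report["artifacts"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.is_file() and p.suffix in {".csv", ".json", ".svg"}
        and p.name != "run_report.json"
    }
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
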