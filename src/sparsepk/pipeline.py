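"""End-to-end run orchestration and report assembly.

``run_pipeline`` executes the full analysis chain on a study CSV (or a
simulated study): preprocessing (M6 + Grubbs) -> NCA -> macroconstant model
fitting and AIC selection -> bootstrap/VPC validation -> UIR construction,
writing an NCA summary table, a parameter/bootstrap table, VPC bands, a GOF
table, the UIR as JSON, and a plain-text run log of every decision.  Every
output names the hash of the configuration that produced it, and all
stochastic stages draw from the single configured seed, so identical configs
give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .macrofit import select_model
from .nca import NCAOptions, bioavailability, nca_summary
from .preprocess import preprocess_arm
from .simulate import default_truth, simulate_study
from .study import StudyArm, read_study_csv, write_study_csv
from .uir import uir_from_fit
from .validation import bootstrap_fit, gof_tables, vpc

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)

_DEFAULTS = {
    "study_csv": "",
    "simulate_analyte": "",
    "simulate_route": "IV",
    "analyte": "",
    "seed": "0",
    "terms": "auto",
    "error": "power",
    "gamma": "1.0",
    "alpha": "0.05",
    "nca_pool": "mean",
    "bootstrap_n": "250",
    "vpc_n": "250",
    "outdir": "sparsepk_report",
}


@dataclass(frozen=True)
class RunConfig:
    """Flat key=value run configuration.

    Either ``study_csv`` (a long-format study file) or ``simulate_analyte``
    (CAB/MPA, simulated at the built-in truth) must be set.  Every stochastic
    stage (simulation, multi-start jitter, bootstrap, VPC) derives from
    ``seed``.
    """

    values: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(_DEFAULTS)
        for k, v in self.values.items():
            if k not in _DEFAULTS:
                raise ValueError(f"unknown config key {k!r}")
            merged[k] = str(v)
        object.__setattr__(self, "values", merged)

    def __getitem__(self, key: str) -> str:
        return self.values[key]

    @property
    def hash(self) -> str:
        # outdir is where results land, not part of what was computed
        text = "\n".join(
            f"{k}={self.values[k]}" for k in sorted(self.values) if k != "outdir"
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Parse a key=value config file ('#' starts a comment)."""
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {line!r}")
        k, v = line.split("=", 1)
        values[k.strip()] = v.strip()
    return RunConfig(values)


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def _nca_row(res) -> dict:
    return {
        "analyte": res.analyte,
        "route": res.route,
        "dose_ug": res.dose_ug,
        "t_half_h": res.t_half,
        "c0_ng_ml": res.c0,
        "cmax_ng_ml": res.cmax,
        "tmax_h": res.tmax,
        "auc_partial_ng_h_ml": res.auc_partial,
        "auc_inf_ng_h_ml": res.auc_inf,
        "auc_inf_per_dose_ng_h_ml_per_ng": res.auc_inf_per_dose,
        "pct_extrapolated": res.pct_extrapolated,
        "lambda_z_per_h": res.lambda_z,
        "n_lambda_points": res.n_lambda_points,
        "adj_r2": res.adj_r2,
    }


def run_pipeline(config: RunConfig, arms: list[StudyArm] | None = None) -> dict:
    """Run preprocess -> NCA -> fit/select -> validate -> UIR and write a report.

    Returns a dict of in-memory results keyed by stage.  ``arms`` may be
    supplied directly (bypassing file/simulation input) for programmatic use.
    """
    seed = int(config["seed"])
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash

    log_lines: list[str] = [
        f"sparsepk {__version__} run, config hash {cfg_hash}",
        *(f"config: {k}={config.values[k]}" for k in sorted(config.values)),
    ]

    if arms is None:
        if config["study_csv"]:
            arms = read_study_csv(config["study_csv"])
            log_lines.append(f"stage input: read {config['study_csv']}")
        elif config["simulate_analyte"]:
            truth = default_truth(
                config["simulate_analyte"], config["simulate_route"], seed=seed
            )
            arms = [simulate_study(truth)]
            log_lines.append(
                f"stage input: simulated {truth.analyte} {truth.route} "
                f"(seed {seed})"
            )
        else:
            raise ValueError("config needs study_csv or simulate_analyte")
    if config["analyte"]:
        arms = [a for a in arms if a.analyte == config["analyte"]]
    if not arms:
        raise ValueError("no arms selected")

    results: dict = {"config_hash": cfg_hash}

    # --- preprocess + NCA on every arm ---------------------------------
    processed: dict[tuple[str, str], StudyArm] = {}
    nca_rows = []
    nca_results: dict[tuple[str, str], object] = {}
    for arm in arms:
        key = (arm.analyte, arm.route)
        try:
            parm, report = preprocess_arm(arm, alpha=float(config["alpha"]))
        except ValueError as exc:
            raise RuntimeError(f"stage preprocess failed for {key}: {exc}") from exc
        processed[key] = parm
        log_lines.append(
            f"stage preprocess {key}: n={report.n_total}, "
            f"imputed={report.n_imputed} ({report.pct_imputed:.1f}%), "
            f"dropped_blq={report.n_dropped_blq}, "
            f"excluded_outliers={report.n_excluded_outliers}"
        )
        try:
            res = nca_summary(parm, NCAOptions(pool=config["nca_pool"]))
        except ValueError as exc:
            raise RuntimeError(f"stage nca failed for {key}: {exc}") from exc
        nca_results[key] = res
        nca_rows.append(_nca_row(res))
        log_lines.append(
            f"stage nca {key}: t_half={res.t_half:.3g} h, "
            f"auc_inf={res.auc_inf:.6g}, extrapolated={res.pct_extrapolated:.2g}%"
        )

    nca_df = pd.DataFrame(nca_rows)
    for analyte in {a for a, _ in nca_results}:
        iv, sq = nca_results.get((analyte, "IV")), nca_results.get((analyte, "SQ"))
        if iv and sq:
            f_pct = bioavailability(sq, iv)
            nca_df.loc[
                (nca_df.analyte == analyte) & (nca_df.route == "SQ"), "pct_F"
            ] = f_pct
            log_lines.append(f"stage nca {analyte}: %F = {f_pct:.3g}")
    _write_csv(nca_df, outdir / "nca_table.csv", cfg_hash)
    results["nca"] = nca_results

    # --- macroconstant fit on the IV arm -------------------------------
    iv_keys = [k for k in processed if k[1] == "IV"]
    if iv_keys:
        key = iv_keys[0]
        parm = processed[key]
        candidates = (1, 2, 3) if config["terms"] == "auto" else (int(config["terms"]),)
        try:
            ranked = select_model(
                parm,
                n_terms_candidates=candidates,
                error_model=config["error"],
                gamma=float(config["gamma"]),
                seed=seed,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"stage fit failed for {key}: {exc}") from exc
        fit, flags = ranked[0]
        for f2, fl in ranked:
            log_lines.append(
                f"stage fit {key}: {f2.model.n_terms}-term AIC={f2.aic:.2f} "
                f"{'flags=' + ';'.join(fl) if fl else ''}"
            )
        results["fit"] = fit
        results["ranking"] = ranked

        boot = bootstrap_fit(
            parm, fit, n_resamples=int(config["bootstrap_n"]), seed=seed + 1
        )
        results["bootstrap"] = boot
        log_lines.append(
            f"stage bootstrap {key}: {boot.n_resamples} resamples, "
            f"{boot.n_failed_fits} failed"
        )

        rows = []
        cv = fit.cv_pct or {}
        for name, est in _named_params(fit).items():
            rows.append(
                {
                    "parameter": name,
                    "estimate": est,
                    "cv_pct": cv.get(name),
                    "bootstrap_mean": boot.means.get(name),
                    "ci95_lower": boot.ci_lower.get(name),
                    "ci95_upper": boot.ci_upper.get(name),
                }
            )
        _write_csv(pd.DataFrame(rows), outdir / "parameters_table.csv", cfg_hash)

        schedule = _design_of(parm)
        vres = vpc(
            fit,
            schedule,
            lloq_ng_ml=parm.lloq_ng_ml,
            n_sim=int(config["vpc_n"]),
            seed=seed + 2,
        )
        _write_csv(vres.to_frame(), outdir / "vpc_bands.csv", cfg_hash)
        results["vpc"] = vres

        fitted_samples = [
            s for s in parm.eligible_samples() if s.status == "observed"
        ]
        gof = gof_tables(
            fit,
            [s.time_h for s in fitted_samples],
            [s.conc_ng_ml for s in fitted_samples],
        )
        _write_csv(gof, outdir / "gof_table.csv", cfg_hash)
        results["gof"] = gof

        uir = uir_from_fit(fit.model, parm.dose_ug)
        uir_doc = {
            "config_hash": cfg_hash,
            "analyte": parm.analyte,
            "dose_ug": parm.dose_ug,
            "terms_ng_ml_per_ng": [[c, r] for c, r in uir.terms],
        }
        (outdir / "uir.json").write_text(json.dumps(uir_doc, indent=2) + "\n")
        results["uir"] = uir
        log_lines.append(
            "stage uir: "
            + " + ".join(f"{c:.3g}*exp(-{r:.3g}t)" for c, r in uir.terms)
        )

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    results["log"] = log_lines
    return results


def _named_params(fit) -> dict[str, float]:
    names_c = ["A", "B", "C"]
    names_r = ["alpha", "beta", "gamma3"]
    out = {}
    for i, (c, r) in enumerate(fit.model.terms):
        out[names_c[i]] = c
        out[names_r[i]] = r
    if fit.model.error_model is not None:
        out["sigma"] = fit.model.error_model.sigma
    return out


def _design_of(arm: StudyArm) -> list[tuple[float, int]]:
    elig = arm.eligible_samples()
    times = sorted({s.time_h for s in elig})
    return [(t, sum(1 for s in elig if s.time_h == t)) for t in times]
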