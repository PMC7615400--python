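"""End-to-end trial analysis: scoring, primary and secondary endpoints.

``analyze_trial`` takes a :class:`~anginatrial.simulate.TrialDataset`
(simulated or read from disk) through the full analysis:

* the daily composite score is summarized per patient and analyzed by
  ordinal analysis of covariance adjusted for the pre-randomization
  score, reporting the treatment odds ratio (above 1 = worse scores
  under placebo), 95% CI, Wald p-value and model-derived follow-up
  scores per arm for the median-baseline patient;
* the score's components (daily episodes, daily medication units) are
  analyzed the same way;
* secondary endpoints use OLS ANCOVA, logistic regression for freedom
  from angina, and the ordinal model for CCS class;
* the blinding index is computed per arm, respondent and timepoint.

The report is a plain dict of floats/strings, deterministic for a
given dataset, so repeated runs serialize byte-identically.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import blinding as blinding_mod
from . import ordinal, scoring, secondary
from .simulate import TrialDataset


def _component_summary(diary: pd.DataFrame, column: str, window: int,
                       phase: str) -> pd.Series:
    """Per-patient mean of a diary column over one phase's final window."""
    sub = diary[diary["day"] < 0] if phase == "pre" else diary[diary["day"] >= 1]

    def last_window_mean(g: pd.DataFrame) -> float:
        vals = g.sort_values("day")[column].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            return np.nan
        return float(vals[-window:].mean()) if phase == "follow" else float(vals.mean())

    return sub.groupby("patient_id").apply(last_window_mean, include_groups=False)


def _ordinal_endpoint(outcome, placebo, baseline, name, n_knots,
                      max_numeric_levels) -> dict:
    fit = ordinal.fit_cumulative_link(
        outcome, placebo, baseline, n_knots=n_knots,
        max_numeric_levels=max_numeric_levels,
    )
    if not fit.converged:
        return {"name": name, "error": f"model did not converge: {fit.message}"}
    or_, lo, hi = ordinal.odds_ratio(fit)
    pred = ordinal.typical_patient_prediction(fit, float(np.median(baseline)))
    return {
        "name": name,
        "scale": "odds_ratio",
        "effect": or_,
        "lower95": lo,
        "upper95": hi,
        "p_value": ordinal.wald_p_value(fit),
        "arm_values": {"PCI": pred[0.0], "placebo": pred[1.0]},
        "n": fit.n,
    }


def analyze_trial(
    dataset: TrialDataset,
    score_config: scoring.ScoreConfig | None = None,
    n_knots: int = 4,
    max_numeric_levels: int | None = None,
    mi_imputations: int = 20,
    mi_seed: int = 0,
) -> dict:
    """Run the full analysis and return a report dict."""
    score_config = score_config or scoring.ScoreConfig()
    scores = scoring.score_trial(dataset.diary, score_config)
    merged = scores.merge(dataset.patients, on="patient_id")
    placebo = (merged["arm"] == "placebo").astype(float).to_numpy()

    report: dict = {"n_patients": int(len(merged)), "endpoints": []}

    report["endpoints"].append(
        _ordinal_endpoint(
            list(merged["followup_score"]),
            placebo,
            merged["pre_score"].to_numpy(dtype=float),
            "angina_symptom_score",
            n_knots,
            max_numeric_levels,
        )
    )

    window = score_config.summary_window_days
    for column, name in (("episodes", "daily_angina_episodes"),
                         ("med_units", "daily_antianginal_units")):
        fu = _component_summary(dataset.diary, column, window, "follow")
        pre = _component_summary(dataset.diary, column, window, "pre")
        comp = pd.DataFrame({"fu": fu, "pre": pre}).join(
            dataset.patients.set_index("patient_id")["arm"]
        ).dropna()
        if comp["fu"].nunique() < 2:
            report["endpoints"].append(
                {"name": name, "error": "outcome has a single level"}
            )
            continue
        report["endpoints"].append(
            _ordinal_endpoint(
                list(comp["fu"]),
                (comp["arm"] == "placebo").astype(float).to_numpy(),
                comp["pre"].to_numpy(dtype=float),
                name,
                n_knots,
                max_numeric_levels,
            )
        )

    ep = dataset.endpoints
    pci = (ep["arm"] == "PCI").astype(float).to_numpy()
    for base_col, fu_col, name, typical in (
        ("baseline_treadmill_seconds", "followup_treadmill_seconds",
         "treadmill_exercise_time", "mean"),
        ("baseline_saq_angina_frequency", "followup_saq_angina_frequency",
         "saq_angina_frequency", "median"),
        ("baseline_eq5d_index", "followup_eq5d_index", "eq5d_index", "median"),
        ("baseline_stress_echo_score", "followup_stress_echo_score",
         "stress_echo_score", "mean"),
    ):
        try:
            res = secondary.fit_ols_ancova(
                ep[fu_col], pci, ep[base_col], name=name, typical=typical
            )
            report["endpoints"].append(_endpoint_dict(res))
        except ValueError as exc:
            report["endpoints"].append({"name": name, "error": str(exc)})

    free = (ep["followup_saq_angina_frequency"] >= 100).astype(float)
    try:
        res = secondary.fit_logistic_freedom(
            free, pci, ep["baseline_saq_angina_frequency"]
        )
        report["endpoints"].append(_endpoint_dict(res))
    except ValueError as exc:
        report["endpoints"].append({"name": "freedom_from_angina", "error": str(exc)})

    try:
        res = secondary.fit_ordinal_ccs(
            ep["followup_ccs_class"], 1 - pci, ep["baseline_ccs_class"]
        )
        report["endpoints"].append(_endpoint_dict(res))
    except ValueError as exc:
        report["endpoints"].append({"name": "ccs_class", "error": str(exc)})

    # sensitivity analysis for the endpoints interrupted by missed visits
    for base_col, fu_col, name in (
        ("baseline_treadmill_seconds", "followup_treadmill_seconds",
         "treadmill_exercise_time_mi"),
        ("baseline_stress_echo_score", "followup_stress_echo_score",
         "stress_echo_score_mi"),
    ):
        try:
            res = secondary.multiple_imputation_sensitivity(
                ep[fu_col], pci, ep[base_col], m=mi_imputations,
                seed=mi_seed, name=name,
            )
            report["endpoints"].append(_endpoint_dict(res))
        except ValueError as exc:
            report["endpoints"].append({"name": name, "error": str(exc)})

    report["blinding"] = []
    for _, row in dataset.blinding.iterrows():
        table = blinding_mod.BlindingTable(
            int(row["correct_sure"]),
            int(row["correct_unsure"]),
            int(row["dont_know"]),
            int(row["incorrect_unsure"]),
            int(row["incorrect_sure"]),
        )
        bi, lo, hi = blinding_mod.blinding_index(table)
        report["blinding"].append(
            {
                "respondent": row["respondent"],
                "timepoint": row["timepoint"],
                "arm": row["arm"],
                "index": bi,
                "lower95": lo,
                "upper95": hi,
                "n": table.n,
            }
        )
    return report


def _endpoint_dict(res: secondary.EndpointResult) -> dict:
    arm_values = {
        ("PCI" if lvl == 1.0 else "placebo"): v for lvl, v in res.arm_values.items()
    }
    if res.name in ("ccs_class",):  # indicator marks placebo for ordinal CCS
        arm_values = {
            ("placebo" if lvl == 1.0 else "PCI"): v for lvl, v in res.arm_values.items()
        }
    return {
        "name": res.name,
        "scale": res.scale,
        "effect": res.effect,
        "lower95": res.lower95,
        "upper95": res.upper95,
        "p_value": res.p_value,
        "arm_values": arm_values,
        "n": sum(res.n_per_arm.values()),
    }


def report_to_text(report: dict) -> str:
    """Human-readable endpoint table in the trial's reporting shape."""
    lines = [
        f"Patients analyzed: {report['n_patients']}",
        "",
        f"{'Endpoint':32s} {'PCI':>9s} {'Placebo':>9s} "
        f"{'Effect (95% CI)':>24s} {'P':>8s}",
    ]
    for e in report["endpoints"]:
        if "error" in e:
            lines.append(f"{e['name']:32s}  -- {e['error']}")
            continue
        av = e["arm_values"]
        p = f"{e['p_value']:.4f}" if e.get("p_value") is not None else "-"
        lines.append(
            f"{e['name']:32s} {av['PCI']:9.2f} {av['placebo']:9.2f} "
            f"{e['effect']:8.2f} ({e['lower95']:.2f} to {e['upper95']:.2f}) {p:>8s}"
        )
    lines.append("")
    lines.append("Blinding index (0 = effective blinding):")
    for b in report.get("blinding", []):
        lines.append(
            f"  {b['respondent']:8s} {b['timepoint']:14s} {b['arm']:8s} "
            f"{b['index']:+.2f} ({b['lower95']:+.2f} to {b['upper95']:+.2f})"
        )
    return "\n".join(lines) + "\n"


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
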