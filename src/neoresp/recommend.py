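"""Three-category personalized regimen recommendation.

Within each molecular subtype's guideline ladder (HER2+: r3 < r4;
triple-negative: r1 < r2; ER/PR+&HER2-: r5 < r1 < r2), Q1 is the
counterfactual score of the lowest-toxicity rung and Q2 the best score
among the higher-toxicity rungs.  The rule (trial condition checked first,
ties favoring lower toxicity):

    trial   if Q1 < t and Q2 < t
    lower   else if Q1 >= Q2
    higher  otherwise

Scores are corrected pCR probabilities (short-term mode, Youden threshold
from the training split) or negated corrected risk scores (long-term mode,
25%-quantile threshold), so "higher is better" in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import REGIMEN_LADDERS, REGIMENS
from .metrics import hazard_ratio, km_estimate, logrank, risk_cutoff, youden_threshold

__all__ = [
    "RegimenGroup",
    "TrainingScores",
    "RecommendationResult",
    "counterfactual_scores",
    "recommend",
    "recommend_cohort",
    "threshold_for_mode",
    "evaluate_recommendations",
    "policy_value",
]

CATEGORIES = ("lower", "higher", "trial")


@dataclass(frozen=True)
class RegimenGroup:
    subtype: str
    ladder: tuple  # ordered lower -> higher toxicity
    trial_option: bool = True

    def __post_init__(self):
        if not 2 <= len(self.ladder) <= 3:
            raise ValueError("ladder must hold 2-3 regimens")
        for r in self.ladder:
            if r not in REGIMENS:
                raise ValueError(f"unknown regimen {r!r}")


GROUPS = {s: RegimenGroup(s, ladder) for s, ladder in REGIMEN_LADDERS.items()}


@dataclass(frozen=True)
class TrainingScores:
    """Scores carrying provenance, so thresholds can only be computed on the
    training split."""

    scores: np.ndarray
    labels: np.ndarray | None = None  # pCR labels (pcr mode only)
    split: str = "train"


@dataclass(frozen=True)
class RecommendationResult:
    q1: float
    q2: float
    threshold: float
    mode: str
    category: str
    recommended: str  # regimen code name


def recommend(q1: float, q2: float, threshold: float) -> str:
    """Three-category rule; the clinical-trial condition has precedence."""
    if not (np.isfinite(q1) and np.isfinite(q2)):
        raise ValueError("Q scores must be finite")
    if q1 < threshold and q2 < threshold:
        return "trial"
    return "lower" if q1 >= q2 else "higher"


def threshold_for_mode(training: TrainingScores, mode: str) -> float:
    """Youden threshold of training pCR scores (mode='pcr') or the 25%
    quantile of training negated risk scores (mode='survival'); rejects
    scores not tagged as the training split."""
    if training.split != "train":
        raise ValueError("thresholds must be computed on the training split")
    if mode == "pcr":
        if training.labels is None:
            raise ValueError("pcr mode needs training labels")
        return youden_threshold(training.scores, training.labels)
    if mode == "survival":
        return risk_cutoff(training.scores, quantile=0.25)
    raise ValueError(f"unknown mode {mode!r}")


def counterfactual_scores(results, records=None, mode: str = "pcr",
                          checkpoint_metric: str | None = None) -> pd.DataFrame:
    """Ensemble score per patient for every regimen on the patient's
    subtype ladder (corrected pCR probability, or negated corrected risk)."""
    if mode not in ("pcr", "survival"):
        raise ValueError(f"unknown mode {mode!r}")
    metric = checkpoint_metric or ("pcr_auc" if mode == "pcr" else "cindex")
    recs = results.model.records if records is None else records
    for r in recs:
        if r.subtype not in GROUPS:
            raise ValueError(f"unknown subtype {r.subtype!r}")
    needed = sorted({reg for r in recs for reg in GROUPS[r.subtype].ladder})
    per_regimen = {}
    for reg in needed:
        pred = results.predict(records, regimen=reg, checkpoint_metric=metric)
        per_regimen[reg] = (pred["pcr_correct"].to_numpy() if mode == "pcr"
                            else -pred["risk_correct"].to_numpy())
    rows = []
    for i, r in enumerate(recs):
        row = {"patient_id": r.patient_id, "subtype": r.subtype}
        for reg in GROUPS[r.subtype].ladder:
            row[f"score_{reg}"] = per_regimen[reg][i]
        rows.append(row)
    return pd.DataFrame(rows)


def recommend_cohort(scores: pd.DataFrame, threshold: float, mode: str) -> pd.DataFrame:
    """Apply the three-category rule per patient.

    Q2 (and the recommended higher-toxicity rung) is the max/argmax over
    all higher-toxicity rungs; the trial category maps to the best
    available rung in ``effective_regimen`` for policy evaluation.
    """
    rows = []
    for _, row in scores.iterrows():
        ladder = GROUPS[row["subtype"]].ladder
        q1 = float(row[f"score_{ladder[0]}"])
        higher = {reg: float(row[f"score_{reg}"]) for reg in ladder[1:]}
        best_high = max(higher, key=higher.get)
        q2 = higher[best_high]
        cat = recommend(q1, q2, threshold)
        recommended = {"lower": ladder[0], "higher": best_high, "trial": "trial"}[cat]
        if cat == "lower":
            effective = ladder[0]
        elif cat == "higher":
            effective = best_high
        else:  # no trial arm exists in the counterfactual world
            effective = ladder[0] if q1 >= q2 else best_high
        rows.append({"patient_id": row["patient_id"], "subtype": row["subtype"],
                     "q1": q1, "q2": q2, "threshold": threshold, "mode": mode,
                     "category": cat, "recommended": recommended,
                     "effective_regimen": effective})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ evaluation


def policy_value(recommendations: pd.DataFrame, counterfactuals: pd.DataFrame) -> dict:
    """Mean realized counterfactual pCR under the recommended (effective)
    regimen vs the factual assignment, paired on the shared potential
    outcomes; two-sided paired t-test on the difference."""
    cf = counterfactuals.set_index(["patient_id", "regimen"])
    rec_y, fact_y = [], []
    factual = counterfactuals[counterfactuals["assigned"] == 1].set_index("patient_id")
    for _, row in recommendations.iterrows():
        pid = row["patient_id"]
        rec_y.append(cf.loc[(pid, row["effective_regimen"]), "y_pcr"])
        fact_y.append(factual.loc[pid, "y_pcr"])
    rec_y, fact_y = np.asarray(rec_y, float), np.asarray(fact_y, float)
    diff = rec_y - fact_y
    if np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0):
        p = 1.0
    else:
        p = float(stats.ttest_rel(rec_y, fact_y).pvalue)
    return {"mean_recommended": float(rec_y.mean()), "mean_factual": float(fact_y.mean()),
            "mean_difference": float(diff.mean()), "p_value": p, "n": len(diff)}


def evaluate_recommendations(records, recommendations: pd.DataFrame,
                             counterfactuals: pd.DataFrame | None = None) -> dict:
    """Subgroup report within each factual-regimen stratum: KM curves and
    pairwise hazard ratios across recommendation categories, the factual x
    recommended agreement matrix, and (when the counterfactual table is
    available) the paired policy value."""
    rec_by_id = recommendations.set_index("patient_id")
    report: dict = {"strata": {}, "agreement": {}, "notes": []}
    factual = pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "factual": [r.regimen for r in records],
        "time": [r.survival.time for r in records],
        "event": [r.survival.event for r in records],
    }).set_index("patient_id")
    joined = factual.join(rec_by_id, how="inner")

    agreement = pd.crosstab(joined["factual"], joined["recommended"])
    report["agreement"] = agreement.to_dict()

    for regimen, stratum in joined.groupby("factual"):
        cats = stratum["category"].unique()
        entry: dict = {"n": len(stratum), "categories": {}}
        if len(cats) < 2:
            entry["degenerate"] = True
            report["notes"].append(
                f"stratum {regimen}: single recommendation category, no contrasts")
        for cat, grp in stratum.groupby("category"):
            curve = km_estimate(grp["time"].to_numpy(), grp["event"].to_numpy())
            entry["categories"][cat] = {
                "n": len(grp),
                "km_times": curve.times.tolist(),
                "km_survival": curve.survival.tolist(),
            }
        if len(cats) >= 2:
            chi2, p = logrank(stratum["time"].to_numpy(), stratum["event"].to_numpy(),
                              stratum["category"].to_numpy())
            entry["logrank"] = {"chi2": chi2, "p": p}
            entry["hazard_ratios"] = {}
            for a in cats:
                for b in cats:
                    if a >= b:
                        continue
                    sub = stratum[stratum["category"].isin([a, b])]
                    ind = (sub["category"] == b).astype(int).to_numpy()
                    try:
                        entry["hazard_ratios"][f"{b}_vs_{a}"] = hazard_ratio(
                            ind, sub["time"].to_numpy(), sub["event"].to_numpy())
                    except ValueError as err:
                        report["notes"].append(f"stratum {regimen} {b} vs {a}: {err}")
        report["strata"][regimen] = entry

    if counterfactuals is not None and len(recommendations):
        sub_cf = counterfactuals[counterfactuals["patient_id"].isin(
            recommendations["patient_id"])]
        report["policy_value"] = policy_value(recommendations, sub_cf)
    return report
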