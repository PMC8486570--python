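"""Combine the two classifiers into the final tissue-of-origin call.

Per sample: both models' class probabilities are sex-filtered (germ-cell and
prostate classes zeroed for females, ovarian and endometrial for males, mass
renormalized), the top-2 classes per model are extracted, and a two-rule
prioritization produces the reported site(s):

* Rule A — any class predicted with probability > 0.80 by either model;
* Rule B (when A yields nothing) — classes present in *both* models' top-2
  with probability > 0.30 in at least one model;
* fallback — the union of both models' top-2.

Multiple qualifying sites are all reported, ordered by their best
probability across the two models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .panel import FEMALE_ONLY_CLASSES, MALE_ONLY_CLASSES

RULE_A_THRESHOLD = 0.80
RULE_B_THRESHOLD = 0.30


class PredictionError(ValueError):
    pass


def sex_filter(probs: pd.Series, sex: str) -> tuple[pd.Series, list[str]]:
    """Zero sex-incompatible classes and renormalize.

    Returns ``(filtered_probs, excluded_classes)``. Unknown sex leaves the
    vector untouched. Raises if the filter would remove all probability mass.
    """
    if sex == "female":
        drop = sorted(MALE_ONLY_CLASSES & set(probs.index))
    elif sex == "male":
        drop = sorted(FEMALE_ONLY_CLASSES & set(probs.index))
    elif sex in {"unknown", None} or (isinstance(sex, float) and np.isnan(sex)):
        return probs.copy(), []
    else:
        raise PredictionError(f"invalid sex {sex!r}")
    out = probs.copy()
    out[drop] = 0.0
    mass = out.sum()
    if mass <= 0:
        raise PredictionError("sex filter removed all probability mass")
    return out / mass, drop


def top_two(probs: pd.Series) -> tuple[str, str]:
    """The two highest-probability classes, descending; ties alphabetical."""
    if len(probs) < 2:
        raise PredictionError("need at least two classes")
    ordered = probs.sort_index().sort_values(ascending=False, kind="stable")
    return (str(ordered.index[0]), str(ordered.index[1]))


@dataclass
class PredictionReport:
    """Per-sample prediction outcome from the combined classifiers."""

    sample_id: str
    probs_nsc: pd.Series
    probs_lasso: pd.Series
    top2_nsc: tuple[str, str]
    top2_lasso: tuple[str, str]
    sex_excluded: list[str]
    final_sites: list[str] = field(default_factory=list)
    rule_fired: str = ""


def prioritize(report: PredictionReport) -> PredictionReport:
    """Apply the two-criterion rule; fills final_sites and rule_fired.

    Pure function of the (already sex-filtered) probability vectors: fills
    and returns the same report object.
    """
    p_nsc, p_lasso = report.probs_nsc, report.probs_lasso
    best = pd.concat([p_nsc, p_lasso], axis=1).max(axis=1)

    def ordered(sites) -> list[str]:
        return sorted(sites, key=lambda s: (-best[s], s))

    rule_a = [c for c in best.index if p_nsc[c] > RULE_A_THRESHOLD
              or p_lasso[c] > RULE_A_THRESHOLD]
    if rule_a:
        report.final_sites, report.rule_fired = ordered(rule_a), "A"
        return report
    shared = set(report.top2_nsc) & set(report.top2_lasso)
    rule_b = [c for c in shared if best[c] > RULE_B_THRESHOLD]
    if rule_b:
        report.final_sites, report.rule_fired = ordered(rule_b), "B"
        return report
    union = set(report.top2_nsc) | set(report.top2_lasso)
    report.final_sites, report.rule_fired = ordered(union), "fallback"
    return report


def predict_sample(
    nsc_results, lasso_results, x, sample_id: str, sex: str = "unknown"
) -> PredictionReport:
    """Full per-sample pipeline: probabilities -> sex filter -> top-2 -> rule."""
    p_nsc = nsc_results.predict_proba(x)
    p_lasso = lasso_results.predict_proba(x)
    if isinstance(p_nsc, pd.DataFrame):
        p_nsc = p_nsc.iloc[0]
    if isinstance(p_lasso, pd.DataFrame):
        p_lasso = p_lasso.iloc[0]
    p_nsc, excl = sex_filter(p_nsc, sex)
    p_lasso, _ = sex_filter(p_lasso, sex)
    report = PredictionReport(
        sample_id=sample_id,
        probs_nsc=p_nsc,
        probs_lasso=p_lasso,
        top2_nsc=top_two(p_nsc),
        top2_lasso=top_two(p_lasso),
        sex_excluded=excl,
    )
    return prioritize(report)


def predict_cohort(
    nsc_results, lasso_results, matrix: ExpressionMatrix, meta: pd.DataFrame
) -> list[PredictionReport]:
    sex_by_id = dict(zip(meta["sample_id"], meta["sex"]))
    reports = []
    for sid in matrix.sample_ids:
        x = matrix.data.loc[sid]
        reports.append(
            predict_sample(
                nsc_results, lasso_results, x, sid,
                sex=sex_by_id.get(sid, "unknown"),
            )
        )
    return reports


def reports_to_frame(reports: list[PredictionReport]) -> pd.DataFrame:
    """One row per sample: top-2 per model, final sites, rule fired."""
    rows = []
    for r in reports:
        rows.append(
            {
                "sample_id": r.sample_id,
                "nsc_top1": r.top2_nsc[0],
                "nsc_top1_prob": r.probs_nsc[r.top2_nsc[0]],
                "nsc_top2": r.top2_nsc[1],
                "nsc_top2_prob": r.probs_nsc[r.top2_nsc[1]],
                "lasso_top1": r.top2_lasso[0],
                "lasso_top1_prob": r.probs_lasso[r.top2_lasso[0]],
                "lasso_top2": r.top2_lasso[1],
                "lasso_top2_prob": r.probs_lasso[r.top2_lasso[1]],
                "sex_excluded": ";".join(r.sex_excluded),
                "final_sites": ";".join(r.final_sites),
                "rule_fired": r.rule_fired,
            }
        )
    return pd.DataFrame(rows)


def reports_to_long(reports: list[PredictionReport]) -> pd.DataFrame:
    """Long-format table (sample x model x rank) for plotting prediction grids."""
    rows = []
    for r in reports:
        for model, top2, probs in (
            ("nsc", r.top2_nsc, r.probs_nsc),
            ("lasso", r.top2_lasso, r.probs_lasso),
        ):
            for rank, site in enumerate(top2, start=1):
                rows.append(
                    {
                        "sample_id": r.sample_id,
                        "model": model,
                        "rank": rank,
                        "site": site,
                        "probability": probs[site],
                    }
                )
    return pd.DataFrame(rows)


def model_agreement(reports: list[PredictionReport]) -> float:
    """Fraction of samples whose two models share a prioritized site.

    Agreement means a non-empty overlap between the sites each model would
    report on its own under the same prioritization rules.
    """
    if not reports:
        raise PredictionError("no reports")
    agree = 0
    for r in reports:
        sites_by_model = []
        for probs, top2 in ((r.probs_nsc, r.top2_nsc), (r.probs_lasso, r.top2_lasso)):
            a = {c for c in probs.index if probs[c] > RULE_A_THRESHOLD}
            if a:
                sites_by_model.append(a)
            else:
                b = {c for c in top2 if probs[c] > RULE_B_THRESHOLD}
                sites_by_model.append(b if b else set(top2))
        if sites_by_model[0] & sites_by_model[1]:
            agree += 1
    return agree / len(reports)
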