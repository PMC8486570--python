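"""Per-miRNA prognostic analysis on the CUP cohort.

For each miRNA: expression is dichotomized at a cutoff (by default the ROC
threshold maximizing sensitivity + specificity for vital status — a
Youden-type cutoff), the two groups are compared with Kaplan-Meier curves
and the log-rank test, and the hazard ratio of the high- vs low-expression
group is estimated by univariate Cox proportional-hazards regression
(Breslow tie handling) with a 95% Wald confidence interval. Raw p <= 0.05
flags significance; a Benjamini-Hochberg column is emitted alongside for
transparency but plays no role in flagging.

Kaplan-Meier, log-rank and Cox fits go through lifelines; the cutoff search
and the screening workflow are this module's own.

A caveat worth knowing: the Youden cutoff is chosen using the outcome
(vital status), so p-values at ROC-derived cutoffs are optimistic.
``cutoff_method="median"`` gives the selection-free alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalFit:
    """Dichotomized prognostic fit for one miRNA."""

    mirna_id: str
    cutoff: float
    hr: float
    ci_low: float
    ci_high: float
    logrank_p: float
    n_high: int
    n_low: int
    monotone: bool = False  # no events in one group: CI effectively unbounded

    def summary(self) -> str:
        return (
            f"{self.mirna_id}: HR {self.hr:.3g} "
            f"(95% CI {self.ci_low:.3g}-{self.ci_high:.3g}), "
            f"log-rank p = {self.logrank_p:.3g} "
            f"[high n={self.n_high}, low n={self.n_low}, cutoff {self.cutoff:.4g}]"
        )


def optimal_cutoff(expression, status) -> float:
    """Youden-type cutoff: maximize sensitivity + specificity for status=1.

    Candidates are midpoints between consecutive sorted unique expression
    values; the positive group is expression > cutoff. Ties on the
    objective go to the lowest threshold. Raises on constant expression or
    a one-sided status vector.
    """
    x = np.asarray(expression, dtype=float)
    s = np.asarray(status, dtype=int)
    if set(np.unique(s)) - {0, 1}:
        raise SurvivalError("status must be binary 0/1")
    if s.sum() == 0 or s.sum() == len(s):
        raise SurvivalError("both status groups must be non-empty")
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise SurvivalError("constant expression has no informative cutoff")
    mids = (uniq[:-1] + uniq[1:]) / 2
    n_pos = s.sum()
    n_neg = len(s) - n_pos
    best_c, best_j = None, -np.inf
    for c in mids:  # low to high: ties keep the lowest threshold
        high = x > c
        sens = (s[high] == 1).sum() / n_pos
        spec = (s[~high] == 0).sum() / n_neg
        j = sens + spec
        # the marker may be protective: orient so the better direction counts
        j = max(j, 2.0 - j)
        if j > best_j + 1e-12:
            best_c, best_j = c, j
    return float(best_c)


@dataclass
class KMResult:
    curves: dict  # group label -> fitted KaplanMeierFitter
    statistic: float
    p_value: float


def km_logrank(time, event, group) -> KMResult:
    """Kaplan-Meier curves per group + two-sample log-rank test.

    The statistic is chi-squared with 1 df. A group with zero events warns
    but the statistic stays defined.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if (time < 0).any():
        raise SurvivalError("negative survival times")
    labels = np.unique(group)
    if len(labels) != 2:
        raise SurvivalError(f"need exactly two groups, got {len(labels)}")
    curves = {}
    for g in labels:
        mask = group == g
        if event[mask].sum() == 0:
            warnings.warn(f"group {g!r} has zero events")
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(time[mask], event[mask])
        curves[g] = kmf
    a, b = labels
    res = logrank_test(time[group == a], time[group == b],
                       event[group == a], event[group == b])
    return KMResult(curves=curves, statistic=float(res.test_statistic),
                    p_value=float(res.p_value))


def cox_univariate(time, event, group) -> tuple[float, tuple[float, float], bool]:
    """Univariate Cox PH fit on a binary group covariate.

    Returns ``(hr, (ci_low, ci_high), monotone)`` where hr = exp(beta) for
    group 1 vs 0, the CI is the 95% Wald interval, and ``monotone`` flags a
    degenerate likelihood (no events in one group), for which the interval
    is effectively unbounded. Breslow tie handling.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    if set(np.unique(group)) - {0, 1}:
        raise SurvivalError("group must be binary 0/1")
    monotone = (event[group == 1].sum() == 0) or (event[group == 0].sum() == 0)
    df = pd.DataFrame({"time": time, "event": event, "group": group})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-9, "max_steps": 500})
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    return hr, ci, monotone


def fit_mirna(
    expression, time, event, mirna_id: str = "", cutoff_method: str = "roc"
) -> SurvivalFit:
    """Cutoff -> dichotomize -> log-rank + Cox HR for one miRNA."""
    x = np.asarray(expression, dtype=float)
    event = np.asarray(event, dtype=int)
    if cutoff_method == "roc":
        cutoff = optimal_cutoff(x, event)
    elif cutoff_method == "median":
        cutoff = float(np.median(x))
    else:
        raise SurvivalError(f"unknown cutoff_method {cutoff_method!r}")
    high = (x > cutoff).astype(int)
    if high.sum() in (0, len(high)):
        raise SurvivalError(f"{mirna_id}: cutoff puts all samples in one group")
    km = km_logrank(time, event, high)
    hr, (lo, hi), monotone = cox_univariate(time, event, high)
    return SurvivalFit(
        mirna_id=mirna_id,
        cutoff=cutoff,
        hr=hr,
        ci_low=lo,
        ci_high=hi,
        logrank_p=km.p_value,
        n_high=int(high.sum()),
        n_low=int(len(high) - high.sum()),
        monotone=monotone,
    )


def screen_panel(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    cutoff_method: str = "roc",
    min_samples: int = 10,
) -> pd.DataFrame:
    """Prognostic screen of every panel miRNA on samples with survival data.

    Emits one row per miRNA: cutoff, group sizes, HR with 95% CI, log-rank
    p, ``significant`` (raw p <= alpha) and a BH-adjusted q column.
    Per-miRNA failures (constant expression, one-sided groups) are recorded
    in an ``error`` column, not fatal.
    """
    has_surv = meta["time_months"].notna() & meta["event"].notna()
    sub_meta = meta.loc[has_surv]
    if len(sub_meta) < min_samples:
        raise SurvivalError(
            f"need >= {min_samples} samples with survival data, "
            f"have {len(sub_meta)}"
        )
    sub = matrix.data.loc[sub_meta["sample_id"]]
    time = sub_meta["time_months"].to_numpy(dtype=float)
    event = sub_meta["event"].to_numpy(dtype=int)
    rows = []
    for mirna in sub.columns:
        try:
            fit = fit_mirna(sub[mirna], time, event, mirna_id=mirna,
                            cutoff_method=cutoff_method)
            rows.append(
                {
                    "mirna_id": mirna, "cutoff": fit.cutoff, "hr": fit.hr,
                    "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                    "logrank_p": fit.logrank_p, "n_high": fit.n_high,
                    "n_low": fit.n_low, "monotone": fit.monotone, "error": "",
                }
            )
        except Exception as exc:  # record per-miRNA failure, don't abort
            rows.append(
                {
                    "mirna_id": mirna, "cutoff": np.nan, "hr": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan, "logrank_p": np.nan,
                    "n_high": 0, "n_low": 0, "monotone": False,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    ok = table["logrank_p"].notna()
    table["significant"] = ok & (table["logrank_p"] <= alpha)
    table["bh_q"] = np.nan
    if ok.any():
        table.loc[ok, "bh_q"] = multipletests(
            table.loc[ok, "logrank_p"], method="fdr_bh"
        )[1]
    return table


def plot_km(fit_or_km, time=None, event=None, group=None, ax=None):
    """Plot the two KM curves of a dichotomized fit (matplotlib axes)."""
    import matplotlib.pyplot as plt

    if isinstance(fit_or_km, KMResult):
        km = fit_or_km
    else:
        km = km_logrank(time, event, group)
    if ax is None:
        _, ax = plt.subplots()
    for kmf in km.curves.values():
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("months from diagnosis")
    ax.set_ylabel("overall survival probability")
    ax.set_title(f"log-rank p = {km.p_value:.3g}")
    return ax
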