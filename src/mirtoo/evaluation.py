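"""Performance assessment: bootstrap error, confusion, top-2, concordance.

Bootstrap error is out-of-bag: each replicate resamples the training set
with replacement (stratified within class so no class disappears), fits the
model on the resample and scores first-choice misclassification on the
samples left out of the resample. Both classifiers can be evaluated on
identical resamples (pass the same seed) so the comparison is paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .classifiers import MultinomialLasso, NearestShrunkenCentroids


class EvaluationError(ValueError):
    pass


def nsc_spec(delta: float = 0.0, priors=None) -> Callable:
    """Model spec for bootstrap_error: fit NSC with fixed settings."""
    return lambda X, y: NearestShrunkenCentroids(X, y, delta=delta, priors=priors).fit()


def lasso_spec(lam: float = 0.019, **fit_kwargs) -> Callable:
    return lambda X, y: MultinomialLasso(X, y, lam=lam).fit(**fit_kwargs)


@dataclass
class BootstrapResult:
    n_boot: int
    seed: int
    per_class_error: pd.Series
    overall_error: float
    per_class_n_oob: pd.Series = field(default=None)


def _stratified_resample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def bootstrap_error(
    X,
    y,
    model_spec: Callable,
    n_boot: int = 100,
    seed: int = 0,
    stratified: bool = True,
    apparent: bool = False,
) -> BootstrapResult:
    """Out-of-bag bootstrap misclassification, per class and overall.

    ``model_spec(X, y)`` must return a fitted object with ``predict``.
    ``apparent=True`` scores the resample itself (resubstitution) instead of
    the out-of-bag samples. Per-class errors pool misclassifications over
    replicates; the overall error is the pooled (sample-weighted) rate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(y))
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise EvaluationError("every class needs >= 2 samples")
    rng = np.random.default_rng(seed)
    wrong = pd.Series(0.0, index=classes)
    total = pd.Series(0.0, index=classes)
    n = len(y)
    for _ in range(n_boot):
        if stratified:
            boot = _stratified_resample(y, rng)
        else:
            boot = rng.integers(0, n, size=n)
        test = boot if apparent else np.setdiff1d(np.arange(n), boot)
        if test.size == 0:
            continue
        fitted = model_spec(X[boot], y[boot])
        pred = np.asarray(fitted.predict(X[test]))
        truth = y[test]
        for c in classes:
            mask = truth == c
            total[c] += mask.sum()
            wrong[c] += (pred[mask] != c).sum()
    per_class = wrong / total.replace(0, np.nan)
    overall = float(wrong.sum() / total.sum())
    return BootstrapResult(
        n_boot=n_boot,
        seed=seed,
        per_class_error=per_class,
        overall_error=overall,
        per_class_n_oob=total,
    )


def confusion_matrix(y_true, y_pred) -> tuple[pd.DataFrame, pd.Series, float]:
    """K x K counts (rows = truth), per-class PPR, median PPR.

    The positive prediction rate of class k is the correctly predicted
    fraction of samples truly in k (diagonal over row sum).
    """
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    if len(y_true) != len(y_pred):
        raise EvaluationError("label vectors differ in length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for a, b in zip(y_true, y_pred):
        counts.loc[a, b] += 1
    row_sums = counts.sum(axis=1)
    ppr = counts.to_numpy().diagonal() / row_sums.replace(0, np.nan)
    ppr = pd.Series(ppr, index=classes, name="ppr")
    median_ppr = float(ppr.loc[row_sums > 0].median())
    return counts, ppr, median_ppr


def top2_accuracy(y_true, top2_lists) -> float:
    """Fraction of samples whose true class is in the model's top-2."""
    y_true = list(y_true)
    top2_lists = list(top2_lists)
    if len(y_true) != len(top2_lists):
        raise EvaluationError("length mismatch")
    if not y_true:
        raise EvaluationError("empty input")
    hits = sum(t in set(pair) for t, pair in zip(y_true, top2_lists))
    return hits / len(y_true)


def metastasis_concordance(reports, meta: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-patient agreement of final sites across multiple metastases.

    A patient with >= 2 samples is concordant when the intersection of the
    prioritized final_sites over their samples is non-empty. Returns the
    per-patient flags and the cohort concordance rate.
    """
    patient_by_sample = dict(zip(meta["sample_id"], meta["patient_id"]))
    sites_by_patient: dict[str, list[set]] = {}
    for r in reports:
        pid = patient_by_sample.get(r.sample_id)
        if pid is None:
            raise EvaluationError(f"sample {r.sample_id} missing from metadata")
        sites_by_patient.setdefault(pid, []).append(set(r.final_sites))
    flags = {}
    for pid, site_sets in sites_by_patient.items():
        if len(site_sets) < 2:
            continue
        flags[pid] = len(set.intersection(*site_sets)) > 0
    if not flags:
        raise EvaluationError("no patients with multiple samples")
    flags = pd.Series(flags, name="concordant")
    return flags, float(flags.mean())
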