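"""Evaluation statistics for the screening models.

Implements the evaluation protocol: AUROC (Mann-Whitney
construction, ties counted 1/2), scaled Brier score, non-parametric
percentile bootstrap over patients (2000 resamples by default, point
estimates reported as bootstrap medians), a paired Z statistic with a
bootstrap standard error computed on shared resamples, equal-width
calibration tables, and a sensitivity-targeted operating cutoff derived by
stratified k-fold cross-validation on the training data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

DEFAULT_B = 2000


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("metric requires both outcome classes to be present")


def auroc(scores, labels) -> float:
    """P(score_positive > score_negative) with ties counted 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    ranks = stats.rankdata(scores)  # average ranks handle ties
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def scaled_brier(scores, labels) -> float:
    """1 - BS / BS_ref with BS_ref the constant-prevalence predictor."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_two_classes(labels.astype(int))
    bs = float(np.mean((scores - labels) ** 2))
    p = float(labels.mean())
    return 1.0 - bs / (p * (1.0 - p))


def sensitivity_specificity(scores=None, labels=None, cutoff=None, *,
                            tp=None, fp=None, fn=None, tn=None):
    """Sensitivity, specificity and the confusion matrix at a cutoff.

    Either pass scores/labels/cutoff (positive iff score >= cutoff), or the
    four confusion-matrix counts directly.
    """
    if tp is None:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        pred = scores >= cutoff
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return sens, spec, {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def _resample_indices(rng: np.random.Generator, n: int, labels: np.ndarray,
                      B: int) -> np.ndarray:
    """B bootstrap resamples of patients; single-class resamples redrawn."""
    idx = rng.integers(0, n, size=(B, n))
    for b in range(B):
        tries = 0
        while len(np.unique(labels[idx[b]])) < 2:
            idx[b] = rng.integers(0, n, size=n)
            tries += 1
            if tries > 1000:
                raise RuntimeError("could not draw a two-class bootstrap resample")
        if tries:
            logger.debug("redrew %d degenerate resample(s)", tries)
    return idx


def bootstrap_ci(metric, scores, labels, B: int = DEFAULT_B, seed: int = 0):
    """Percentile bootstrap over patients: (median, lo 2.5%, hi 97.5%)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    idx = _resample_indices(rng, labels.size, labels, B)
    vals = np.array([metric(scores[i], labels[i]) for i in idx])
    return (
        float(np.median(vals)),
        float(np.percentile(vals, 2.5)),
        float(np.percentile(vals, 97.5)),
    )


def paired_bootstrap_z(metric, scores_a, scores_b, labels,
                       B: int = DEFAULT_B, seed: int = 0):
    """Paired model comparison: Z = observed difference / bootstrap SE.

    Both models are evaluated on the *same* patient resamples, as required
    for paired models; the two-sided p comes from the standard normal.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    delta_obs = metric(scores_a, labels) - metric(scores_b, labels)
    rng = np.random.default_rng(seed)
    idx = _resample_indices(rng, labels.size, labels, B)
    deltas = np.array(
        [metric(scores_a[i], labels[i]) - metric(scores_b[i], labels[i]) for i in idx]
    )
    sd = float(np.std(deltas, ddof=1))
    if sd == 0.0:
        if delta_obs == 0.0:
            return 0.0, 1.0
        warnings.warn("zero bootstrap SD with nonzero difference", stacklevel=2)
        return math.copysign(math.inf, delta_obs), 0.0
    z = delta_obs / sd
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def sensitivity_threshold(scores, labels, target_sens: float) -> float:
    """Largest cutoff t with sensitivity(score >= t) >= target."""
    pos = np.sort(np.asarray(scores, dtype=float)[np.asarray(labels) == 1])[::-1]
    if pos.size == 0:
        raise ValueError("no positives to derive a threshold from")
    k = math.ceil(target_sens * pos.size)
    if k <= 0:
        return 0.0
    return float(pos[k - 1])


@dataclass
class CutoffResult:
    cutoff: float
    fold_thresholds: list[float]
    target_sensitivity: float
    k: int


def derive_cutoff(scores_fn, labels, target_sens: float = 0.90, k: int = 3,
                  seed: int = 0) -> CutoffResult:
    """Operating cutoff via stratified k-fold CV on the training data.

    ``scores_fn(train_idx, test_idx) -> scores`` must retrain the model on
    the in-fold portion and score the out-fold portion.  Each fold
    contributes the largest threshold achieving the target sensitivity on
    its held-out part; the final cutoff is their arithmetic mean.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.sum() < k:
        raise ValueError("fewer positives than folds; cannot stratify")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    thresholds = []
    for tr, te in skf.split(np.zeros_like(labels), labels):
        s = np.asarray(scores_fn(tr, te), dtype=float)
        thresholds.append(sensitivity_threshold(s, labels[te], target_sens))
    return CutoffResult(
        cutoff=float(np.mean(thresholds)),
        fold_thresholds=[float(t) for t in thresholds],
        target_sensitivity=target_sens,
        k=k,
    )


def calibration_curve(scores, labels, bins: int = 10) -> pd.DataFrame:
    """Equal-width calibration table on [0, 1]; empty bins kept with n=0."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    edges = np.linspace(0.0, 1.0, bins + 1)
    which = np.clip(np.digitize(scores, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        m = which == b
        rows.append(
            {
                "bin_mid": (edges[b] + edges[b + 1]) / 2.0,
                "mean_predicted": float(scores[m].mean()) if m.any() else np.nan,
                "observed_fraction": float(labels[m].mean()) if m.any() else np.nan,
                "n": int(m.sum()),
            }
        )
    return pd.DataFrame(rows)


def metric_report(scores_by_model: dict[str, np.ndarray], labels,
                  cutoffs: dict[str, float], B: int = DEFAULT_B,
                  seed: int = 0, bins: int = 10) -> dict:
    """Full evaluation block: per-model point estimates with bootstrap CIs,
    confusion matrices at the operating cutoffs, paired comparisons between
    every model pair, and calibration tables."""
    labels = np.asarray(labels, dtype=int)
    report: dict = {"n": int(labels.size), "prevalence": float(labels.mean()),
                    "models": {}, "comparisons": {}}
    for name, s in scores_by_model.items():
        cut = cutoffs[name]
        entry = {"cutoff": float(cut)}
        for mname, fn in (("auroc", auroc), ("scaled_brier", scaled_brier)):
            med, lo, hi = bootstrap_ci(fn, s, labels, B=B, seed=seed)
            entry[mname] = {"point": float(fn(s, labels)), "median": med,
                            "lo": lo, "hi": hi}
        sens, spec, cm = sensitivity_specificity(s, labels, cut)

        def _sens(sc, lb, c=cut):
            return sensitivity_specificity(sc, lb, c)[0]

        def _spec(sc, lb, c=cut):
            return sensitivity_specificity(sc, lb, c)[1]

        for mname, fn in (("sensitivity", _sens), ("specificity", _spec)):
            med, lo, hi = bootstrap_ci(fn, s, labels, B=B, seed=seed)
            entry[mname] = {
                "point": float(fn(s, labels)), "median": med, "lo": lo, "hi": hi,
            }
        entry["confusion"] = cm
        entry["calibration"] = calibration_curve(s, labels, bins).to_dict("list")
        report["models"][name] = entry

    names = list(scores_by_model)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            comp = {}
            for mname, fn in (("auroc", auroc), ("scaled_brier", scaled_brier)):
                z, p = paired_bootstrap_z(
                    fn, scores_by_model[a], scores_by_model[b], labels, B=B, seed=seed
                )
                comp[mname] = {"z": z, "p": p}
            report["comparisons"][f"{a}_vs_{b}"] = comp
    return report
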