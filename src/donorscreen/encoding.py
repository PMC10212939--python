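"""Static-variable encoding, data partitioning, and class weighting.

Partition protocol: 85% of non-donors form the unlabelled embedding
training set (``ae_train``); the remaining non-donors plus every donor are
split 60/20/20 into train/validation/test, stratified by donor subtype
with largest-remainder rounding so realized sizes are within one patient
per stratum of the requested fractions.

Static predictors are deliberately limited to the responsible medical
specialty (smoothed target-mean encoded; missingness is its own category)
and the presence of head imaging (binary pass-through).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import substream

PARTITIONS = ("ae_train", "train", "validation", "test")
MISSING_CATEGORY = "__missing__"


def largest_remainder(n: int, fractions: np.ndarray) -> np.ndarray:
    """Integer allocation of ``n`` items proportional to ``fractions``."""
    fractions = np.asarray(fractions, dtype=float)
    quota = n * fractions
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def make_splits(
    stays: pd.DataFrame,
    seed: int,
    ae_frac: float = 0.85,
    tvt: tuple[float, float, float] = (0.60, 0.20, 0.20),
) -> pd.DataFrame:
    """Assign every stay to ae_train / train / validation / test.

    Donors never enter ``ae_train``.  Deterministic given ``seed``.
    """
    if abs(sum(tvt) - 1.0) > 1e-9:
        raise ValueError("train/validation/test fractions must sum to 1")
    rng = substream(seed, "splits")
    out = {}

    non_donor_ids = stays.loc[stays["label"] == 0, "patient_id"].to_numpy()
    perm = rng.permutation(len(non_donor_ids))
    n_ae = int(round(ae_frac * len(non_donor_ids)))
    for pid in non_donor_ids[perm[:n_ae]]:
        out[pid] = "ae_train"
    rest = stays[~stays["patient_id"].isin(out)].copy()

    tvt_arr = np.asarray(tvt)
    for _, grp in rest.groupby("subtype", sort=True):
        ids = grp["patient_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        counts = largest_remainder(len(ids), tvt_arr)
        pos = 0
        for part, c in zip(("train", "validation", "test"), counts):
            for pid in ids[pos : pos + c]:
                out[pid] = part
            pos += c

    splits = pd.DataFrame(
        {"patient_id": list(out.keys()), "partition": list(out.values())}
    )
    # preserve stays order for readability
    order = {p: i for i, p in enumerate(stays["patient_id"])}
    return (
        splits.sort_values("patient_id", key=lambda s: s.map(order))
        .reset_index(drop=True)
    )


def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Inverse-prevalence weights: non-donor 1, donor n_neg / n_pos."""
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute class weights")
    return {0: 1.0, 1: n_neg / n_pos}


@dataclass
class TargetMeanEncoder:
    """Smoothed target-mean encoding of a categorical variable.

    encoded(c) = (n_c * mean_c + m * global_mean) / (n_c + m); an unseen or
    empty category collapses to the global mean.  Fit only on labelled
    training rows — never on validation/test and never on the unlabelled
    embedding set.
    """

    smoothing: float = 10.0
    global_mean: float = field(default=np.nan, init=False)
    stats: dict = field(default_factory=dict, init=False)  # cat -> (n, mean)

    @staticmethod
    def _clean(categories: pd.Series) -> pd.Series:
        return categories.astype("string").fillna(MISSING_CATEGORY).replace(
            "", MISSING_CATEGORY
        )

    def fit(self, categories: pd.Series, labels: np.ndarray) -> "TargetMeanEncoder":
        cats = self._clean(categories)
        y = pd.Series(np.asarray(labels, dtype=float).ravel(), index=cats.index)
        self.global_mean = float(y.mean())
        g = y.groupby(cats.to_numpy())
        self.stats = {c: (int(n), float(m)) for c, n, m in
                      zip(g.mean().index, g.size(), g.mean())}
        return self

    def transform(self, categories: pd.Series) -> np.ndarray:
        if not np.isfinite(self.global_mean):
            raise ValueError("encoder not fitted")
        m = self.smoothing
        vals = []
        for c in self._clean(categories):
            n_c, mean_c = self.stats.get(c, (0, self.global_mean))
            vals.append((n_c * mean_c + m * self.global_mean) / (n_c + m) if (n_c + m) > 0
                        else mean_c)
        return np.asarray(vals)

    def to_json(self) -> str:
        return json.dumps(
            {
                "smoothing": self.smoothing,
                "global_mean": self.global_mean,
                "stats": self.stats,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "TargetMeanEncoder":
        d = json.loads(s)
        enc = cls(smoothing=d["smoothing"])
        enc.global_mean = d["global_mean"]
        enc.stats = {k: tuple(v) for k, v in d["stats"].items()}
        return enc


def fit_static_encoder(
    train_stays: pd.DataFrame, smoothing: float = 10.0
) -> TargetMeanEncoder:
    return TargetMeanEncoder(smoothing=smoothing).fit(
        train_stays["specialty"], train_stays["label"].to_numpy()
    )


def encode_static(stays: pd.DataFrame, encoder: TargetMeanEncoder) -> np.ndarray:
    """(n, 2) static matrix: encoded specialty, head_imaging."""
    spec = encoder.transform(stays["specialty"])
    img = stays["head_imaging"].to_numpy(dtype=float)
    return np.column_stack([spec, img])
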