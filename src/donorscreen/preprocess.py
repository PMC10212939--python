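"""Temporal structuring and imputation of the laboratory time series.

The last 72 h of each stay (ending at an *anchor*, by default ICU discharge
or death) are divided into 9 blocks of 8 h, keeping only the last value in
each block.  Blocks are half-open, right-closed: block ``k`` covers
``(anchor - 72 + 8(k-1), anchor - 72 + 8k]`` hours, so an event exactly at
the anchor lands in block 9 and an event exactly 72 h old is discarded.

Missing cells are then imputed in two steps:

1. last value carried forward (LVCF) within the window — a value observed
   in an earlier block is carried into every later unset block;
2. residual cells are drawn independently from a Gaussian whose central
   95% interval equals the analyte's physiological normal range, i.e.
   ``mu = (low + high) / 2`` and ``sigma = (high - low) / (2 * 1.95996)``.
   Draws are deliberately not truncated at physical bounds; downstream
   standardization absorbs scale.

Each cell keeps a provenance mask (observed / lvcf / gaussian) so that no
imputation step can overwrite an observed value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortBundle

logger = logging.getLogger(__name__)

N_BLOCKS = 9
BLOCK_HOURS = 8.0
WINDOW_HOURS = N_BLOCKS * BLOCK_HOURS  # 72 h

MASK_UNSET = 0
MASK_OBSERVED = 1
MASK_LVCF = 2
MASK_GAUSSIAN = 3

_Z95 = 1.959963984540054


def normal_range_sigma(normal_low, normal_high):
    """SD of the imputation Gaussian: central 95% interval == normal range."""
    return (np.asarray(normal_high) - np.asarray(normal_low)) / (2.0 * _Z95)


@dataclass
class TemporalTensor:
    """Patient x analyte x 9-block grid with per-cell provenance."""

    values: np.ndarray  # (n_patients, n_analytes, 9) float
    mask: np.ndarray  # (n_patients, n_analytes, 9) int8
    patient_ids: np.ndarray  # (n_patients,) str
    analytes: list[str]
    anchors: pd.Series = field(repr=False, default=None)  # patient_id -> anchor

    def copy(self) -> "TemporalTensor":
        return TemporalTensor(
            self.values.copy(), self.mask.copy(), self.patient_ids.copy(),
            list(self.analytes),
            None if self.anchors is None else self.anchors.copy(),
        )

    @property
    def shape(self):
        return self.values.shape


def compute_lab_prevalence(bundle: CohortBundle) -> CohortBundle:
    """Fraction of stays with >= 1 order per analyte, stored into the panel.

    A stay contributes at most once per analyte regardless of how many
    orders it placed.
    """
    n_stays = bundle.n_stays
    counts = (
        bundle.labs.drop_duplicates(["patient_id", "analyte_code"])
        .groupby("analyte_code")
        .size()
    )
    panel = bundle.panel.copy()
    panel["prevalence"] = (
        panel["analyte_code"].map(counts).fillna(0).astype(float) / max(n_stays, 1)
    )
    out = bundle.copy()
    out.panel = panel
    return out


def filter_rare_labs(panel: pd.DataFrame, threshold: float = 0.10) -> pd.DataFrame:
    """Drop analytes ordered in strictly less than ``threshold`` of stays."""
    if "prevalence" not in panel.columns:
        raise ValueError("panel has no prevalence column; run compute_lab_prevalence")
    kept = panel[panel["prevalence"] >= threshold].reset_index(drop=True)
    if kept.empty:
        raise ValueError(
            f"rare-lab filter at threshold {threshold} removed every analyte"
        )
    return kept


def default_anchors(bundle: CohortBundle, truncation_hours: float = 0.0) -> pd.Series:
    """Anchor per patient: stay_end minus the prospective truncation horizon."""
    if truncation_hours < 0:
        raise ValueError("truncation_hours must be non-negative")
    stays = bundle.stays
    anchors = stays["stay_end"] - pd.to_timedelta(truncation_hours, unit="h")
    too_early = anchors <= stays["stay_start"]
    if too_early.any():
        logger.info(
            "%d patient(s) have anchors at or before stay_start; "
            "their grids will be fully imputed",
            int(too_early.sum()),
        )
    return pd.Series(anchors.to_numpy(), index=stays["patient_id"].to_numpy())


def build_blocks(
    bundle: CohortBundle,
    anchors: pd.Series | None = None,
    truncation_hours: float = 0.0,
) -> TemporalTensor:
    """Grid the lab events onto the 9 x 8 h window ending at each anchor.

    Within a block the event with the latest charttime wins; charttime ties
    are broken by file order (last row wins), consistent with ingestion
    deduplication.  Events after the anchor or at/before anchor - 72 h are
    discarded.
    """
    if anchors is None:
        anchors = default_anchors(bundle, truncation_hours)
    stays = bundle.stays
    if (anchors.loc[stays["patient_id"]].to_numpy() > stays["stay_end"].to_numpy()).any():
        raise ValueError("anchor after stay_end")

    analytes = list(bundle.panel["analyte_code"])
    pat_ids = stays["patient_id"].to_numpy()
    a_index = {a: j for j, a in enumerate(analytes)}
    p_index = {p: i for i, p in enumerate(pat_ids)}

    labs = bundle.labs
    labs = labs[labs["analyte_code"].isin(a_index)]
    anchor_per_event = anchors.loc[labs["patient_id"]].to_numpy()
    age_h = (
        (anchor_per_event - labs["charttime"].to_numpy()).astype("timedelta64[ns]")
        / np.timedelta64(1, "s")
    ) / 3600.0
    age_h = np.asarray(age_h, dtype=float)
    in_window = (age_h >= 0.0) & (age_h < WINDOW_HOURS)
    labs = labs[in_window]
    age_h = age_h[in_window]
    block = N_BLOCKS - 1 - np.floor(age_h / BLOCK_HOURS).astype(int)  # 0-based

    # last value per (patient, analyte, block): stable sort keeps file order
    sel = pd.DataFrame(
        {
            "pi": labs["patient_id"].map(p_index).to_numpy(),
            "aj": labs["analyte_code"].map(a_index).to_numpy(),
            "block": block,
            "charttime": labs["charttime"].to_numpy(),
            "value": labs["value"].to_numpy(),
        }
    )
    sel = sel.sort_values("charttime", kind="stable")
    sel = sel.drop_duplicates(["pi", "aj", "block"], keep="last")

    values = np.zeros((len(pat_ids), len(analytes), N_BLOCKS))
    mask = np.zeros(values.shape, dtype=np.int8)
    values[sel["pi"], sel["aj"], sel["block"]] = sel["value"]
    mask[sel["pi"], sel["aj"], sel["block"]] = MASK_OBSERVED
    return TemporalTensor(values, mask, pat_ids.copy(), analytes, anchors)


def impute_lvcf(tensor: TemporalTensor) -> TemporalTensor:
    """Carry each observed value forward into subsequent unset blocks."""
    out = tensor.copy()
    vals, mask = out.values, out.mask
    observed = mask == MASK_OBSERVED
    block_idx = np.arange(N_BLOCKS)
    src = np.where(observed, block_idx, -1)
    src = np.maximum.accumulate(src, axis=2)  # latest observed block so far
    fill = (mask == MASK_UNSET) & (src >= 0)
    gathered = np.take_along_axis(vals, np.clip(src, 0, None), axis=2)
    vals[fill] = gathered[fill]
    mask[fill] = MASK_LVCF
    return out


def impute_normal_gaussian(
    tensor: TemporalTensor, panel: pd.DataFrame, rng: np.random.Generator
) -> TemporalTensor:
    """Fill residual unset cells from the normal-range Gaussian."""
    panel = panel.set_index("analyte_code").loc[tensor.analytes]
    lo = panel["normal_low"].to_numpy(float)
    hi = panel["normal_high"].to_numpy(float)
    if not (lo < hi).all():
        raise ValueError("degenerate normal range (low >= high)")
    mu = (lo + hi) / 2.0
    sigma = normal_range_sigma(lo, hi)

    out = tensor.copy()
    unset = out.mask == MASK_UNSET
    if unset.any():
        draws = rng.standard_normal(out.values.shape) * sigma[None, :, None] + mu[
            None, :, None
        ]
        out.values[unset] = draws[unset]
        out.mask[unset] = MASK_GAUSSIAN
    return out


@dataclass
class Standardization:
    """Per-analyte z-scaling constants, fit on the embedding-training rows."""

    mean: np.ndarray
    sd: np.ndarray
    analytes: list[str]

    @classmethod
    def fit(cls, tensor: TemporalTensor, row_mask: np.ndarray) -> "Standardization":
        sub = tensor.values[row_mask]
        if sub.size == 0:
            raise ValueError("no rows selected for standardization fit")
        mean = sub.mean(axis=(0, 2))
        sd = sub.std(axis=(0, 2))
        sd = np.where(sd < 1e-8, 1.0, sd)
        return cls(mean, sd, list(tensor.analytes))

    def transform(self, tensor: TemporalTensor) -> TemporalTensor:
        if list(tensor.analytes) != self.analytes:
            raise ValueError("analyte order mismatch in standardization")
        out = tensor.copy()
        out.values = (out.values - self.mean[None, :, None]) / self.sd[None, :, None]
        return out

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "analytes": self.analytes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardization":
        return cls(np.asarray(d["mean"]), np.asarray(d["sd"]), list(d["analytes"]))


_MASK_NAMES = {MASK_UNSET: "unset", MASK_OBSERVED: "observed",
               MASK_LVCF: "lvcf", MASK_GAUSSIAN: "gaussian"}


def tensor_to_frame(tensor: TemporalTensor) -> pd.DataFrame:
    """Wide serialization: one row per (patient, analyte) with 9 value and
    9 mask columns."""
    n, a, b = tensor.shape
    rows = {
        "patient_id": np.repeat(tensor.patient_ids, a),
        "analyte_code": np.tile(tensor.analytes, n),
    }
    for k in range(b):
        rows[f"block_{k + 1}"] = tensor.values[:, :, k].reshape(-1)
    for k in range(b):
        rows[f"mask_{k + 1}"] = tensor.mask[:, :, k].reshape(-1)
    return pd.DataFrame(rows)


def frame_to_tensor(frame: pd.DataFrame, analytes: list[str]) -> TemporalTensor:
    pats = frame["patient_id"].drop_duplicates().to_numpy()
    n, a = len(pats), len(analytes)
    wide = frame.set_index(["patient_id", "analyte_code"])
    vals = np.stack(
        [wide[f"block_{k + 1}"].to_numpy().reshape(n, a) for k in range(N_BLOCKS)],
        axis=2,
    )
    mask = np.stack(
        [wide[f"mask_{k + 1}"].to_numpy().reshape(n, a) for k in range(N_BLOCKS)],
        axis=2,
    ).astype(np.int8)
    return TemporalTensor(vals, mask, pats, list(analytes), None)
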