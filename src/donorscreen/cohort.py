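"""Cohort data model, CSV ingestion/validation, and inclusion filters.

The cohort is carried as three pandas tables sharing one schema contract:

``labs``
    long-format laboratory events — ``patient_id, analyte_code, charttime,
    value`` with one row per result.
``stays``
    one row per ICU stay — ``patient_id, stay_start, stay_end, specialty,
    head_imaging, label, subtype, died_in_icu``.  ``label`` is 1 iff the
    patient is a potential organ donor, i.e. ``subtype != "non_donor"``.
``panel``
    per-analyte metadata — ``analyte_code, units, normal_low, normal_high``
    and, once computed, per-cohort ordering ``prevalence``.

Inclusion criteria: one index stay per patient (the one
ending last) and a minimum length of stay of 16 h (inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBTYPES = (
    "non_donor",
    "local_donor",
    "transferred_donor",
    "referred_ineligible",
    "potential_not_referred",
)
DONOR_SUBTYPES = SUBTYPES[1:]

LABS_COLUMNS = ["patient_id", "analyte_code", "charttime", "value"]
STAYS_COLUMNS = [
    "patient_id",
    "stay_start",
    "stay_end",
    "specialty",
    "head_imaging",
    "label",
    "subtype",
    "died_in_icu",
]
PANEL_COLUMNS = ["analyte_code", "units", "normal_low", "normal_high"]

TIME_FORMAT = "%Y-%m-%dT%H:%M:%S"


class CohortSchemaError(ValueError):
    """A table is missing columns or violates a field-level contract."""


class CohortValidationError(ValueError):
    """Cross-table referential integrity or invariant failure."""


@dataclass
class CohortBundle:
    """Validated labs + stays + panel with provenance counters."""

    labs: pd.DataFrame
    stays: pd.DataFrame
    panel: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_stays(self) -> int:
        return len(self.stays)

    @property
    def n_events(self) -> int:
        return len(self.labs)

    def copy(self) -> "CohortBundle":
        return CohortBundle(
            self.labs.copy(), self.stays.copy(), self.panel.copy(),
            dict(self.provenance),
        )


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{name} is missing column(s): {', '.join(missing)}")


def _parse_times(series: pd.Series, name: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="ISO8601", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 2)[:5]  # 1-based + header
        raise CohortSchemaError(
            f"unparseable timestamp in {name} at file line(s) {list(rows)}"
        )
    return parsed


def validate_bundle(bundle: CohortBundle) -> CohortBundle:
    """Check all cross-table invariants; raise on the first violation."""
    labs, stays, panel = bundle.labs, bundle.stays, bundle.panel

    if not np.isfinite(labs["value"].to_numpy(dtype=float)).all():
        raise CohortValidationError("labs contains non-finite values")
    if (labs["analyte_code"].astype(str).str.len() == 0).any():
        raise CohortValidationError("labs contains empty analyte codes")

    unknown = set(labs["analyte_code"]) - set(panel["analyte_code"])
    if unknown:
        raise CohortValidationError(
            f"lab events reference analyte(s) absent from panel: {sorted(unknown)}"
        )
    orphans = set(labs["patient_id"]) - set(stays["patient_id"])
    if orphans:
        raise CohortValidationError(
            f"lab events reference patient(s) absent from stays: "
            f"{sorted(orphans)[:5]}"
        )

    if not (stays["stay_end"] > stays["stay_start"]).all():
        raise CohortValidationError("stay_end must be strictly after stay_start")
    bad_sub = set(stays["subtype"]) - set(SUBTYPES)
    if bad_sub:
        raise CohortValidationError(f"unknown donor subtype(s): {sorted(bad_sub)}")
    expect_label = (stays["subtype"] != "non_donor").astype(int)
    if not (stays["label"].astype(int) == expect_label).all():
        raise CohortValidationError("label must be 1 iff subtype != non_donor")

    lo = panel["normal_low"].to_numpy(dtype=float)
    hi = panel["normal_high"].to_numpy(dtype=float)
    if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
        raise CohortValidationError("panel normal ranges must be finite")
    if not (lo < hi).all():
        raise CohortValidationError("panel requires normal_low < normal_high")
    if "prevalence" in panel.columns:
        prev = panel["prevalence"].dropna()
        if ((prev < 0) | (prev > 1)).any():
            raise CohortValidationError("panel prevalence must lie in [0, 1]")
    return bundle


def read_cohort(labs_path, stays_path, panel_path) -> CohortBundle:
    """Read and validate the three cohort CSVs.

    Duplicate ``(patient_id, analyte_code, charttime)`` lab rows are collapsed
    keeping the last file occurrence (mirroring last-value semantics used
    downstream); the dropped count is logged and recorded in provenance.
    """
    # keep_default_na: analyte codes like "NA" are real identifiers
    labs = pd.read_csv(labs_path, dtype={"patient_id": str, "analyte_code": str},
                       keep_default_na=False, na_values=[""])
    stays = pd.read_csv(stays_path, dtype={"patient_id": str},
                        keep_default_na=False, na_values=[""])
    panel = pd.read_csv(panel_path, dtype={"analyte_code": str},
                        keep_default_na=False, na_values=[""])

    _require_columns(labs, LABS_COLUMNS, "labs")
    _require_columns(stays, STAYS_COLUMNS, "stays")
    _require_columns(panel, PANEL_COLUMNS, "panel")

    labs["charttime"] = _parse_times(labs["charttime"], "labs.charttime")
    labs["value"] = labs["value"].astype(float)
    stays["stay_start"] = _parse_times(stays["stay_start"], "stays.stay_start")
    stays["stay_end"] = _parse_times(stays["stay_end"], "stays.stay_end")
    stays["specialty"] = stays["specialty"].astype("string")
    for col in ("head_imaging", "label", "died_in_icu"):
        stays[col] = stays[col].astype(int)

    n_raw = len(labs)
    labs = labs.drop_duplicates(
        subset=["patient_id", "analyte_code", "charttime"], keep="last"
    ).reset_index(drop=True)
    n_dup = n_raw - len(labs)
    if n_dup:
        logger.info("deduplicated %d repeated lab rows (kept last occurrence)", n_dup)

    bundle = CohortBundle(
        labs, stays, panel,
        provenance={"labs_rows_read": n_raw, "labs_duplicates_dropped": n_dup},
    )
    return validate_bundle(bundle)


def write_cohort(bundle: CohortBundle, outdir) -> dict[str, Path]:
    """Write labs/stays/panel CSVs in the canonical dialect (UTF-8, LF)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    labs = bundle.labs.copy()
    labs["charttime"] = labs["charttime"].dt.strftime(TIME_FORMAT)
    stays = bundle.stays.copy()
    for col in ("stay_start", "stay_end"):
        stays[col] = stays[col].dt.strftime(TIME_FORMAT)
    for name, df in (("labs", labs), ("stays", stays), ("panel", bundle.panel)):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, lineterminator="\n", encoding="utf-8")
        paths[name] = p
    return paths


def select_index_stays(bundle: CohortBundle, min_los_hours: float = 16.0) -> CohortBundle:
    """Apply the inclusion filters: latest stay per patient, LOS >= 16 h.

    Idempotent; lab events of removed stays are dropped.  Returns a new
    bundle with before/after counts appended to provenance.
    """
    stays = bundle.stays
    n_before = len(stays)
    # latest ICU stay per patient (ties broken by file order, keep last)
    stays = stays.loc[stays.groupby("patient_id")["stay_end"].idxmax()]
    los_h = (stays["stay_end"] - stays["stay_start"]).dt.total_seconds() / 3600.0
    stays = stays[los_h >= min_los_hours].reset_index(drop=True)

    keep = set(stays["patient_id"])
    labs = bundle.labs[bundle.labs["patient_id"].isin(keep)].reset_index(drop=True)

    if stays.empty:
        logger.warning("inclusion filters removed every stay")
    prov = dict(bundle.provenance)
    prov.update({"stays_before_inclusion": n_before, "stays_after_inclusion": len(stays)})
    return CohortBundle(labs, stays, bundle.panel.copy(), prov)


def stay_los_hours(stays: pd.DataFrame) -> pd.Series:
    return (stays["stay_end"] - stays["stay_start"]).dt.total_seconds() / 3600.0
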