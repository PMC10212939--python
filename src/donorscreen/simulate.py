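"""Seeded synthetic ICU cohort generator.

Emulates the statistical structure the screening pipeline assumes, so every
downstream stage is testable without access to the restricted hospital
cohort:

* ~2% outcome prevalence (potential organ donors) with four donor subtypes;
* ~100 analytes, each with a laboratory normal range; a configurable
  fraction are rarely ordered so the rare-lab filter is exercised;
* irregular, missing-not-at-random ordering — the instantaneous ordering
  intensity is multiplied by ``1 + mnar_strength * |z|`` of the last
  observed value, mimicking clinicians re-ordering abnormal tests;
* end-of-stay trajectory drift in donor-labelled patients on a designated
  signal subset of analytes, with per-analyte random sign.  ``signal_shape
  = "monotone"`` ramps to its maximum at the end of stay; ``"transient"``
  peaks mid-way through the drift window and returns to baseline, leaving
  the final value uninformative (a purely temporal signal).

Values evolve as an Ornstein-Uhlenbeck process around a per-patient
baseline drawn near the middle of the normal range; all dispersion is
expressed in units of the range-implied SD (range width / 3.92).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import substream
from .cohort import CohortBundle, DONOR_SUBTYPES, stay_los_hours, validate_bundle

logger = logging.getLogger(__name__)

_SPECIALTIES = (
    "cardiac_surgery",
    "general_surgery",
    "hepatology",
    "internal_medicine",
    "neurosurgery",
    "intensive_care",
    "burn_unit",
)
_SPECIALTY_BASE_P = np.array([0.37, 0.10, 0.05, 0.045, 0.04, 0.05, 0.035])
# residual mass -> other wards + missing
_SPECIALTY_MISSING_P = 0.05

# half-width of the central 95% interval of a standard normal
_Z95 = 1.959963984540054


@dataclass
class SimConfig:
    """Generator configuration; defaults are the reference study conditions."""

    n_patients: int = 2000
    donor_prevalence: float = 0.02
    n_analytes: int = 103
    ordering_rate: float = 2.0  # mean orders / analyte / 24 h, common analytes
    rare_fraction: float = 0.25
    n_signal_analytes: int = 15
    effect_size: float = 2.0  # drift amplitude in range-SD units
    drift_onset_hours: float = 48.0
    signal_shape: str = "monotone"  # or "transient"
    mnar_strength: float = 1.0
    # LOS = 16 h + LogNormal(mu, sigma) hours  -> median ~ 49 h
    los_lognormal: tuple[float, float] = (3.5, 0.9)
    subtype_props: tuple[float, ...] = (0.60, 0.20, 0.12, 0.08)
    head_imaging_base: float = 0.21
    head_imaging_donor: float = 0.74
    static_effects: bool = True  # donor-conditional statics (off => null statics)
    # within-patient dynamics, in range-SD units
    baseline_sd: float = 0.5
    ou_sd: float = 0.5
    ou_tau_hours: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.donor_prevalence < 1.0:
            raise ValueError("donor_prevalence must lie in (0, 1)")
        if self.effect_size < 0 or self.mnar_strength < 0 or self.ordering_rate < 0:
            raise ValueError("rates and effect sizes must be non-negative")
        if self.signal_shape not in ("monotone", "transient"):
            raise ValueError("signal_shape must be 'monotone' or 'transient'")
        if abs(sum(self.subtype_props) - 1.0) > 1e-9:
            raise ValueError("subtype_props must sum to 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _make_panel(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    mid = 10.0 ** rng.uniform(0.0, 2.5, cfg.n_analytes)
    width = mid * rng.uniform(0.2, 0.8, cfg.n_analytes)
    return pd.DataFrame(
        {
            "analyte_code": [f"LAB{i:03d}" for i in range(cfg.n_analytes)],
            "units": "arb",
            "normal_low": mid - width / 2,
            "normal_high": mid + width / 2,
        }
    )


def _drift_shape(t: np.ndarray, los: float, onset: float, shape: str) -> np.ndarray:
    """Drift envelope in [0, 1] as a function of time since stay start."""
    start = max(0.0, los - onset)
    span = los - start
    if span <= 0:
        return np.zeros_like(t)
    if shape == "monotone":
        return np.clip((t - start) / onset, 0.0, 1.0)
    peak = start + span / 2.0
    return np.clip(1.0 - np.abs(t - peak) / (span / 2.0), 0.0, 1.0)


def generate_cohort(config: SimConfig) -> CohortBundle:
    """Draw a full synthetic cohort; deterministic given ``config.seed``.

    Returns a validated :class:`CohortBundle` whose provenance carries the
    realized configuration and the ground-truth signal/rare analyte sets.
    """
    cfg = config
    if cfg.n_patients * cfg.donor_prevalence < 2:
        warnings.warn(
            "expected donor count below 2; the donor class may be degenerate",
            stacklevel=2,
        )

    panel = _make_panel(cfg, substream(cfg.seed, "panel"))
    mids = ((panel["normal_low"] + panel["normal_high"]) / 2).to_numpy()
    range_sd = ((panel["normal_high"] - panel["normal_low"]) / (2 * _Z95)).to_numpy()
    A = cfg.n_analytes

    rng_struct = substream(cfg.seed, "structure")
    n_rare = int(round(cfg.rare_fraction * A))
    rare_idx = rng_struct.choice(A, size=n_rare, replace=False)
    is_rare = np.zeros(A, bool)
    is_rare[rare_idx] = True
    # per-analyte base intensity per hour; rare analytes below the 10% filter
    rate = (cfg.ordering_rate / 24.0) * np.exp(rng_struct.normal(0.0, 0.3, A))
    rate[is_rare] = rng_struct.uniform(0.0003, 0.0015, n_rare)
    common_idx = np.flatnonzero(~is_rare)
    n_signal = min(cfg.n_signal_analytes, common_idx.size)
    signal_idx = rng_struct.choice(common_idx, size=n_signal, replace=False)
    signal_sign = np.zeros(A)
    signal_sign[signal_idx] = rng_struct.choice([-1.0, 1.0], size=n_signal)

    rng_pat = substream(cfg.seed, "patients")
    rng_lab = substream(cfg.seed, "labels")
    rng_stat = substream(cfg.seed, "statics")
    rng_ev = substream(cfg.seed, "events")

    n = cfg.n_patients
    los = 16.0 + rng_pat.lognormal(*cfg.los_lognormal, size=n)
    start_offset_h = rng_pat.uniform(0.0, 4 * 365 * 24.0, size=n)
    t0 = pd.Timestamp("2015-01-01")

    labels = (rng_lab.random(n) < cfg.donor_prevalence).astype(int)
    subtype = np.where(labels == 1, "", "non_donor").astype(object)
    donors = np.flatnonzero(labels == 1)
    subtype[donors] = rng_lab.choice(
        DONOR_SUBTYPES, size=donors.size, p=cfg.subtype_props
    )

    if cfg.static_effects:
        p_img = np.where(labels == 1, cfg.head_imaging_donor, cfg.head_imaging_base)
    else:
        p_img = np.full(n, cfg.head_imaging_base)
    head_imaging = (rng_stat.random(n) < p_img).astype(int)

    spec_p = np.concatenate([_SPECIALTY_BASE_P, [_SPECIALTY_MISSING_P]])
    spec_p = np.append(spec_p, 1.0 - spec_p.sum())  # "other"
    cats = list(_SPECIALTIES) + ["", "other"]
    spec_p_donor = spec_p.copy()
    if cfg.static_effects:
        for name in ("neurosurgery", "intensive_care"):
            spec_p_donor[cats.index(name)] *= 3.0
        spec_p_donor /= spec_p_donor.sum()
    specialty = np.empty(n, object)
    for i in range(n):
        p = spec_p_donor if labels[i] == 1 else spec_p
        specialty[i] = cats[rng_stat.choice(len(cats), p=p)]

    p_die = np.where(labels == 1, 0.9, 0.09)
    died = (rng_stat.random(n) < p_die).astype(int)

    pat_ids = np.array([f"P{i:06d}" for i in range(n)])
    ev_pat: list[np.ndarray] = []
    ev_code: list[np.ndarray] = []
    ev_t: list[np.ndarray] = []
    ev_val: list[np.ndarray] = []

    codes = panel["analyte_code"].to_numpy()

    for i in range(n):
        baseline = mids + range_sd * cfg.baseline_sd * rng_ev.standard_normal(A)
        drift_amp = (
            cfg.effect_size * range_sd * signal_sign if labels[i] == 1 else None
        )
        t = np.zeros(A)
        z = cfg.ou_sd * rng_ev.standard_normal(A)  # stationary start
        z_last_obs = np.zeros(A)  # nothing observed yet -> base intensity
        active = np.ones(A, bool)
        li = los[i]
        for _ in range(500):
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            lam = rate[idx] * (1.0 + cfg.mnar_strength * np.abs(z_last_obs[idx]))
            gaps = rng_ev.exponential(1.0, idx.size) / lam
            t_new = t[idx] + gaps
            alive = t_new <= li
            dead = idx[~alive]
            active[dead] = False
            idx = idx[alive]
            if idx.size == 0:
                continue
            dt = t_new[alive] - t[idx]
            decay = np.exp(-dt / cfg.ou_tau_hours)
            z[idx] = z[idx] * decay + cfg.ou_sd * np.sqrt(
                1.0 - decay**2
            ) * rng_ev.standard_normal(idx.size)
            t[idx] = t_new[alive]
            val = baseline[idx] + range_sd[idx] * z[idx]
            if drift_amp is not None:
                shape = _drift_shape(
                    t[idx], li, cfg.drift_onset_hours, cfg.signal_shape
                )
                val = val + drift_amp[idx] * shape
            z_last_obs[idx] = (val - mids[idx]) / range_sd[idx]
            ev_pat.append(np.full(idx.size, i, dtype=np.int32))
            ev_code.append(idx.astype(np.int32))
            ev_t.append(t[idx].copy())
            ev_val.append(val)

    pi = np.concatenate(ev_pat) if ev_pat else np.empty(0, np.int32)
    ai = np.concatenate(ev_code) if ev_code else np.empty(0, np.int32)
    th = np.concatenate(ev_t) if ev_t else np.empty(0)
    vv = np.concatenate(ev_val) if ev_val else np.empty(0)

    abs_seconds = np.round((start_offset_h[pi] + th) * 3600.0).astype("int64")
    charttime = t0 + pd.to_timedelta(abs_seconds, unit="s")
    labs = pd.DataFrame(
        {
            "patient_id": pat_ids[pi],
            "analyte_code": codes[ai],
            "charttime": charttime,
            "value": vv,
        }
    ).sort_values(["patient_id", "charttime"], kind="stable").reset_index(drop=True)
    labs = labs.drop_duplicates(
        subset=["patient_id", "analyte_code", "charttime"], keep="last"
    ).reset_index(drop=True)

    stays = pd.DataFrame(
        {
            "patient_id": pat_ids,
            "stay_start": t0 + pd.to_timedelta(np.round(start_offset_h * 3600), unit="s"),
            "stay_end": t0
            + pd.to_timedelta(np.round((start_offset_h + los) * 3600), unit="s"),
            "specialty": pd.array(specialty, dtype="string"),
            "head_imaging": head_imaging,
            "label": labels,
            "subtype": subtype.astype(str),
            "died_in_icu": died,
        }
    )
    stays.loc[stays["specialty"] == "", "specialty"] = pd.NA

    truth = {
        "config": cfg.to_dict(),
        "signal_analytes": sorted(codes[signal_idx].tolist()),
        "rare_analytes": sorted(codes[rare_idx].tolist()),
    }
    bundle = CohortBundle(labs, stays, panel, provenance={"simulation": truth})
    return validate_bundle(bundle)


def cohort_summary(bundle: CohortBundle) -> pd.DataFrame:
    """Per-subtype counts/percentages plus LOS and imaging descriptives."""
    stays = bundle.stays
    n = len(stays)
    rows = []
    counts = stays["subtype"].value_counts()
    for s in ("non_donor",) + DONOR_SUBTYPES:
        c = int(counts.get(s, 0))
        rows.append({"item": f"subtype:{s}", "value": c, "pct": 100.0 * c / n if n else np.nan})
    los = stay_los_hours(stays)
    if n:
        q1, med, q3 = los.quantile([0.25, 0.5, 0.75])
    else:
        q1 = med = q3 = np.nan
    rows.append({"item": "los_median_h", "value": float(med), "pct": np.nan})
    rows.append({"item": "los_iqr_h", "value": float(q3 - q1), "pct": np.nan})
    img = stays["head_imaging"].mean() if n else np.nan
    rows.append({"item": "head_imaging_fraction", "value": float(img), "pct": np.nan})
    died = stays["died_in_icu"].mean() if n else np.nan
    rows.append({"item": "died_in_icu_fraction", "value": float(died), "pct": np.nan})
    return pd.DataFrame(rows)
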