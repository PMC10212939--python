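"""End-to-end screening model with a statsmodels-style Model/Results API.

:class:`DonorScreeningModel` is constructed from a cohort (read from CSVs
or simulated) plus a :class:`RunConfig`; :meth:`DonorScreeningModel.fit`
executes the full screening protocol —

    inclusion filters -> rare-lab filter -> ae/train/validation/test split
    -> 9 x 8 h blocking -> LVCF + normal-range Gaussian imputation ->
    standardization (fit on the embedding set) -> autoencoder on
    non-donors -> deep classifier and logistic baseline -> operating
    cutoff by threefold CV on the training partition -> one final
    evaluation on the untouched test partition

— and returns a :class:`DonorScreeningResults` carrying scores, metric
report, cutoffs and diagnostics, with ``summary()``, ``prospective()``
(re-anchored evaluation T hours before end of stay with frozen models)
and ``rare_lab_ablation()`` (full retrain at coarser prevalence filters).

Test-set hygiene is instrumented: test labels are only reachable through a
counting accessor, and a completed fit performs exactly one read.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import child_seed, substream
from .cohort import (
    CohortBundle, DONOR_SUBTYPES, read_cohort, select_index_stays,
)
from .encoding import (
    TargetMeanEncoder, class_weights, encode_static, fit_static_encoder,
    make_splits,
)
from .metrics import auroc, bootstrap_ci, derive_cutoff, metric_report
from .networks import (
    AEConfig, ClassifierConfig, DeepClassifier, LogisticBaseline,
    TemporalAutoencoder,
)
from .nncore import fit_network, weighted_bce_loss
from .preprocess import (
    Standardization, build_blocks, compute_lab_prevalence, filter_rare_labs,
    impute_lvcf, impute_normal_gaussian,
)
from .simulate import SimConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs; the defaults are the reference protocol."""

    min_los_hours: float = 16.0
    rare_threshold: float = 0.10
    ae_frac: float = 0.85
    tvt: tuple[float, float, float] = (0.60, 0.20, 0.20)
    smoothing: float = 10.0
    target_sensitivity: float = 0.90
    cutoff_folds: int = 3
    bootstrap_B: int = 2000
    calibration_bins: int = 10
    horizons: tuple[float, ...] = (8.0, 24.0, 48.0)
    ablation_thresholds: tuple[float, ...] = (0.10, 0.20, 0.30)
    use_reconstruction_error: bool = False
    ae: AEConfig | None = None
    clf: ClassifierConfig | None = None
    seed: int = 0

    def __post_init__(self):
        if any(h < 0 for h in self.horizons):
            raise ValueError("horizons must be non-negative")
        th = list(self.ablation_thresholds)
        if any(not 0 < t < 1 for t in th) or th != sorted(th) or len(set(th)) != len(th):
            raise ValueError("ablation thresholds must be strictly increasing in (0,1)")
        if self.ae is None:
            self.ae = AEConfig(seed=child_seed(self.seed, "ae"))
        if self.clf is None:
            self.clf = ClassifierConfig(seed=child_seed(self.seed, "clf"))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ModelBundle:
    """Everything needed to score a new cohort with the frozen models."""

    ae: TemporalAutoencoder
    clf: DeepClassifier
    lm: LogisticBaseline
    standardization: Standardization
    static_encoder: TargetMeanEncoder
    analytes: list[str]
    cutoffs: dict[str, float]
    config: RunConfig
    imputation_seed: int
    use_reconstruction_error: bool = False

    def fingerprint(self) -> str:
        return "|".join(self.analytes)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez(
            outdir / "weights.npz",
            **{f"ae_{i}": w for i, w in enumerate(self.ae.get_weights())},
            **{f"clf_{i}": w for i, w in enumerate(self.clf.get_weights())},
            lm_coef=self.lm.coef_, lm_intercept=np.array([self.lm.intercept_]),
            lm_classes=self.lm.model.classes_,
        )
        manifest = {
            "analytes": self.analytes,
            "cutoffs": self.cutoffs,
            "imputation_seed": self.imputation_seed,
            "use_reconstruction_error": self.use_reconstruction_error,
            "standardization": self.standardization.to_dict(),
            "static_encoder": json.loads(self.static_encoder.to_json()),
            "ae_config": dataclasses.asdict(self.config.ae),
            "clf_config": dataclasses.asdict(self.config.clf),
            "run_config": {
                k: v for k, v in self.config.to_dict().items()
                if k not in ("ae", "clf")
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, outdir) -> "ModelBundle":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        run_cfg = RunConfig(**manifest["run_config"],
                            ae=AEConfig(**manifest["ae_config"]),
                            clf=ClassifierConfig(**manifest["clf_config"]))
        analytes = manifest["analytes"]
        ae = TemporalAutoencoder(len(analytes), run_cfg.ae)
        n_static = 2 + (1 if manifest["use_reconstruction_error"] else 0)
        clf = DeepClassifier(run_cfg.ae.latent_dim + n_static, run_cfg.clf)
        with np.load(outdir / "weights.npz") as z:
            ae.set_weights([z[f"ae_{i}"] for i in range(len(ae.get_weights()))])
            clf.set_weights([z[f"clf_{i}"] for i in range(len(clf.get_weights()))])
            lm = LogisticBaseline()
            lm.model.coef_ = z["lm_coef"].reshape(1, -1)
            lm.model.intercept_ = z["lm_intercept"]
            lm.model.classes_ = z["lm_classes"]
        enc = TargetMeanEncoder.from_json(json.dumps(manifest["static_encoder"]))
        return cls(
            ae=ae, clf=clf, lm=lm,
            standardization=Standardization.from_dict(manifest["standardization"]),
            static_encoder=enc, analytes=analytes,
            cutoffs=manifest["cutoffs"], config=run_cfg,
            imputation_seed=manifest["imputation_seed"],
            use_reconstruction_error=manifest["use_reconstruction_error"],
        )

    def _features(self, bundle: CohortBundle, truncation_hours: float):
        """Grid, impute, standardize and encode a cohort for scoring."""
        missing = set(self.analytes) - set(bundle.panel["analyte_code"])
        if missing:
            raise ValueError(
                f"cohort panel lacks analyte(s) the model was fitted on: "
                f"{sorted(missing)[:5]}"
            )
        panel = (
            bundle.panel.set_index("analyte_code")
            .loc[self.analytes]
            .reset_index()
        )
        sub = bundle.copy()
        sub.panel = panel
        tensor = build_blocks(sub, truncation_hours=truncation_hours)
        tensor = impute_lvcf(tensor)
        rng = substream(self.imputation_seed, "impute", f"h{float(truncation_hours)}")
        tensor = impute_normal_gaussian(tensor, panel, rng)
        tensor = self.standardization.transform(tensor)
        statics = encode_static(sub.stays, self.static_encoder)
        return tensor, statics

    def predict(self, bundle: CohortBundle, truncation_hours: float = 0.0
                ) -> pd.DataFrame:
        """Per-stay risk scores for both models; deterministic."""
        if bundle.n_stays == 0:
            return pd.DataFrame(columns=["patient_id", "score_nn", "score_lm"])
        tensor, statics = self._features(bundle, truncation_hours)
        feats = [self.ae.encode(tensor.values), statics]
        if self.use_reconstruction_error:
            feats.append(self.ae.reconstruction_error(tensor.values)[:, None])
        score_nn = self.clf.predict_proba(np.column_stack(feats))
        lm_X = np.column_stack([tensor.values[:, :, -1], statics])
        score_lm = self.lm.predict_proba(lm_X)
        return pd.DataFrame(
            {"patient_id": tensor.patient_ids, "score_nn": score_nn,
             "score_lm": score_lm}
        )


class DonorScreeningModel:
    """The screening pipeline as a fittable model over a cohort bundle."""

    def __init__(self, bundle: CohortBundle, config: RunConfig | None = None):
        self.raw_bundle = bundle
        self.config = config or RunConfig()

    @classmethod
    def from_csv(cls, labs_path, stays_path, panel_path,
                 config: RunConfig | None = None) -> "DonorScreeningModel":
        return cls(read_cohort(labs_path, stays_path, panel_path), config)

    @classmethod
    def from_simulation(cls, sim_config: SimConfig,
                        config: RunConfig | None = None) -> "DonorScreeningModel":
        if config is None:
            config = RunConfig(seed=sim_config.seed)
        return cls(generate_cohort(sim_config), config)

    # -- fitting ---------------------------------------------------------

    def fit(self) -> "DonorScreeningResults":
        cfg = self.config
        logger.info("stage=inclusion")
        bundle = select_index_stays(self.raw_bundle, cfg.min_los_hours)
        bundle = compute_lab_prevalence(bundle)
        panel_full = bundle.panel
        bundle = bundle.copy()
        bundle.panel = filter_rare_labs(panel_full, cfg.rare_threshold)
        logger.info(
            "stage=rare_lab_filter kept=%d of %d analytes",
            len(bundle.panel), len(panel_full),
        )

        splits = make_splits(bundle.stays, cfg.seed, cfg.ae_frac, cfg.tvt)
        part = splits.set_index("patient_id")["partition"]
        stays = bundle.stays
        part_row = part.loc[stays["patient_id"]].to_numpy()
        labels_all = stays["label"].to_numpy().astype(int)
        is_ae = part_row == "ae_train"
        is_tr = part_row == "train"
        is_va = part_row == "validation"
        is_te = part_row == "test"

        # the hygiene guard: test labels reachable only via the accessor
        self._test_labels_store = labels_all[is_te].copy()
        self._test_label_reads = 0
        labels_masked = labels_all.copy()
        labels_masked[is_te] = -1  # sentinel: not to be used in fitting

        imput_seed = child_seed(cfg.seed, "imputation")
        tensor_raw = self._prepare_raw_tensor(bundle, imput_seed, 0.0)
        std = Standardization.fit(tensor_raw, is_ae)
        tensor = std.transform(tensor_raw)

        logger.info("stage=static_encoding")
        enc = fit_static_encoder(stays[is_tr], cfg.smoothing)
        statics = encode_static(stays, enc)

        logger.info("stage=autoencoder n=%d", int(is_ae.sum()))
        ae = TemporalAutoencoder(len(tensor.analytes), cfg.ae)
        ae.fit(tensor.values[is_ae], labels_masked[is_ae])

        latents = ae.encode(tensor.values)
        feats = [latents, statics]
        if cfg.use_reconstruction_error:
            feats.append(ae.reconstruction_error(tensor.values)[:, None])
        X_nn = np.column_stack(feats)
        X_lm = np.column_stack([tensor.values[:, :, -1], statics])

        y_tr, y_va = labels_masked[is_tr], labels_masked[is_va]
        w_tr = _per_sample_weights(y_tr)
        w_va = _per_sample_weights(y_va)

        logger.info("stage=classifier n_train=%d", int(is_tr.sum()))
        clf = DeepClassifier(X_nn.shape[1], cfg.clf)
        clf.fit(X_nn[is_tr], y_tr, w_tr, X_nn[is_va], y_va, w_va)

        logger.info("stage=logistic")
        y_trva = labels_masked[is_tr | is_va]
        lm = LogisticBaseline(seed=cfg.seed)
        lm.fit(X_lm[is_tr | is_va], y_trva, _per_sample_weights(y_trva))

        logger.info("stage=cutoff folds=%d", cfg.cutoff_folds)
        cut_seed = child_seed(cfg.seed, "cutoff")
        cutoffs = {
            "nn": self._cv_cutoff_nn(X_nn[is_tr], y_tr, clf, cut_seed),
            "lm": self._cv_cutoff_lm(X_lm[is_tr], y_tr, cut_seed),
        }

        score_nn = clf.predict_proba(X_nn)
        score_lm = lm.predict_proba(X_lm)

        logger.info("stage=evaluation n_test=%d", int(is_te.sum()))
        y_test = self._read_test_labels()
        boot_seed = child_seed(cfg.seed, "bootstrap")
        report = metric_report(
            {"nn": score_nn[is_te], "lm": score_lm[is_te]}, y_test,
            cutoffs, B=cfg.bootstrap_B, seed=boot_seed,
            bins=cfg.calibration_bins,
        )
        subgroups = _subgroup_aurocs(
            score_nn[is_te], score_lm[is_te], y_test,
            stays.loc[is_te, "subtype"].to_numpy(),
        )

        labels_out = labels_masked.copy()
        labels_out[is_te] = y_test
        predictions = pd.DataFrame(
            {
                "patient_id": stays["patient_id"],
                "score_nn": score_nn,
                "score_lm": score_lm,
                "label": labels_out,
                "subtype": stays["subtype"],
                "partition": part_row,
            }
        )

        model_bundle = ModelBundle(
            ae=ae, clf=clf, lm=lm, standardization=std, static_encoder=enc,
            analytes=list(tensor.analytes), cutoffs=cutoffs, config=cfg,
            imputation_seed=imput_seed,
            use_reconstruction_error=cfg.use_reconstruction_error,
        )
        return DonorScreeningResults(
            model=self, bundle=bundle, model_bundle=model_bundle,
            splits=splits, predictions=predictions, metrics=report,
            cutoffs=cutoffs, subgroup_aurocs=subgroups,
            diagnostics={
                "test_label_reads": self._test_label_reads,
                "ae_history": ae.history,
                "clf_history": clf.history,
                "provenance": bundle.provenance,
            },
        )

    # -- internals -------------------------------------------------------

    def _read_test_labels(self) -> np.ndarray:
        self._test_label_reads += 1
        return self._test_labels_store.copy()

    @staticmethod
    def _prepare_raw_tensor(bundle, imput_seed, truncation_hours):
        tensor = build_blocks(bundle, truncation_hours=truncation_hours)
        tensor = impute_lvcf(tensor)
        rng = substream(imput_seed, "impute", f"h{float(truncation_hours)}")
        return impute_normal_gaussian(tensor, bundle.panel, rng)

    def _cv_cutoff_nn(self, X, y, fitted_clf, seed):
        cfg = self.config
        epochs = fitted_clf.history["refit_epochs"]
        fold_no = [0]

        def scores_fn(tr, te):
            fold_no[0] += 1
            sub = DeepClassifier(
                X.shape[1],
                dataclasses.replace(cfg.clf, seed=child_seed(seed, "fold", fold_no[0])),
            )
            w = _per_sample_weights(y[tr])
            fit_network(
                sub.net, np.asarray(X[tr], np.float32),
                np.asarray(y[tr], np.float32), loss_fn=weighted_bce_loss,
                sample_weight=w, epochs=epochs, batch_size=cfg.clf.batch_size,
                lr=cfg.clf.lr, l2=cfg.clf.l2, patience=None,
                rng=substream(seed, "fold-train", fold_no[0]),
            )
            return sub.predict_proba(X[te])

        return derive_cutoff(
            scores_fn, y, cfg.target_sensitivity, cfg.cutoff_folds, seed
        ).cutoff

    def _cv_cutoff_lm(self, X, y, seed):
        cfg = self.config

        def scores_fn(tr, te):
            lm = LogisticBaseline()
            lm.fit(X[tr], y[tr], _per_sample_weights(y[tr]))
            return lm.predict_proba(X[te])

        return derive_cutoff(
            scores_fn, y, cfg.target_sensitivity, cfg.cutoff_folds, seed
        ).cutoff


def _per_sample_weights(labels: np.ndarray) -> np.ndarray:
    w = class_weights(labels)
    return np.where(np.asarray(labels) == 1, w[1], w[0]).astype(float)


def _subgroup_aurocs(score_nn, score_lm, y_test, subtype_test) -> pd.DataFrame:
    """AUROC of each donor subtype against all test non-donors."""
    rows = []
    neg = y_test == 0
    for sub in DONOR_SUBTYPES:
        m = subtype_test == sub
        sel = neg | m
        row = {"subtype": sub, "n_donors": int(m.sum())}
        for name, s in (("nn", score_nn), ("lm", score_lm)):
            if m.any():
                row[f"auroc_{name}"] = auroc(s[sel], (subtype_test[sel] == sub))
            else:
                row[f"auroc_{name}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class DonorScreeningResults:
    """Fitted-pipeline results: scores, metrics, cutoffs, diagnostics."""

    model: DonorScreeningModel
    bundle: CohortBundle = field(repr=False)
    model_bundle: ModelBundle = field(repr=False)
    splits: pd.DataFrame = field(repr=False)
    predictions: pd.DataFrame = field(repr=False)
    metrics: dict = field(repr=False)
    cutoffs: dict
    subgroup_aurocs: pd.DataFrame = field(repr=False)
    diagnostics: dict = field(repr=False)

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        rep = self.metrics
        lines = [
            "Donor screening results (test partition)",
            "=" * 56,
            f"n test = {rep['n']}   prevalence = {rep['prevalence']:.3f}",
            "",
            f"{'':14}{'NN model':>20}{'Logistic model':>22}",
        ]
        for metric in ("auroc", "scaled_brier", "sensitivity", "specificity"):
            row = [f"{metric:<14}"]
            for m in ("nn", "lm"):
                e = rep["models"][m][metric]
                row.append(f"{e['median']:.3f} ({e['lo']:.3f}-{e['hi']:.3f})")
            lines.append(f"{row[0]}{row[1]:>20}{row[2]:>22}")
        for m in ("nn", "lm"):
            lines.append(f"cutoff {m:<3}      {rep['models'][m]['cutoff']:.3f}")
        comp = rep["comparisons"]["nn_vs_lm"]
        lines += [
            "",
            f"paired AUROC z = {comp['auroc']['z']:+.2f}, p = {comp['auroc']['p']:.3f}",
            f"paired scaled-Brier z = {comp['scaled_brier']['z']:+.2f}, "
            f"p = {comp['scaled_brier']['p']:.3f}",
        ]
        return "\n".join(lines)

    # -- secondary analyses ---------------------------------------------

    def prospective(self, horizons: tuple[float, ...] | None = None
                    ) -> pd.DataFrame:
        """Frozen-model evaluation anchored T hours before end of stay."""
        cfg = self.model.config
        horizons = cfg.horizons if horizons is None else horizons
        is_te = (self.predictions["partition"] == "test").to_numpy()
        y_test = self.predictions.loc[is_te, "label"].to_numpy().astype(int)
        boot_seed = child_seed(cfg.seed, "bootstrap")
        rows = []
        for T in sorted(set([0.0] + [float(h) for h in horizons])):
            scores = self.model_bundle.predict(self.bundle, truncation_hours=T)
            for name in ("nn", "lm"):
                s = scores[f"score_{name}"].to_numpy()[is_te]
                med, lo, hi = bootstrap_ci(
                    auroc, s, y_test, B=cfg.bootstrap_B, seed=boot_seed
                )
                rows.append(
                    {"horizon_h": T, "model": name,
                     "auroc": auroc(s, y_test), "auroc_median": med,
                     "auroc_lo": lo, "auroc_hi": hi, "n": int(is_te.sum())}
                )
        return pd.DataFrame(rows)

    def rare_lab_ablation(self, thresholds: tuple[float, ...] | None = None
                          ) -> pd.DataFrame:
        """Retrain the full pipeline at coarser rare-lab thresholds."""
        cfg = self.model.config
        thresholds = cfg.ablation_thresholds if thresholds is None else thresholds
        rows = []
        for t in thresholds:
            sub_cfg = dataclasses.replace(
                cfg, rare_threshold=float(t),
                ae=dataclasses.replace(cfg.ae),
                clf=dataclasses.replace(cfg.clf),
            )
            try:
                res = DonorScreeningModel(self.model.raw_bundle, sub_cfg).fit()
            except ValueError as err:
                rows.append({"threshold": t, "failed": True, "error": str(err)})
                continue
            for name in ("nn", "lm"):
                e = res.metrics["models"][name]["auroc"]
                rows.append(
                    {"threshold": t, "failed": False, "model": name,
                     "n_analytes": len(res.model_bundle.analytes),
                     "auroc": e["point"], "auroc_median": e["median"],
                     "auroc_lo": e["lo"], "auroc_hi": e["hi"]}
                )
        return pd.DataFrame(rows)

    # -- artifacts -------------------------------------------------------

    def save_artifacts(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "metrics.json").write_text(json.dumps(self.metrics, indent=2))
        self.predictions.to_csv(outdir / "predictions.csv", index=False)
        self.splits.to_csv(outdir / "splits.csv", index=False)
        cal = []
        for m in ("nn", "lm"):
            c = pd.DataFrame(self.metrics["models"][m]["calibration"])
            c.insert(0, "model", m)
            cal.append(c)
        pd.concat(cal).to_csv(outdir / "calibration.csv", index=False)
        (outdir / "cutoff.json").write_text(json.dumps(self.cutoffs, indent=2))
        self.subgroup_aurocs.to_csv(outdir / "subgroup_aurocs.csv", index=False)
        self.model_bundle.save(outdir / "model")


def run_pipeline(bundle: CohortBundle, config: RunConfig | None = None
                 ) -> DonorScreeningResults:
    """Functional wrapper over DonorScreeningModel(...).fit()."""
    return DonorScreeningModel(bundle, config).fit()
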