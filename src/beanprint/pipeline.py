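"""Configuration-driven orchestration of the full discrimination experiment.

One experiment = one label scheme (e.g. Yemen vs. other origins), one
preprocessing chain, and ``n_interactions`` independent balanced databases.
Per interaction the pipeline:

1. draws the sample-grouped test set and the balanced 80/20 train/cv sets,
2. preprocesses every spectrum (per-spectrum transforms — leak-free),
3. runs the top-down PC-count sweep on train/cv and keeps the best PCA-LDA,
4. classifies the training, cross-validation and test spectra,
5. reports accuracy/sensitivity/specificity per set.

Metrics are aggregated to mean ± sd across interactions. All table outputs
are plain CSV; the run log records seeds, chosen component counts and
effective parameters, one structured line per stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import find_peaks

from .dataset import (
    LabelScheme,
    SpectralDataset,
    read_dataset,
    subset_by_labels,
)
from .discriminant import topdown_select
from .evaluate import (
    ClassReport,
    SplitPlan,
    aggregate_interactions,
    evaluate_predictions,
    make_balanced_splits,
)
from .pca import NIPALSPCA
from .preprocess import PreprocessConfig, baseline_offset, preprocess_chain
from .synthetic import SyntheticSpec, generate_dataset


@dataclass
class ExperimentConfig:
    """Everything needed to run one discrimination experiment.

    Exactly one of (``spectra_path`` + ``meta_path``) or ``synthetic`` must
    be given. ``test_sample_counts`` maps class -> number of whole samples
    held out for test; by default 20% of each class's samples (rounded, at
    least 1).
    """

    spectra_path: str | None = None
    meta_path: str | None = None
    synthetic: SyntheticSpec | None = None
    scheme_level: str = "country-set"
    scheme_classes: list[str] | None = None
    scheme_positive: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    lo_pct: float = 95.0
    hi_pct: float = 99.9
    max_models: int = 10
    n_interactions: int = 3
    test_sample_counts: dict[str, int] | None = None
    test_fraction: float = 0.2
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        has_files = self.spectra_path is not None and self.meta_path is not None
        if has_files == (self.synthetic is not None):
            raise ValueError(
                "config needs exactly one of (spectra_path+meta_path) or synthetic"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticSpec(**raw["synthetic"])
        if "preprocess" in raw and raw["preprocess"] is not None:
            pp = raw["preprocess"]
            if "window_nm" in pp and pp["window_nm"] is not None:
                pp["window_nm"] = tuple(pp["window_nm"])
            raw["preprocess"] = PreprocessConfig(**pp)
        return cls(**raw)


@dataclass
class InteractionResult:
    plan: SplitPlan
    chosen_k: int
    explained_pct: float
    reports: dict[str, ClassReport]  # keys: train, cv, test
    model: object = field(repr=False, default=None)  # fitted PCALDA


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    scheme: LabelScheme
    interactions: list[InteractionResult]
    aggregates: dict[str, pd.DataFrame]  # per set: tidy mean ± sd table
    log: list[dict]

    def metrics_frame(self) -> pd.DataFrame:
        frames = []
        for subset, table in self.aggregates.items():
            t = table.copy()
            t.insert(0, "set", subset)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def split_frame(self) -> pd.DataFrame:
        rows = []
        for res in self.interactions:
            tr, cv, te = res.plan.counts()
            rows.append(
                {
                    "interaction": res.plan.interaction_id,
                    "train_spectra": tr,
                    "cv_spectra": cv,
                    "test_spectra": te,
                    "total": tr + cv + te,
                    "chosen_k": res.chosen_k,
                    "explained_pct": round(res.explained_pct, 4),
                }
            )
        return pd.DataFrame(rows)


def _load_inputs(cfg: ExperimentConfig) -> tuple[SpectralDataset, LabelScheme]:
    if cfg.synthetic is not None:
        return generate_dataset(cfg.synthetic)
    ds = read_dataset(cfg.spectra_path, cfg.meta_path)
    scheme = LabelScheme.from_metadata(
        ds,
        level=cfg.scheme_level,
        classes=cfg.scheme_classes,
        positive=cfg.scheme_positive,
    )
    return ds, scheme


def _default_test_counts(
    ds: SpectralDataset, scheme: LabelScheme, fraction: float
) -> dict[str, int]:
    table = ds.sample_table()
    counts = {}
    for c in scheme.classes:
        n = sum(1 for s, cl in scheme.mapping.items() if cl == c and s in table.index)
        counts[c] = max(1, int(round(fraction * n)))
    return counts


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Execute the experiment; write report CSVs if ``cfg.output_dir`` is set."""
    log: list[dict] = []
    ds, scheme = _load_inputs(cfg)
    if cfg.scheme_positive is not None and cfg.synthetic is None:
        positive = cfg.scheme_positive
    elif cfg.scheme_positive is not None:
        positive = cfg.scheme_positive
    else:
        positive = scheme.classes[0] if len(scheme.classes) == 2 else None
    ds_sub, y = subset_by_labels(ds, scheme)
    log.append(
        {
            "stage": "load",
            "n_spectra": int(ds_sub.n_spectra),
            "n_wavelengths": int(ds_sub.n_wavelengths),
            "classes": list(scheme.classes),
            "seed": cfg.seed,
        }
    )

    test_counts = cfg.test_sample_counts or _default_test_counts(
        ds_sub, scheme, cfg.test_fraction
    )
    plans = make_balanced_splits(
        ds_sub, scheme, test_counts, n_interactions=cfg.n_interactions, seed=cfg.seed
    )

    dsp = preprocess_chain(ds_sub, cfg.preprocess)
    log.append(
        {
            "stage": "preprocess",
            "effective_sg_window": cfg.preprocess.effective_window
            if cfg.preprocess.derivative_order == 2
            else None,
            "n_wavelengths_out": int(dsp.n_wavelengths),
        }
    )

    interactions: list[InteractionResult] = []
    for plan in plans:
        try:
            X = dsp.absorbance
            sel = topdown_select(
                X[plan.train_idx],
                y[plan.train_idx],
                X[plan.cv_idx],
                y[plan.cv_idx],
                lo_pct=cfg.lo_pct,
                hi_pct=cfg.hi_pct,
                max_models=cfg.max_models,
                classes=scheme.classes,
            )
            reports = {}
            for name, idx in (
                ("train", plan.train_idx),
                ("cv", plan.cv_idx),
                ("test", plan.test_idx),
            ):
                pred = sel.model.predict(X[idx])
                reports[name] = evaluate_predictions(
                    y[idx], pred, scheme.classes, positive_class=positive
                )
            interactions.append(
                InteractionResult(
                    plan=plan,
                    chosen_k=sel.chosen_k,
                    explained_pct=sel.chosen_explained_pct,
                    reports=reports,
                    model=sel.model,
                )
            )
            log.append(
                {
                    "stage": "model",
                    "interaction": plan.interaction_id,
                    "chosen_k": sel.chosen_k,
                    "explained_pct": round(sel.chosen_explained_pct, 4),
                    "cv_accuracy_pct": round(
                        reports["cv"].accuracy_pct, 4
                    ),
                }
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage 'model' failed in interaction {plan.interaction_id}: {exc}"
            ) from exc

    aggregates = {
        name: aggregate_interactions([r.reports[name] for r in interactions])
        for name in ("train", "cv", "test")
    }
    result = ExperimentResult(cfg, scheme, interactions, aggregates, log)
    if cfg.output_dir is not None:
        _write_reports(result, dsp, y, Path(cfg.output_dir))
    return result


def _write_reports(
    result: ExperimentResult, dsp: SpectralDataset, y: np.ndarray, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.split_frame().to_csv(outdir / "split_table.csv", index=False)
    result.metrics_frame().to_csv(outdir / "metrics.csv", index=False)
    per_interaction = []
    for res in result.interactions:
        for subset, rep in res.reports.items():
            per_interaction.append(
                {
                    "interaction": res.plan.interaction_id,
                    "set": subset,
                    "accuracy_pct": rep.accuracy_pct,
                    "sensitivity_pct": rep.summary_sensitivity_pct,
                    "specificity_pct": rep.summary_specificity_pct,
                }
            )
    pd.DataFrame(per_interaction).to_csv(outdir / "interaction_metrics.csv", index=False)
    tables = export_exploratory(dsp, y, n_components=2)
    for name, frame in tables.items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "run_log.jsonl", "w") as fh:
        for line in result.log:
            fh.write(json.dumps(line) + "\n")


# ---------------------------------------------------------------------------
# exploratory exports


def export_exploratory(
    ds: SpectralDataset,
    labels: np.ndarray,
    raw_ds: SpectralDataset | None = None,
    n_components: int = 2,
    prominence_frac: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Class-mean spectra, 2-PC scores and annotated loadings as DataFrames.

    ``ds`` is the (preprocessed) dataset the PCA runs on; ``raw_ds``, if
    given, supplies the baseline-corrected raw class means. Loadings are
    annotated with the wavelengths of their local |loading| extrema
    (prominence >= ``prominence_frac`` of the maximum magnitude).
    """
    if n_components < 2:
        raise ValueError("exploratory export needs at least 2 components")
    labels = np.asarray(labels, dtype=object)
    classes = pd.unique(labels)
    for c in classes:
        if not np.any(labels == c):
            raise ValueError(f"class {c!r} has no spectra")

    def class_means(d: SpectralDataset) -> pd.DataFrame:
        out = {"wavelength_nm": d.wavelengths_nm}
        for c in classes:
            out[str(c)] = d.absorbance[labels == c].mean(axis=0)
        return pd.DataFrame(out)

    tables: dict[str, pd.DataFrame] = {}
    if raw_ds is not None:
        raw_corrected = SpectralDataset(
            raw_ds.wavelengths_nm, baseline_offset(raw_ds.absorbance), raw_ds.meta
        )
        tables["mean_raw_spectra"] = class_means(raw_corrected)
    tables["mean_transformed_spectra"] = class_means(ds)

    pca = NIPALSPCA(n_components=n_components).fit(ds.absorbance)
    scores = pd.DataFrame(
        pca.scores_, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    scores.insert(0, "spectrum_id", ds.meta["spectrum_id"].to_numpy())
    scores["label"] = labels
    tables["pca_scores"] = scores

    loadings = pd.DataFrame({"wavelength_nm": ds.wavelengths_nm})
    annotations = []
    for i in range(n_components):
        vec = pca.components_[i]
        loadings[f"PC{i + 1}"] = vec
        mag = np.abs(vec)
        peaks, _ = find_peaks(mag, prominence=prominence_frac * mag.max())
        for p in peaks:
            annotations.append(
                {
                    "component": f"PC{i + 1}",
                    "wavelength_nm": float(ds.wavelengths_nm[p]),
                    "loading": float(vec[p]),
                    "explained_pct": float(pca.explained_variance_pct_[i]),
                }
            )
    tables["pca_loadings"] = loadings
    tables["loading_extrema"] = pd.DataFrame(
        annotations, columns=["component", "wavelength_nm", "loading", "explained_pct"]
    )
    return tables
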