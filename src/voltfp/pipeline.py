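"""End-to-end orchestration: simulate -> clean -> extract -> classify ->
segment -> RadViz, with a reproducible config and a run manifest.

A single seed drives all stochastic stages through independently derived
streams, so e.g. changing the cross-validation fold seed does not perturb
data generation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify, extremes, radviz, segment, synthetic
from .errors import ParameterError
from .io import Voltammogram, write_curves
from .synthetic import DEFAULT_OUTLIER_FLAGS, DatasetSpec
from .wavelet import wavelet_attributes


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    seed: int = 1
    n_tissues: int = 9
    n_subjects: int = 8
    n_replicates: int = 5
    outlier_flags: list = field(
        default_factory=lambda: [list(f) for f in DEFAULT_OUTLIER_FLAGS])
    merge_min_distance: int = extremes.DEFAULT_MIN_DISTANCE
    peak_windows: dict = field(
        default_factory=lambda: {k: list(v) for k, v in
                                 extremes.DEFAULT_PEAK_WINDOWS.items()})
    wavelet_level: int = 5
    classification_mode: str = "wavelet32"
    folds: int = 10
    minimal_leaf_size: int = classify.DEFAULT_MINIMAL_LEAF_SIZE
    segment_halfwidth: int = segment.DEFAULT_HALFWIDTH
    outlier_factor: float = 5.0
    cleaning: str = "manual"       # manual (use outlier_flags) | auto
    output_dir: str = "results/run"

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derived_seed(seed: int, stage: str) -> int:
    """Independent per-stage substream seed (stable, < 2^31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage, writing artifacts under ``config.output_dir``.

    Returns the manifest (also written as JSON) with curve counts and
    headline metrics.  Identical configs produce identical artifacts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_digest": config.digest(), "seed": config.seed}
    windows = {k: tuple(v) for k, v in config.peak_windows.items()}

    def _stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return wrap

    # simulate
    spec = DatasetSpec(n_tissues=config.n_tissues,
                       n_subjects=config.n_subjects,
                       n_replicates=config.n_replicates,
                       outlier_flags=[tuple(f) for f in config.outlier_flags],
                       seed=derived_seed(config.seed, "simulate"))
    profiles = _stage("simulate")(synthetic.make_tissue_profiles, spec.seed)
    dataset = _stage("simulate")(synthetic.generate_dataset, spec, profiles)
    write_curves(dataset, out / "dataset.csv", "tidy-csv")
    manifest["curves_generated"] = len(dataset)

    # clean
    manual = [tuple(f) for f in config.outlier_flags] \
        if config.cleaning == "manual" else None
    cleaned, flagged = _stage("clean")(
        extremes.clean_dataset, dataset, config.outlier_factor, manual)
    manifest["curves_flagged"] = len(flagged)
    manifest["curves_analysed"] = len(cleaned)
    with open(out / "cleaning_report.json", "w", encoding="utf-8") as fh:
        json.dump({"generated": len(dataset), "flagged": sorted(
            [list(map(str, k)) for k in flagged]),
            "analysed": len(cleaned)}, fh, indent=2)

    # extract feature tables
    tables = {}
    for mode in classify.MODES:
        tables[mode] = _stage("extract")(
            classify.build_feature_table, cleaned, mode,
            min_distance=config.merge_min_distance, windows=windows,
            wavelet_level=config.wavelet_level)
        tables[mode].frame.to_csv(out / f"features_{mode}.csv", index=False)
        manifest[f"rows_{mode}"] = len(tables[mode])

    # classify
    cv_seed = derived_seed(config.seed, "cv")
    table = tables[config.classification_mode]
    cv = _stage("classify")(classify.cross_validate, table,
                            config.folds, config.minimal_leaf_size, cv_seed)
    cv.to_frame().to_csv(out / "confusion_matrix.csv")
    precision, recall, accuracy = classify.confusion_metrics(cv.confusion)
    with open(out / "cv_metrics.json", "w", encoding="utf-8") as fh:
        json.dump({
            "mode": config.classification_mode,
            "accuracy_mean_pct": cv.accuracy_mean,
            "accuracy_sd_pct": cv.accuracy_sd,
            "pooled_accuracy_pct": accuracy,
            "precision_pct": dict(zip(cv.classes, precision.round(2))),
            "recall_pct": dict(zip(cv.classes, recall.round(2))),
        }, fh, indent=2, default=float)
    manifest["cv_accuracy_mean_pct"] = round(cv.accuracy_mean, 2)
    manifest["cv_accuracy_sd_pct"] = round(cv.accuracy_sd, 2)
    model = _stage("classify")(classify.induce_tree, table,
                               config.minimal_leaf_size)
    (out / "tree.txt").write_text(model.render(), encoding="utf-8")

    # segment families
    families, fits = _stage("segment")(
        segment.fit_families, cleaned,
        min_distance=config.merge_min_distance, windows=windows,
        halfwidth=config.segment_halfwidth)
    pd.DataFrame([dataclasses.asdict(f) for f in fits]).to_csv(
        out / "segment_fits.csv", index=False)
    fam_frame = pd.DataFrame([{
        "tissue": f.tissue, "alpha": f.alpha, "beta": f.beta,
        "intersection_x": f.intersection[0], "intersection_y": f.intersection[1],
        "r2": f.r2, "n_fits": f.n_fits} for f in families])
    fam_frame.to_csv(out / "tissue_families.csv", index=False)
    manifest["tissues_with_family"] = len(families)
    r = segment.correlate_alpha_with_level(
        families, synthetic.MT_LEVELS)
    manifest["corr_neg_alpha_mt_pct"] = round(r, 1)

    # radviz
    pts = _stage("radviz")(radviz.project_wavelet_subset, tables["wavelet32"])
    pts.to_csv(out / "radviz_points.csv", index=False)

    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def classify_single_curve(model: classify.DecisionTreeModel,
                          curve: Voltammogram, wavelet_level: int = 5) -> str:
    """Predict the tissue of one curve with a wavelet32-trained tree."""
    att = wavelet_attributes(curve, wavelet_level)
    names = att.names()
    if names != model.feature_names:
        raise ParameterError(
            "model was not trained on these wavelet attributes")
    row = pd.DataFrame([dict(zip(names, att.coefs))])
    return str(model.predict(row)[0])
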