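"""End-to-end orchestration: simulate -> calibrate -> preprocess -> split
-> train (full-spectrum and 10-PC SVC) -> evaluate -> map.

Everything is driven by a :class:`PipelineConfig` (serializable to a flat
YAML file) and a master seed; given both, the run is bit-reproducible.
Artifacts (manifest, preprocessed spectra, split assignment, grid-search
tables, serialized models, metrics, map fractions and a few rendered
maps) are written under the configured output directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics, evaluation, preprocessing, svc, synthetic
from .hypercube import calibrate_reflectance
from .synthetic import Scene, SceneParams, TREATMENT_LABELS, TREATMENT_NAMES

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "PipelineError"]

FEATURE_MODES = ("full_spectrum", "pc10")
SPLIT_MODES = ("4:1:1", "ks_2to1")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All pipeline constants in one place.

    Defaults are the analysis constants of the study design: 434-953 nm
    band window, Daubechies-9 level-3 denoising, 7-point moving average,
    10 PCA features, per-class 4:1:1 splitting and a 17x17 log-decade
    (C, gamma) grid (N = -8..8).
    """

    scene: SceneParams = field(default_factory=SceneParams)
    n_per_group: int = 40
    band_lo_nm: float = 434.0
    band_hi_nm: float = 953.0
    wavelet: str = "db9"
    wavelet_level: int = 3
    ma_window: int = 7
    n_components: int = 10
    split_mode: str = "4:1:1"
    grid_n_min: int = -8
    grid_n_max: int = 8
    svc_tol: float = 1e-3
    seed: int = 1
    outdir: str = "hsistress_run"
    write_scenes: bool = False
    n_map_pngs: int = 3

    def __post_init__(self) -> None:
        if self.split_mode not in SPLIT_MODES:
            raise ValueError(f"split_mode must be one of {SPLIT_MODES}")
        if self.grid_n_min > self.grid_n_max:
            raise ValueError("grid_n_min must not exceed grid_n_max")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        scene_d = d.pop("scene", {}) or {}
        # YAML maps treatment keys to plain ints already
        for key in ("visible_shift", "nir_shift"):
            if key in scene_d:
                scene_d[key] = {int(k): float(v) for k, v in scene_d[key].items()}
        return cls(scene=SceneParams(**scene_d), **d)


@dataclass
class PipelineReport:
    """Summary of one pipeline run."""

    config: PipelineConfig
    metrics: pd.DataFrame          # mode x subset accuracy/kappa + counts
    grid_tables: dict              # feature mode -> grid DataFrame
    chosen_params: dict            # feature mode -> (C, gamma)
    pixel_summary: pd.DataFrame
    majority_match_fraction: float
    n_features: dict               # feature mode -> SVC input dimension
    outdir: Path


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig) -> list[Scene]:
    return synthetic.simulate_dataset(config.n_per_group, config.scene,
                                      seed=config.seed)


@_stage("preprocess")
def _preprocess(config: PipelineConfig, scenes: list[Scene]):
    """Calibrate, segment and reduce every scene to its mean sample spectrum.

    Returns (X, labels, wavelengths, masks, reflectance cubes); the cubes
    and masks are reused by the mapping stage.
    """
    spectra, labels, masks, cubes = [], [], [], []
    wavelengths = None
    for k, scene in enumerate(scenes):
        cube = calibrate_reflectance(scene.raw, scene.dark, scene.white)
        mask = preprocessing.segment_plant(cube)
        px = preprocessing.extract_pixel_spectra(
            cube, mask, sample_id=f"scene{k:03d}", label=scene.label)
        px = preprocessing.preprocess_pixel_spectra(
            px, config.band_lo_nm, config.band_hi_nm, config.wavelet,
            config.wavelet_level, config.ma_window)
        spectra.append(preprocessing.mean_spectrum(px))
        labels.append(scene.label)
        masks.append(mask)
        cubes.append(cube)
        wavelengths = px.wavelengths
    return (np.array(spectra), np.array(labels), wavelengths, masks, cubes)


@_stage("split")
def _split(config: PipelineConfig, X: np.ndarray, labels: np.ndarray
           ) -> chemometrics.DatasetSplit:
    if config.split_mode == "4:1:1":
        return chemometrics.split_4_1_1(labels, X)
    cal, pred = chemometrics.kennard_stone_split(X, 2 / 3)
    # 2:1 calibration/prediction: score model selection on the training set
    return chemometrics.DatasetSplit(cal, np.array([], dtype=int), pred)


@_stage("train")
def _train(config: PipelineConfig, X: np.ndarray, labels: np.ndarray,
           split: chemometrics.DatasetSplit):
    grid = svc.default_grid(config.grid_n_min, config.grid_n_max)
    tr, va = split.train, split.validation
    if len(va) == 0:  # ks_2to1 mode has no held-out validation set
        va = tr
    results, features = {}, {}
    pca = chemometrics.SpectralPCA(n_components=config.n_components
                                   ).fit(X[split.train])
    features["full_spectrum"] = X
    features["pc10"] = pca.transform(X)
    for mode in FEATURE_MODES:
        F = features[mode]
        results[mode] = svc.grid_search((F[tr], labels[tr]),
                                        (F[va], labels[va]),
                                        grid, tol=config.svc_tol)
    return results, features, pca


@_stage("evaluate")
def _evaluate(labels: np.ndarray, split: chemometrics.DatasetSplit,
              results: dict, features: dict) -> pd.DataFrame:
    rows = []
    subsets = {"train": split.train, "validation": split.validation,
               "test": split.test}
    for mode, res in results.items():
        for subset, idx in subsets.items():
            if len(idx) == 0:
                continue
            pred = res.best_model.predict(features[mode][idx])
            cm = evaluation.confusion_matrix(labels[idx], pred)
            row = {"feature_mode": mode, "subset": subset, "n": cm.total,
                   "accuracy": evaluation.accuracy(cm),
                   "kappa": evaluation.cohen_kappa(cm)}
            for i, a in enumerate(TREATMENT_LABELS):
                for j, p in enumerate(TREATMENT_LABELS):
                    row[f"n_{TREATMENT_NAMES[a]}_as_{TREATMENT_NAMES[p]}"] = \
                        int(cm.counts[i, j])
            rows.append(row)
    return pd.DataFrame(rows)


@_stage("map")
def _map(config: PipelineConfig, scenes: list[Scene], masks, cubes,
         pca, model):
    maps = []
    for scene, mask, cube in zip(scenes, masks, cubes):
        maps.append(evaluation.prediction_map(
            cube, mask, pca, model, true_label=scene.label,
            lo_nm=config.band_lo_nm, hi_nm=config.band_hi_nm,
            wavelet=config.wavelet, level=config.wavelet_level,
            window=config.ma_window))
    match = float(np.mean([m.majority_label == m.true_label for m in maps]))
    by_group = {lab: [m for m in maps if m.true_label == lab]
                for lab in TREATMENT_LABELS}
    summary = evaluation.pixel_summary(by_group)
    return maps, match, summary


def _write_map_png(pmap: evaluation.PredictionMap, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import colors, pyplot as plt

    cmap = colors.ListedColormap(["black", "#2ca02c", "#d62728", "#1f77b4"])
    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(pmap.label_image, cmap=cmap, vmin=0, vmax=3,
              interpolation="nearest")
    ax.set_title(f"true: {TREATMENT_NAMES.get(pmap.true_label, '?')}")
    ax.axis("off")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage and write the artifact set; see module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    scenes = _simulate(config)
    manifest = pd.DataFrame({
        "scene_id": [f"scene{k:03d}" for k in range(len(scenes))],
        "label": [s.label for s in scenes],
        "treatment": [TREATMENT_NAMES[s.label] for s in scenes],
        "seed": [s.seed for s in scenes],
        "path": "",
    })
    if config.write_scenes:
        from .hypercube import write_envi_cube
        scene_dir = outdir / "scenes"
        scene_dir.mkdir(exist_ok=True)
        paths = []
        for k, s in enumerate(scenes):
            base = scene_dir / f"scene{k:03d}"
            write_envi_cube(s.raw, base, "bil")
            np.savetxt(f"{base}.dark.txt", s.dark.data[0])
            np.savetxt(f"{base}.white.txt", s.white.data[0])
            np.savetxt(f"{base}.mask.txt", s.truth_mask.astype(int), fmt="%d")
            paths.append(str(base.with_suffix(".hdr")))
        manifest["path"] = paths
    manifest.to_csv(outdir / "manifest.csv", index=False)

    X, labels, wavelengths, masks, cubes = _preprocess(config, scenes)
    spectra_df = pd.DataFrame(X, columns=[f"{w:.2f}" for w in wavelengths])
    spectra_df.insert(0, "label", labels)
    spectra_df.insert(0, "sample_id", manifest["scene_id"])
    spectra_df.to_csv(outdir / "spectra.csv", index=False)

    split = _split(config, X, labels)
    subset_of = {}
    for name, idx in (("train", split.train), ("validation", split.validation),
                      ("test", split.test)):
        for i in idx:
            subset_of[int(i)] = name
    pd.DataFrame({
        "sample_id": manifest["scene_id"],
        "subset": [subset_of[i] for i in range(len(labels))],
    }).to_csv(outdir / "splits.csv", index=False)

    results, features, pca = _train(config, X, labels, split)
    chemometrics.save_pca(pca, outdir / "pca.txt")
    chosen = {}
    n_features = {}
    for mode, res in results.items():
        res.table.to_csv(outdir / f"grid_{mode}.csv", index=False)
        svc.save_svc(res.best_model, outdir / f"model_{mode}.txt")
        chosen[mode] = (res.best_C, res.best_gamma)
        n_features[mode] = res.best_model.n_features_in_

    metrics = _evaluate(labels, split, results, features)
    metrics.to_csv(outdir / "metrics.csv", index=False)

    maps, match, summary = _map(config, scenes, masks, cubes, pca,
                                results["pc10"].best_model)
    frac_rows = []
    for sid, m in zip(manifest["scene_id"], maps):
        frac_rows.append({"scene_id": sid, "true_label": m.true_label,
                          **{f"frac_{TREATMENT_NAMES[k]}": v
                             for k, v in m.fractions.items()},
                          "majority_label": m.majority_label})
    pd.DataFrame(frac_rows).to_csv(outdir / "map_fractions.csv", index=False)
    summary.to_csv(outdir / "pixel_summary.csv", index=False)
    for k in range(min(config.n_map_pngs, len(maps))):
        _write_map_png(maps[k], outdir / f"map_scene{k:03d}.png")

    # score-image panel of the first scene (PC1..PC10 pseudo color)
    px0 = preprocessing.preprocess_pixel_spectra(
        preprocessing.extract_pixel_spectra(cubes[0], masks[0]),
        config.band_lo_nm, config.band_hi_nm, config.wavelet,
        config.wavelet_level, config.ma_window)
    chemometrics.render_score_images(px0, pca, masks[0].shape,
                                     outdir / "score_images_scene000.png")

    return PipelineReport(config=config, metrics=metrics,
                          grid_tables={m: r.table for m, r in results.items()},
                          chosen_params=chosen, pixel_summary=summary,
                          majority_match_fraction=match,
                          n_features=n_features, outdir=outdir)
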