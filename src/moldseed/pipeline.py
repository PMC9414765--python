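"""End-to-end orchestration: simulate/load -> preprocess -> select bands ->
optimize -> train -> evaluate, with one global seed fanned out to stages.

Three model arms are supported on a shared stratified split: a plain
random forest (n_estimators=5, max_features=3), the plain sparrow-search
tuned forest, and the elite-reverse variant.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.model_selection import train_test_split

from . import preprocessing
from .classify import (
    EvaluationReport,
    RfHyperparams,
    evaluate,
    make_fitness,
    position_to_params,
    train_final,
)
from .feature_selection import (
    cars_select,
    rf_band_importance,
    select_positive_importance,
)
from .jyssa import JyssaConfig, optimize
from .segmentation import SeedSpectraTable
from .synthetic_data import SyntheticConfig, generate_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run", "compare_models", "BASELINE_PARAMS"]

BASELINE_PARAMS = RfHyperparams(n_trees=5, n_features_per_split=3)

# Stage seed offsets: lets any stage be re-run in isolation reproducibly.
_SEED_OFFSETS = {
    "simulate": 0, "split": 1, "select": 2, "ssa": 3, "jyssa": 4,
    "train": 5, "inner_cv": 6,
}


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    spectra_csv: str | None = None          # if None, simulate
    synthetic: dict = field(default_factory=dict)
    preprocess: str = "none"                # none|snv|msc|smooth|d1|d2
    window: int = 11
    polyorder: int = 2
    band_mode: str = "full"                 # full|rfimp|cars
    algorithms: tuple[str, ...] = ("rf", "ssa-rf", "jyssa-rf")
    test_fraction: float = 0.2
    pop_size: int = 10
    max_iter: int = 10
    max_trees: int = 100
    cv_folds: int = 5
    importance_trees: int = 200
    cars_runs: int = 50

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.algorithms = tuple(cfg.algorithms)
        return cfg


def _stage_seed(seed: int, stage: str) -> int:
    return seed * 10007 + _SEED_OFFSETS[stage]


def _apply_preprocess(cfg: PipelineConfig, X: np.ndarray, wl: np.ndarray) -> np.ndarray:
    if cfg.preprocess == "none":
        return X
    if cfg.preprocess == "snv":
        return preprocessing.snv(X)
    if cfg.preprocess == "msc":
        return preprocessing.msc(X)[0]
    if cfg.preprocess == "smooth":
        return preprocessing.smooth(X, cfg.window, cfg.polyorder)
    if cfg.preprocess in ("d1", "d2"):
        order = 1 if cfg.preprocess == "d1" else 2
        return preprocessing.derivative(X, wl, order, cfg.window, cfg.polyorder)
    raise ValueError(f"unknown preprocess method {cfg.preprocess!r}")


def _select_bands(
    cfg: PipelineConfig, X: np.ndarray, y: np.ndarray, wl: np.ndarray
) -> np.ndarray:
    if cfg.band_mode == "full":
        return np.arange(X.shape[1])
    seed = _stage_seed(cfg.seed, "select")
    if cfg.band_mode == "rfimp":
        table = SeedSpectraTable(
            seed_ids=np.arange(1, len(y) + 1), spectra=X,
            wavelengths_nm=wl, class_labels=y,
        )
        scores = rf_band_importance(table, n_trees=cfg.importance_trees, seed=seed)
        bands = select_positive_importance(scores, threshold=0.0)
        if bands.size < 2:
            raise ValueError("importance screen kept fewer than 2 bands")
        return bands
    if cfg.band_mode == "cars":
        result = cars_select(X, y.astype(float), n_runs=cfg.cars_runs, seed=seed)
        return result.selected
    raise ValueError(f"unknown band mode {cfg.band_mode!r}")


def _optimize_arm(
    algo: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: PipelineConfig,
) -> tuple[RfHyperparams, np.ndarray]:
    """Tune the forest for one optimizer arm; returns params + fg history."""
    stage = "jyssa" if algo == "jyssa-rf" else "ssa"
    fitness = make_fitness(
        X_train, y_train,
        cv_folds=cfg.cv_folds,
        inner_seed=_stage_seed(cfg.seed, "inner_cv"),
        max_trees=cfg.max_trees,
    )
    jcfg = JyssaConfig(
        lower=[1.0, 1.0],
        upper=[float(cfg.max_trees), float(X_train.shape[1])],
        pop_size=cfg.pop_size,
        max_iter=cfg.max_iter,
        rng_seed=_stage_seed(cfg.seed, stage),
        elite_reverse_enabled=(algo == "jyssa-rf"),
    )
    result = optimize(fitness, jcfg)
    params = position_to_params(result.x, n_bands=X_train.shape[1],
                                max_trees=cfg.max_trees)
    return params, result.history


def compare_models(
    X: np.ndarray,
    y: np.ndarray,
    cfg: PipelineConfig,
) -> dict[str, dict]:
    """Train and evaluate the requested arms on one shared stratified split."""
    X_train, X_test, y_train, y_test = train_test_split(
        X, y,
        test_size=cfg.test_fraction,
        random_state=_stage_seed(cfg.seed, "split"),
        stratify=y,
    )
    out: dict[str, dict] = {}
    for algo in cfg.algorithms:
        t0 = time.perf_counter()
        if algo == "rf":
            params, history = BASELINE_PARAMS, np.array([])
        elif algo in ("ssa-rf", "jyssa-rf"):
            params, history = _optimize_arm(algo, X_train, y_train, cfg)
        else:
            raise ValueError(f"unknown algorithm {algo!r}")
        clf = train_final(X_train, y_train, params,
                          seed=_stage_seed(cfg.seed, "train"))
        report = evaluate(y_test, clf.predict(X_test))
        logger.info(
            "arm=%s params=(%d,%d) accuracy=%.3f elapsed=%.1fs",
            algo, params.n_trees, params.n_features_per_split,
            report.accuracy, time.perf_counter() - t0,
        )
        out[algo] = {"params": params, "report": report, "history": history}
    return out


def _report_to_dict(report: EvaluationReport) -> dict:
    return {
        "labels": report.labels.tolist(),
        "confusion": report.confusion.tolist(),
        "precision": [round(p, 6) for p in report.precision],
        "recall": [round(r, 6) for r in report.recall],
        "sample_size": report.support.tolist(),
        "accuracy": round(report.accuracy, 6),
    }


def run(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and write artifacts; returns the manifest."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(cfg)
    cfg_dict["algorithms"] = list(cfg.algorithms)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:16]

    if cfg.spectra_csv is not None:
        table = SeedSpectraTable.from_csv(cfg.spectra_csv)
        if table.class_labels is None:
            raise ValueError("input spectra table carries no class labels")
        X, y, wl = table.spectra, table.class_labels, table.wavelengths_nm
    else:
        syn = SyntheticConfig(
            **{**cfg.synthetic, "rng_seed": _stage_seed(cfg.seed, "simulate")}
        )
        X, y, wl = generate_table(syn)
    logger.info("stage=load n=%d bands=%d", X.shape[0], X.shape[1])

    X = _apply_preprocess(cfg, X, wl)
    bands = _select_bands(cfg, X, y, wl)
    logger.info("stage=select mode=%s kept=%d/%d", cfg.band_mode, bands.size, X.shape[1])
    Xb = X[:, bands]

    spectra_path = out_dir / "spectra.csv"
    SeedSpectraTable(
        seed_ids=np.arange(1, len(y) + 1), spectra=X,
        wavelengths_nm=wl, class_labels=y,
    ).to_csv(spectra_path)
    bands_path = out_dir / "bands.json"
    bands_path.write_text(json.dumps(
        {"mode": cfg.band_mode, "bands": bands.tolist(),
         "wavelengths_nm": wl[bands].tolist()}, indent=2))

    arms = compare_models(Xb, y, cfg)
    manifest: dict = {
        "config_hash": cfg_hash,
        "seed": cfg.seed,
        "stage_seeds": {k: _stage_seed(cfg.seed, k) for k in _SEED_OFFSETS},
        "n_rows": int(X.shape[0]),
        "n_bands_full": int(X.shape[1]),
        "n_bands_used": int(bands.size),
        "artifacts": {"spectra": str(spectra_path), "bands": str(bands_path)},
        "models": {},
    }
    for algo, arm in arms.items():
        tag = algo.replace("-", "_")
        report_path = out_dir / f"report_{tag}.json"
        report_path.write_text(json.dumps({
            "config_hash": cfg_hash,
            "seed": cfg.seed,
            "params": asdict(arm["params"]),
            **_report_to_dict(arm["report"]),
        }, indent=2))
        if len(arm["history"]):
            hist_path = out_dir / f"history_{tag}.csv"
            with open(hist_path, "w") as fh:
                fh.write("iteration,fg\n")
                for i, fg in enumerate(arm["history"], start=1):
                    fh.write(f"{i},{fg!r}\n")
            manifest["artifacts"][f"history_{tag}"] = str(hist_path)
        manifest["models"][algo] = {
            "params": asdict(arm["params"]),
            "accuracy": round(arm["report"].accuracy, 6),
            "report": str(report_path),
        }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
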