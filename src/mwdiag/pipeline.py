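"""End-to-end orchestration: simulate -> process (TW/FE) -> diagnose -> report.

``run_pipeline`` ties the stages together under a single ``RunConfig``:
generate a scan set, remove the antenna artefact, build the observation
table for the chosen processing mode (TW = 60 aligned time samples,
FE = 30 features of the raw record, TW+FE = 30 features of the windowed
signature), run scan-level nested cross-validation with the requested
EA/MA/EAC model, and write prediction tables plus a JSON report.  Every
output carries the config hash, and all randomness flows from
``RunConfig.seed``, so a rerun with the same config reproduces the outputs
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnosis import CVResult, nested_cv
from .errors import ConfigError
from .evaluate import optimal_threshold, roc_curve
from .features import feature_matrix
from .geometry import ChannelRanking, rank_channels_by_proximity
from .io import config_hash, save_scanset, write_table
from .simulate import DesignSpec, GLANDULAR_PRESETS, ScanSet, generate_dataset
from .windowing import remove_artifact, tumour_signature

logger = logging.getLogger(__name__)

MODES = ("TW", "FE", "TW+FE")
MODEL_KINDS = ("EA", "MA", "EAC")

__all__ = [
    "RunConfig",
    "RunResult",
    "run_pipeline",
    "signatures_for_scanset",
    "build_observation_table",
    "scan_rankings",
]


@dataclass
class RunConfig:
    """Complete, hashable description of one pipeline run."""

    mode: str = "TW+FE"
    model: str = "EAC"
    angle: float = 30.0
    w: int | None = None          # None = all available channels in the vote
    k: int = 5
    seed: int = 0
    budget: int = 10
    threshold: float = 0.5
    search_space: dict | None = None
    # generator parameters
    n_breasts: int = 1
    n_tumours: int = 24
    n_positions: int = 5
    glandular_fractions: tuple[float, ...] = (0.05,)
    noise_sigma: float = 0.05
    n_samples: int = 2560
    s_benign: tuple[float, float] = (0.0, 0.25)
    s_malignant: tuple[float, float] = (0.50, 0.90)
    # output
    out_dir: str | None = None
    save_scans: bool = False

    def hash(self) -> str:
        """Config hash over the scientific fields (output paths excluded)."""
        payload = {
            k: v for k, v in dataclasses.asdict(self).items()
            if k not in ("out_dir", "save_scans")
        }
        return config_hash(payload)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.model not in MODEL_KINDS:
            raise ConfigError(f"model must be one of {MODEL_KINDS}, got {self.model!r}")
        if self.model == "EA" and self.angle not in range(0, 181):
            pass  # angle validity is checked against the array's angles at run time
        if self.k < 2:
            raise ConfigError(f"k must be >= 2, got {self.k}")


@dataclass
class RunResult:
    """Bundle returned by :func:`run_pipeline`."""

    config: RunConfig
    cfg_hash: str
    scanset: ScanSet
    table: pd.DataFrame
    cv: CVResult
    pooled_auc: float
    best_threshold: float
    timings: dict = field(default_factory=dict)


def signatures_for_scanset(
    scanset: ScanSet, channel_indices: list[int] | None = None
) -> np.ndarray:
    """Windowed 60-sample signatures, shape (n_scans, n_channels, 60)."""
    idx = list(range(len(scanset.channels))) if channel_indices is None else channel_indices
    out = np.empty((len(scanset.scans), len(idx), 60))
    for i, scan in enumerate(scanset.scans):
        media = scan.breast.media(centre=scanset.array.centre)
        for k, j in enumerate(idx):
            sig = tumour_signature(
                scan.signals[j], scanset.references[j], scan.tumour.position,
                scanset.channels[j], scanset.array, media, scanset.pulse,
                fs=scanset.fs, scan_id=scan.scan_id,
            )
            out[i, k] = sig.samples
    return out


def build_observation_table(
    scanset: ScanSet, mode: str, angles: list[float] | None = None
) -> pd.DataFrame:
    """One row per (scan, channel): meta columns plus the mode's data columns.

    TW rows are the 60 aligned time samples (columns ts00..ts59); FE rows are
    the 30 features of the artefact-removed full record (columns f01..f30);
    TW+FE rows are the 30 features of the windowed signature.  ``angles``
    optionally restricts processing to channels at those channel angles
    (cheaper when only a narrow EA/MA model will consume the table).
    """
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {mode!r}")
    keep = [
        j for j, ch in enumerate(scanset.channels)
        if angles is None or ch.angle_z in angles
    ]
    channels = [scanset.channels[j] for j in keep]
    meta = pd.DataFrame([
        {
            "scan_id": scan.scan_id,
            "tx": ch.tx,
            "rx": ch.rx,
            "angle": ch.angle_z,
            "label": scan.label,
        }
        for scan in scanset.scans
        for ch in channels
    ])
    if mode in ("TW", "TW+FE"):
        sigs = signatures_for_scanset(scanset, channel_indices=keep)
        if mode == "TW":
            data = sigs.reshape(-1, 60)
            cols = [f"ts{i:02d}" for i in range(60)]
        else:
            data = feature_matrix(sigs.reshape(-1, 60), fs=30.0)
            cols = [f"f{i:02d}" for i in range(1, 31)]
    else:  # FE on the raw artefact-removed records
        raw = np.concatenate([
            remove_artifact(scan.signals[keep], scanset.references[keep])
            for scan in scanset.scans
        ])
        data = feature_matrix(raw, fs=scanset.fs)
        cols = [f"f{i:02d}" for i in range(1, 31)]
    return pd.concat([meta, pd.DataFrame(data, columns=cols)], axis=1)


def scan_rankings(scanset: ScanSet) -> dict[str, ChannelRanking]:
    """Proximity ranking of all channels for every scan's true tumour position."""
    return {
        scan.scan_id: rank_channels_by_proximity(
            scanset.channels, scan.tumour.position, scanset.array
        )
        for scan in scanset.scans
    }


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full simulate -> process -> diagnose -> evaluate chain."""
    config.validate()
    cfg_hash = config.hash()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    scanset = generate_dataset(
        design=DesignSpec(config.n_breasts, config.n_tumours, config.n_positions),
        glandular_fractions=config.glandular_fractions or GLANDULAR_PRESETS,
        seed=config.seed,
        n_samples=config.n_samples,
        noise_sigma=config.noise_sigma,
        s_benign=config.s_benign,
        s_malignant=config.s_malignant,
    )
    timings["simulate_s"] = time.perf_counter() - t0
    logger.info("stage=simulate seed=%d scans=%d elapsed=%.1fs",
                config.seed, len(scanset.scans), timings["simulate_s"])

    t0 = time.perf_counter()
    table = build_observation_table(scanset, config.mode)
    rankings = scan_rankings(scanset)
    timings["process_s"] = time.perf_counter() - t0
    logger.info("stage=process mode=%s rows=%d elapsed=%.1fs",
                config.mode, len(table), timings["process_s"])

    t0 = time.perf_counter()
    cv = nested_cv(
        table, rankings, kind=config.model, angle=config.angle, k=config.k,
        seed=config.seed, search_space=config.search_space, budget=config.budget,
        w=config.w, threshold=config.threshold,
    )
    timings["diagnose_s"] = time.perf_counter() - t0
    logger.info("stage=diagnose model=%s angle=%g mean_auc=%.3f elapsed=%.1fs",
                config.model, config.angle, cv.mean_auc, timings["diagnose_s"])

    pooled = roc_curve(cv.predictions["fused_score"], cv.predictions["true_label"])
    best_thr = optimal_threshold(pooled)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.save_scans:
            save_scanset(out / "scans.h5", scanset)
        write_table(out / f"features_{config.mode.replace('+', '_')}.csv", table, cfg_hash)
        write_table(out / "predictions.csv", cv.predictions, cfg_hash)
        report = {
            "config": dataclasses.asdict(config),
            "config_hash": cfg_hash,
            "fold_aucs": cv.fold_aucs,
            "mean_auc": cv.mean_auc,
            "pooled_auc": pooled.auc,
            "optimal_threshold": best_thr,
            "fold_configs": [dataclasses.asdict(c) for c in cv.fold_configs],
            "timings": timings,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)

    return RunResult(
        config=config, cfg_hash=cfg_hash, scanset=scanset, table=table, cv=cv,
        pooled_auc=pooled.auc, best_threshold=best_thr, timings=timings,
    )
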