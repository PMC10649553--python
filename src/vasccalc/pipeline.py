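"""End-to-end orchestration: phantom cohort → training → segmentation →
calcium scoring → evaluation, with a run manifest for reproducibility.

Every summary number the pipeline reports is recomputable from persisted
per-slice artifacts (per-slice Dice and calcified-voxel CSVs); the
manifest records configs, seeds and package version so a rerun with the
same inputs reproduces identical deterministic outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .augment import AugmentConfig, augment_dataset
from .calcscore import ScoreConfig, calcium_score
from .metrics import ape, fit_line, mape, per_slice_dice
from .model import ModelConfig, predict_volume, save_model
from .phantom import make_cohort
from .train import TrainingConfig, train_on_slices
from .volume import write_mask, write_volume

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Stage configuration for a full phantom-driven run."""

    n_train_patients: int = 6
    n_test_patients: int = 8
    slices_per_patient: int = 8
    image_size: int = 64
    noise_sigma: float = 5.0
    augment: bool = False
    augment_multiplicity: int = 3
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    scoring: ScoreConfig = field(default_factory=ScoreConfig)
    seed: int = 0
    save_volumes: bool = False
    make_plots: bool = True


@dataclass
class RunManifest:
    command: str
    seed: int
    config: dict
    outputs: dict
    package_version: str = __version__
    started: str = ""
    finished: str = ""

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=1, default=str))
        return path


def _stage(name):
    """Tag exceptions with the pipeline stage that raised them."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Run the full workflow and persist per-slice and summary artifacts.

    Writes: training history CSV, per-patient Dice table, per-slice Dice
    CSV, per-slice calcium CSV, per-patient score comparison (true vs
    predicted volume with APE), a regression summary JSON, the trained
    model, and optional scatter/bar plots.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    seed = config.seed

    with _stage("phantom"):
        train_cohort = make_cohort(
            config.n_train_patients, seed=seed,
            image_size=config.image_size, n_slices=config.slices_per_patient,
            noise_sigma=config.noise_sigma,
        )
        test_cohort = make_cohort(
            config.n_test_patients, seed=seed + 1000,
            image_size=config.image_size, n_slices=config.slices_per_patient,
            noise_sigma=config.noise_sigma,
        )
        for i, (vol, _) in enumerate(test_cohort):
            vol.patient_id = f"T{i:02d}"
        if config.save_volumes:
            vol_dir = out_dir / "volumes"
            vol_dir.mkdir(exist_ok=True)
            for vol, truth in train_cohort + test_cohort:
                write_volume(vol, vol_dir / f"{vol.patient_id}.nii.gz")
                write_mask(truth.vessel_mask, vol_dir / f"{vol.patient_id}_vessel.nii.gz")

    with _stage("train"):
        # last training patient is the validation hold-out
        fit_pairs, val_pair = train_cohort[:-1], train_cohort[-1]
        xi = np.concatenate([v.voxels for v, _ in fit_pairs]).astype(np.uint8)
        yi = np.concatenate([t.vessel_mask.voxels for _, t in fit_pairs])
        if config.augment:
            aug_cfg = AugmentConfig(seed=seed)
            xi, yi = augment_dataset(xi, yi, aug_cfg, config.augment_multiplicity)
        xv = val_pair[0].voxels.astype(np.uint8)
        yv = val_pair[1].vessel_mask.voxels
        model, history = train_on_slices(xi, yi, xv, yv, config.model, config.training)
        pd.DataFrame(history).to_csv(out_dir / "history.csv", index=False)
        save_model(model, out_dir / "model.npz")

    with _stage("evaluate"):
        dice_rows, slice_rows = [], []
        for vol, truth in test_cohort:
            _, pred = predict_volume(model, vol, config.training.binarize_threshold)
            d = per_slice_dice(pred.voxels, truth.vessel_mask.voxels)
            for s, val in enumerate(d):
                slice_rows.append(
                    {"patient_id": vol.patient_id, "slice": s, "dice": float(val)}
                )
            dice_rows.append({"patient_id": vol.patient_id, "mean_dice": float(d.mean())})
        slice_dice = pd.DataFrame(slice_rows)
        patient_dice = pd.DataFrame(dice_rows)
        slice_dice.to_csv(out_dir / "slice_dice.csv", index=False)
        patient_dice.to_csv(out_dir / "patient_dice.csv", index=False)

    with _stage("score"):
        score_rows, calc_slices = [], []
        for vol, truth in test_cohort:
            _, pred = predict_volume(model, vol, config.training.binarize_threshold)
            report = calcium_score(vol, pred, config.scoring)
            calc_slices.append(report.to_frame())
            truth_vol = truth.true_calcium_volume
            row = {
                "patient_id": vol.patient_id,
                "true_volume_mm3": truth_vol,
                "predicted_volume_mm3": report.total_volume_mm3,
            }
            if truth_vol > 0:
                row["ape_pct"] = ape(truth_vol, report.total_volume_mm3)
            score_rows.append(row)
        scores = pd.DataFrame(score_rows)
        scores.to_csv(out_dir / "patient_scores.csv", index=False)
        pd.concat(calc_slices).to_csv(out_dir / "slice_calcium.csv", index=False)

        yt = scores["true_volume_mm3"].to_numpy()
        yp = scores["predicted_volume_mm3"].to_numpy()
        summary = {
            "mean_dice": float(patient_dice["mean_dice"].mean()),
            "mape_pct": mape(yt, yp) if np.all(yt > 0) else None,
            "n_test_patients": int(len(scores)),
        }
        if len(scores) >= 2 and yt.std() > 0:
            line = fit_line(yt, yp)
            summary["regression"] = {
                "slope": line.slope,
                "intercept": line.intercept,
                "r_squared": line.r_squared,
            }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))

    if config.make_plots:
        with _stage("plots"):
            _write_plots(out_dir, patient_dice, scores)

    manifest = RunManifest(
        command="run",
        seed=seed,
        config={
            "pipeline": {
                k: v for k, v in config.__dict__.items()
                if not hasattr(v, "__dict__") or isinstance(v, (tuple, list))
            },
            "model": config.model.__dict__ if hasattr(config.model, "__dict__") else {},
            "training": config.training.__dict__,
            "scoring": config.scoring.__dict__,
        },
        outputs={
            "summary": str(out_dir / "summary.json"),
            "patient_dice": str(out_dir / "patient_dice.csv"),
            "patient_scores": str(out_dir / "patient_scores.csv"),
        },
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out_dir)
    return manifest


def _write_plots(out_dir: Path, patient_dice: pd.DataFrame, scores: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(patient_dice["patient_id"], patient_dice["mean_dice"])
    ax.set_ylabel("mean per-slice Dice")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(out_dir / "patient_dice.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    yt = scores["true_volume_mm3"]
    yp = scores["predicted_volume_mm3"]
    ax.scatter(yt, yp)
    if len(scores) >= 2 and yt.std() > 0:
        from .metrics import fit_line

        line = fit_line(yt.to_numpy(), yp.to_numpy())
        xs = np.linspace(yt.min(), yt.max(), 50)
        ax.plot(xs, line.slope * xs + line.intercept,
                label=f"y={line.slope:.2f}x+{line.intercept:.1f}, r²={line.r_squared:.3f}")
        ax.legend()
    ax.set_xlabel("manual (true) calcium volume, mm³")
    ax.set_ylabel("automated calcium volume, mm³")
    fig.tight_layout()
    fig.savefig(out_dir / "score_regression.png", dpi=100)
    plt.close(fig)

    if "ape_pct" in scores:
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(scores["patient_id"], scores["ape_pct"])
        ax.set_ylabel("APE, %")
        fig.tight_layout()
        fig.savefig(out_dir / "patient_ape.png", dpi=100)
        plt.close(fig)
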