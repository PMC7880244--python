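"""End-to-end study orchestration and the reproducible-run manifest.

:func:`run_study` performs the complete in-memory experiment the package is
built around: simulate a pure-adipose image, a pure-muscle image (both
10-frame averages) and a single-acquisition margin image; preprocess all
three; assemble training (first half of the pure images, split by scan
line) and validation sets (remaining halves plus the whole margin image);
grid-search the classifiers; and render the margin map.

:func:`run_pipeline` is the file-based wrapper used by the CLI: it writes
every intermediate artifact to disk and records a manifest of config hash,
seeds and output digests so identical configs reproduce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import __version__
from .budget import PhotonBudgetParams, budget_ratios
from .classify import (
    ClassifierBundle,
    ClassifierConfig,
    LabeledDataset,
    MarginMap,
    MetricsReport,
    assemble_datasets,
    compute_metrics,
    grid_search_train,
    predict_with_probability,
    render_margin_map,
)
from .preprocess import PreprocessConfig, ProcessedCube, preprocess_cube
from .synthetic import (
    GroundTruth,
    SceneConfig,
    adipose_template,
    default_scene_config,
    generate_calibration_reference,
    generate_intensity_standard,
    generate_scene,
    muscle_template,
)

__all__ = ["StudyResult", "run_study", "RunManifest", "run_pipeline"]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


@dataclass
class StudyResult:
    """Outputs of one simulated margin-detection study."""

    bundle: ClassifierBundle
    leaderboard: list[dict]
    train: LabeledDataset
    validation: LabeledDataset
    margin_map: MarginMap
    validation_accuracy: float
    margin_metrics: MetricsReport
    truth_margin_column: int
    selected_wavenumbers: np.ndarray
    processed: dict[str, ProcessedCube]
    truths: dict[str, GroundTruth]


def _prepare_cube(config: SceneConfig, preprocess_config: PreprocessConfig):
    cube, truth = generate_scene(config)
    reference = generate_calibration_reference(
        config.n_channels,
        truth.true_calibration,
        preprocess_config.calibration_peaks,
    )
    standard = generate_intensity_standard(
        config.n_y,
        config.n_channels,
        scratch_count=config.scratch_count,
        seed=config.seed,
        smooth=truth.response,
    )
    processed, _ = preprocess_cube(cube, reference, standard.image, preprocess_config)
    return cube, truth, processed


def run_study(
    seed: int = 0,
    scene: SceneConfig | None = None,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
    classifier_config: ClassifierConfig | None = None,
    n_frames_pure: int = 10,
) -> StudyResult:
    """Simulate, preprocess, train and map one complete margin study."""
    if scene is None:
        scene = default_scene_config()
    if scene.margin_column is None:
        raise ValueError("run_study requires a margin scene (margin_column set)")
    s_adipose, s_muscle, s_margin, s_model = _child_seeds(seed, 4)
    adipose_cfg = replace(
        scene,
        margin_column=None,
        templates=(adipose_template(), muscle_template()),
        n_frames=n_frames_pure,
        seed=s_adipose,
    )
    muscle_cfg = replace(
        scene,
        margin_column=None,
        templates=(muscle_template(), adipose_template()),
        n_frames=n_frames_pure,
        seed=s_muscle,
    )
    margin_cfg = replace(scene, n_frames=1, seed=s_margin)

    _, truth_a, proc_a = _prepare_cube(adipose_cfg, preprocess_config)
    _, truth_m, proc_m = _prepare_cube(muscle_cfg, preprocess_config)
    _, truth_x, proc_x = _prepare_cube(margin_cfg, preprocess_config)

    train, validation = assemble_datasets(proc_a, proc_m, proc_x, truth_x.label_map)
    if classifier_config is None:
        classifier_config = ClassifierConfig(seed=s_model)
    bundle, leaderboard = grid_search_train(train, validation, classifier_config)
    best_acc = max(row["validation_accuracy"] for row in leaderboard)

    margin_map = render_margin_map(bundle, proc_x, truth_line=margin_cfg.margin_column)
    keep = proc_x.retained
    labels, _ = predict_with_probability(
        bundle, proc_x.data[keep].reshape(-1, proc_x.data.shape[-1])
    )
    margin_metrics = compute_metrics(labels, truth_x.label_map[keep])

    return StudyResult(
        bundle=bundle,
        leaderboard=leaderboard,
        train=train,
        validation=validation,
        margin_map=margin_map,
        validation_accuracy=best_acc,
        margin_metrics=margin_metrics,
        truth_margin_column=int(margin_cfg.margin_column),
        selected_wavenumbers=proc_x.axis[bundle.selected_channels],
        processed={"adipose": proc_a, "muscle": proc_m, "margin": proc_x},
        truths={"adipose": truth_a, "muscle": truth_m, "margin": truth_x},
    )


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seeds: dict[str, int]
    version: str
    digests: dict[str, str]
    timestamps: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(
    outdir,
    seed: int = 0,
    scene: SceneConfig | None = None,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
    classifier_config: ClassifierConfig | None = None,
    budget_params: PhotonBudgetParams = PhotonBudgetParams(),
) -> RunManifest:
    """Run the full study and write every artifact plus a manifest to
    ``outdir``."""
    from .io import save_margin_map_png, write_margin_map_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timestamps = {"start": time.time()}

    result = run_study(
        seed=seed,
        scene=scene,
        preprocess_config=preprocess_config,
        classifier_config=classifier_config,
    )

    (outdir / "model.json").write_text(result.bundle.to_json())
    (outdir / "leaderboard.json").write_text(json.dumps(result.leaderboard, indent=2))
    write_margin_map_csv(result.margin_map, outdir / "margin_map.csv")
    save_margin_map_png(result.margin_map, outdir / "margin_map.png")

    report = budget_ratios(budget_params)
    (outdir / "budget.json").write_text(
        json.dumps(
            {
                "intensity_ratio": report.intensity_ratio,
                "transmission_ratio": report.transmission_ratio,
                "na_ratio": report.na_ratio,
                "fiber_ratio": report.fiber_ratio,
                "overall": report.overall,
                "rounded": report.rounded(),
            },
            indent=2,
        )
    )
    metrics = result.margin_metrics
    (outdir / "metrics.json").write_text(
        json.dumps(
            {
                "validation_accuracy": result.validation_accuracy,
                "margin_accuracy": metrics.accuracy,
                "margin_sensitivity": metrics.sensitivity,
                "margin_specificity": metrics.specificity,
                "selected_wavenumbers": result.selected_wavenumbers.tolist(),
                "estimated_margin_column": result.margin_map.margin_column,
                "low_confidence_width_px": result.margin_map.low_confidence_width,
            },
            indent=2,
        )
    )
    timestamps["end"] = time.time()

    scene_used = scene if scene is not None else default_scene_config()
    config_payload = {
        "seed": seed,
        "scene": _config_dict(scene_used),
        "preprocess": _config_dict(preprocess_config),
        "classify": _config_dict(classifier_config) if classifier_config else None,
        "budget": _config_dict(budget_params),
    }
    config_hash = hashlib.sha256(
        json.dumps(config_payload, sort_keys=True, default=str).encode()
    ).hexdigest()

    digests = {
        p.name: _sha256(p)
        for p in sorted(outdir.glob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=config_hash,
        seeds={"base": seed},
        version=__version__,
        digests=digests,
        timestamps=timestamps,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _config_dict(obj) -> dict | None:
    if obj is None:
        return None
    d = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        d[f.name] = str(v) if not isinstance(v, (int, float, str, bool, type(None))) else v
    return d
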