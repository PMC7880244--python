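"""File I/O: HDF5 cube container, CSV reference spectra, YAML configs,
and margin-map export.

Cube container layout (any HDF5 reader can consume it):

* dataset ``cube`` — float array, shape (n_lines, n_y, n_channels)
* dataset ``wavenumber_axis`` — spectral axis (pixel indices or cm^-1)
* optional dataset ``illumination`` — relative illumination, shape (n_y,)
* optional dataset ``label_map`` — per-pixel class labels (bytes), synthetic
  scenes only
* root attributes ``axis_kind``, ``line_step_um``, ``line_length_mm``,
  ``exposure_s``, ``seed``

Reference spectra are two-column CSV with a required header row
``pixel_or_wavenumber,intensity`` (RFC 4180, '.' decimal separator).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .budget import PhotonBudgetParams
from .classify import ClassifierConfig, MarginMap
from .containers import HyperspectralCube, Spectrum
from .errors import SchemaError
from .preprocess import PreprocessConfig
from .synthetic import SceneConfig

__all__ = [
    "write_cube",
    "read_cube",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "load_scene_config",
    "load_preprocess_config",
    "load_classifier_config",
    "load_budget_params",
    "write_margin_map_csv",
    "save_margin_map_png",
]

_CUBE_ATTRS = ("line_step_um", "line_length_mm", "exposure_s", "seed")


def write_cube(
    cube: HyperspectralCube, path, label_map: np.ndarray | None = None
) -> None:
    """Write a cube to the documented HDF5 layout (deterministic bytes)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.data, track_times=False)
        f.create_dataset("wavenumber_axis", data=cube.axis, track_times=False)
        f.attrs["axis_kind"] = cube.axis_kind
        for key in _CUBE_ATTRS:
            if key in cube.metadata:
                f.attrs[key] = cube.metadata[key]
        illum = cube.metadata.get("illumination")
        if illum is not None:
            f.create_dataset("illumination", data=np.asarray(illum), track_times=False)
        if label_map is not None:
            f.create_dataset(
                "label_map",
                data=np.char.encode(label_map.astype(str), "utf-8"),
                track_times=False,
            )


def read_cube(path) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube`; raises SchemaError on a
    malformed file, naming the missing field."""
    with h5py.File(path, "r") as f:
        for name in ("cube", "wavenumber_axis"):
            if name not in f:
                raise SchemaError(f"cube file {path} is missing dataset {name!r}")
        data = f["cube"][()]
        axis = f["wavenumber_axis"][()]
        metadata = {k: f.attrs[k] for k in _CUBE_ATTRS if k in f.attrs}
        axis_kind = str(f.attrs.get("axis_kind", "wavenumber"))
        if "illumination" in f:
            metadata["illumination"] = f["illumination"][()]
        if "label_map" in f:
            metadata["label_map"] = np.char.decode(f["label_map"][()], "utf-8")
    return HyperspectralCube(data=data, axis=axis, axis_kind=axis_kind, metadata=metadata)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"pixel_or_wavenumber": spectrum.axis, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def read_spectrum_csv(path, axis_kind: str = "pixel") -> Spectrum:
    df = pd.read_csv(path)
    for col in ("pixel_or_wavenumber", "intensity"):
        if col not in df.columns:
            raise SchemaError(f"spectrum CSV {path} is missing column {col!r}")
    return Spectrum(
        intensities=df["intensity"].to_numpy(float),
        axis=df["pixel_or_wavenumber"].to_numpy(float),
        axis_kind=axis_kind,
    )


def _build_dataclass(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise SchemaError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**data)


def _load_yaml_section(path, section: str | None) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if section is not None and section in raw:
        raw = raw[section] or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    return raw


def load_scene_config(path, section: str | None = "scene") -> SceneConfig:
    data = _load_yaml_section(path, section)
    for key in ("wavenumber_range", "illumination_profile"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    if "templates" in data:
        raise SchemaError(
            "templates cannot be configured from YAML; construct SceneConfig in code"
        )
    return _build_dataclass(SceneConfig, data)


def load_preprocess_config(path, section: str | None = "preprocess") -> PreprocessConfig:
    data = _load_yaml_section(path, section)
    for key in ("response_smooth_sigma", "calibration_peaks"):
        if key in data:
            data[key] = tuple(data[key])
    return _build_dataclass(PreprocessConfig, data)


def load_classifier_config(path, section: str | None = "classify") -> ClassifierConfig:
    data = _load_yaml_section(path, section)
    for key in (
        "svm_C_grid",
        "svm_gamma_grid",
        "svm_kernels",
        "rf_n_estimators_grid",
        "rf_max_samples_grid",
    ):
        if key in data:
            data[key] = tuple(data[key])
    return _build_dataclass(ClassifierConfig, data)


def load_budget_params(path, section: str | None = "budget") -> PhotonBudgetParams:
    data = _load_yaml_section(path, section)
    return _build_dataclass(PhotonBudgetParams, data)


def write_margin_map_csv(margin_map: MarginMap, path) -> None:
    """Long-format CSV: x, y, predicted class, confidence, masked flag."""
    nx, ny = margin_map.class_map.shape
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pd.DataFrame(
        {
            "x": xs.ravel(),
            "y": ys.ravel(),
            "predicted_class": margin_map.class_map.ravel(),
            "confidence": margin_map.confidence_map.ravel(),
            "masked": margin_map.mask.ravel().astype(int),
        }
    ).to_csv(path, index=False)


def save_margin_map_png(margin_map: MarginMap, path) -> None:
    """Two-panel figure: class map (adipose red, muscle blue, masked black)
    and confidence map (0.5-1.0)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nx, ny = margin_map.class_map.shape
    rgb = np.zeros((nx, ny, 3))
    rgb[margin_map.class_map == "adipose"] = (0.85, 0.12, 0.12)
    rgb[margin_map.class_map == "muscle"] = (0.12, 0.25, 0.85)
    rgb[margin_map.mask] = (0.0, 0.0, 0.0)

    conf = np.ma.masked_where(margin_map.mask, margin_map.confidence_map)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].imshow(np.transpose(rgb, (1, 0, 2)), origin="lower", aspect="auto")
    axes[0].set_title("classification map")
    cmap = plt.cm.viridis.copy()
    cmap.set_bad("black")
    im = axes[1].imshow(
        conf.T, origin="lower", aspect="auto", vmin=0.5, vmax=1.0, cmap=cmap
    )
    axes[1].set_title("confidence map")
    fig.colorbar(im, ax=axes[1], label="confidence of predicted class")
    for ax in axes:
        ax.set_xlabel("scan position x")
        ax.set_ylabel("line position y")
        if margin_map.truth_line is not None:
            ax.axvline(margin_map.truth_line - 0.5, color="lime", lw=1.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
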