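import numpy as np
import pytest

from ramanmargin.synthetic import (
    SceneConfig,
    adipose_template,
    default_scene_config,
    generate_scene,
    muscle_template,
)


@pytest.fixture(scope="session")
def default_margin_scene():
    """Full-size two-tissue margin scene (boundary at column 20)."""
    cfg = default_scene_config(seed=42)
    cube, truth = generate_scene(cfg)
    return cfg, cube, truth


@pytest.fixture(scope="session")
def small_pure_scene():
    """Small noiseless single-class scene for identity checks."""
    cfg = SceneConfig(
        n_lines=10,
        n_y=12,
        margin_column=None,
        spike_rate=0.0,
        noise_scale=0.0,
        apply_response=False,
        illumination_profile=tuple([1.0] * 12),
        seed=3,
    )
    cube, truth = generate_scene(cfg)
    return cfg, cube, truth


@pytest.fixture()
def two_templates():
    return adipose_template(), muscle_template()


def two_band_contrast_dataset(seed: int):
    """Two-class spectra whose templates differ only at the 1001 and 1442
    bands (muscle carries 1001; adipose carries 1442 at twice the
    intensity), pushed through the full preprocessing chain.

    Returns ``(dataset, wavenumber_axis)``.
    """
    from ramanmargin.classify import LabeledDataset
    from ramanmargin.pipeline import _prepare_cube
    from ramanmargin.preprocess import PreprocessConfig
    from ramanmargin.synthetic import BandSpec, TissueTemplate, muscle_template

    shared = tuple(
        b for b in muscle_template().bands if b.center not in (1001.0, 1442.0)
    )
    t_muscle = TissueTemplate(
        "muscle",
        shared + (BandSpec(1001.0, amplitude=1.0), BandSpec(1442.0, amplitude=1.0)),
        snr_scale=1.0,
    )
    t_adipose = TissueTemplate(
        "adipose", shared + (BandSpec(1442.0, amplitude=2.0),), snr_scale=1.6
    )
    feats, labels = [], []
    axis = None
    for i, (tmpl, other) in enumerate(((t_muscle, t_adipose), (t_adipose, t_muscle))):
        cfg = SceneConfig(
            n_lines=12,
            n_y=42,
            margin_column=None,
            templates=(tmpl, other),
            n_frames=10,
            seed=2 * seed + i,
        )
        _, _, proc = _prepare_cube(cfg, PreprocessConfig())
        feats.append(proc.data[proc.retained])
        labels += [tmpl.name] * int(proc.retained.sum())
        axis = proc.axis
    x = np.vstack(feats)
    y = np.asarray(labels, dtype=object).astype(str)
    prov = np.array([("planted", i, 0) for i in range(len(y))], dtype=object)
    return LabeledDataset(x, y, prov, "train"), axis
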