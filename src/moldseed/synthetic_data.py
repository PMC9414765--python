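"""Ground-truthed synthetic spectra tables and hyperspectral cubes.

Five ordered severity classes share a smooth reflectance template whose
peaks near 560 nm and 800 nm shrink with severity, so class k strictly
dominates class k+1 across the 500-900 nm window.  Rows are distorted by a
per-seed affine scatter (gain/offset) plus additive Gaussian noise — exactly
the artifacts SNV/MSC are built to remove.  Cubes render seeds as ellipses
in per-class column blocks on a dark matte background, and raw counts are
synthesized by inverting the reflectance calibration so that
calibrate -> segment -> extract can be tested against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hsi_io import CalibrationPair, HyperCube

__all__ = ["SyntheticConfig", "class_template", "generate_table", "generate_cube"]


@dataclass
class SyntheticConfig:
    n_classes: int = 5
    seeds_per_class: int = 12
    lines: int = 240
    samples: int = 200
    n_bands: int = 462
    wl_min: float = 400.0
    wl_max: float = 1000.0
    amplitude_decay: float = 0.15     # per-class peak shrink factor
    noise_sd: float = 0.02
    scatter_gain: tuple[float, float] = (0.95, 1.05)
    scatter_offset: tuple[float, float] = (-0.02, 0.02)
    ellipse_axes: tuple[int, int] = (10, 7)   # (row, col) half-axes in px
    columns_per_class: int = 2
    background_reflectance: float = 0.05
    white_level: float = 1000.0
    dark_level: float = 100.0
    rng_seed: int = 0
    informative_bands: tuple[int, ...] | None = None
    informative_step: float = 0.08

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.n_bands)


def class_template(
    class_index: int,
    wavelengths: np.ndarray,
    amplitude_decay: float = 0.15,
    n_classes: int = 5,
) -> np.ndarray:
    """Deterministic reflectance template for one severity class.

    Smooth baseline plus Gaussian peaks near 560 and 800 nm scaled by
    ``1 - amplitude_decay * class_index``; higher severity -> lower peaks.
    """
    if not 0 <= class_index < n_classes:
        raise ValueError(f"class_index {class_index} outside 0..{n_classes - 1}")
    wl = np.asarray(wavelengths, dtype=float)
    if np.any(wl < 400.0) or np.any(wl > 1000.0):
        raise ValueError("wavelengths must lie within 400-1000 nm")
    scale = 1.0 - amplitude_decay * class_index
    peak_green = np.exp(-0.5 * ((wl - 560.0) / 45.0) ** 2)
    peak_nir = np.exp(-0.5 * ((wl - 800.0) / 60.0) ** 2)
    return 0.22 + scale * (0.45 * peak_green + 0.35 * peak_nir)


def _row_templates(config: SyntheticConfig) -> np.ndarray:
    """(n_classes, n_bands) templates, honoring the informative-band override."""
    if config.informative_bands is None:
        return np.stack(
            [
                class_template(
                    k, config.wavelengths, config.amplitude_decay, config.n_classes
                )
                for k in range(config.n_classes)
            ]
        )
    # Flat background with class-proportional steps only at the named bands:
    # isolates the signal for feature-selection tests.
    bands = np.asarray(config.informative_bands, dtype=int)
    if np.any(bands < 0) or np.any(bands >= config.n_bands):
        raise ValueError("informative band index out of range")
    templates = np.full((config.n_classes, config.n_bands), 0.3)
    for k in range(config.n_classes):
        templates[k, bands] += config.informative_step * k
    return templates


def generate_table(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-seed spectra matrix with labels: ``(X, y, wavelengths)``.

    Row i of class k is ``a_i * template_k + b_i + noise`` with the gain and
    offset drawn from the configured scatter ranges.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    templates = _row_templates(config)
    n = config.n_classes * config.seeds_per_class
    X = np.empty((n, config.n_bands))
    y = np.empty(n, dtype=int)
    row = 0
    for k in range(config.n_classes):
        for _ in range(config.seeds_per_class):
            a = rng.uniform(*config.scatter_gain)
            b = rng.uniform(*config.scatter_offset)
            noise = rng.normal(0.0, config.noise_sd, size=config.n_bands)
            X[row] = a * templates[k] + b + noise
            y[row] = k
            row += 1
    return X, y, config.wavelengths


def _seed_layout(config: SyntheticConfig) -> list[tuple[int, int, int]]:
    """Centers ``(row, col, class)`` for every seed; raises on overflow."""
    ay, ax = config.ellipse_axes
    block_w = config.samples // config.n_classes
    cols = config.columns_per_class
    rows = math.ceil(config.seeds_per_class / cols)
    col_pitch = block_w // cols
    row_pitch = config.lines // rows
    if col_pitch < 2 * ax + 4 or row_pitch < 2 * ay + 4:
        raise ValueError(
            "seed layout overflows the cube: enlarge dims or shrink ellipses"
        )
    centers = []
    for k in range(config.n_classes):
        placed = 0
        for r in range(rows):
            for c in range(cols):
                if placed >= config.seeds_per_class:
                    break
                cy = row_pitch // 2 + r * row_pitch
                cx = k * block_w + col_pitch // 2 + c * col_pitch
                centers.append((cy, cx, k))
                placed += 1
    return centers


def generate_cube(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[HyperCube, CalibrationPair, np.ndarray, dict[int, int]]:
    """Raw-counts cube plus references, truth labels, and seed classes.

    Raw counts invert the calibration ratio:
    ``raw = reflectance * (white - dark) + dark``.  Truth labels are
    numbered by the same topmost-then-leftmost raster rule the segmenter
    uses, so the two label maps are directly comparable.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    wl = config.wavelengths
    B = config.n_bands
    templates = _row_templates(config)
    ay, ax = config.ellipse_axes

    reflectance = np.full(
        (config.lines, config.samples, B), config.background_reflectance
    )
    labels = np.zeros((config.lines, config.samples), dtype=np.int32)
    yy, xx = np.mgrid[0 : config.lines, 0 : config.samples]

    anchors: list[tuple[int, int, int, int]] = []  # (top_r, left_c, prov_id, class)
    for prov_id, (cy, cx, k) in enumerate(_seed_layout(config), start=1):
        a = rng.uniform(*config.scatter_gain)
        b = rng.uniform(*config.scatter_offset)
        inside = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        labels[inside] = prov_id
        seed_spec = a * templates[k] + b
        reflectance[inside] = seed_spec
        rr, cc = np.nonzero(inside)
        anchors.append((int(rr[0]), int(cc[0]), prov_id, k))

    if config.noise_sd > 0:
        reflectance += rng.normal(0.0, config.noise_sd, size=reflectance.shape)

    # Renumber 1..K by raster order of the topmost-then-leftmost pixel.
    anchors.sort()
    truth = np.zeros_like(labels)
    class_of_seed: dict[int, int] = {}
    for new_id, (_, _, prov, k) in enumerate(anchors, start=1):
        truth[labels == prov] = new_id
        class_of_seed[new_id] = k

    # Per-band references with a gentle spectral slope on the white frame.
    white = config.white_level * (0.9 + 0.1 * (wl - wl[0]) / (wl[-1] - wl[0]))
    dark = np.full(B, config.dark_level)
    raw = reflectance * (white - dark) + dark
    cube = HyperCube(
        data=raw,
        wavelengths_nm=wl,
        meta={"description": "synthetic seed plate", "seed": str(config.rng_seed)},
    )
    return cube, CalibrationPair(white=white, dark=dark), truth, class_of_seed
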