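"""Seed segmentation and per-seed spectrum extraction.

A single calibrated band (default: the band nearest 598.71 nm) is binarized
by Otsu's method, cleaned by morphological opening then closing, and split
into 8-connected components.  Components are numbered 1..K in raster order
of their topmost-then-leftmost pixel so that seed ids are deterministic, and
each seed's spectrum is the arithmetic mean over its member pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology

from .hsi_io import HyperCube

__all__ = [
    "SeedSpectraTable",
    "otsu_threshold",
    "clean_mask",
    "label_and_number",
    "extract_spectra",
]


@dataclass
class SeedSpectraTable:
    """Per-seed mean spectra with optional class labels.

    ``spectra`` is (n_seeds, n_bands); ``seed_ids`` are unique and sorted;
    ``class_labels`` is None or an int array aligned with ``seed_ids``.
    """

    seed_ids: np.ndarray
    spectra: np.ndarray
    wavelengths_nm: np.ndarray
    class_labels: np.ndarray | None = None
    pixel_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.seed_ids = np.asarray(self.seed_ids, dtype=int)
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be 2-D (seeds x bands)")
        if self.spectra.shape[0] != self.seed_ids.shape[0]:
            raise ValueError("seed_ids and spectra row count differ")
        if self.spectra.shape[1] != self.wavelengths_nm.shape[0]:
            raise ValueError("spectra band count != wavelength grid length")
        if self.seed_ids.size and (
            np.any(np.diff(self.seed_ids) <= 0)
        ):
            raise ValueError("seed_ids must be unique and sorted ascending")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite values")
        if self.class_labels is not None:
            self.class_labels = np.asarray(self.class_labels, dtype=int)
            if self.class_labels.shape[0] != self.seed_ids.shape[0]:
                raise ValueError("class_labels length != number of seeds")

    def __len__(self) -> int:
        return int(self.seed_ids.size)

    def to_frame(self) -> pd.DataFrame:
        """Export as a DataFrame: seed_id, class, w<λ1>..w<λB>."""
        cols = {f"w{w:.2f}": self.spectra[:, j] for j, w in enumerate(self.wavelengths_nm)}
        cls = self.class_labels if self.class_labels is not None else np.full(len(self), -1)
        return pd.DataFrame({"seed_id": self.seed_ids, "class": cls, **cols})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SeedSpectraTable":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c.startswith("w")]
        wavelengths = np.array([float(c[1:]) for c in wl_cols])
        labels = df["class"].to_numpy()
        return cls(
            seed_ids=df["seed_id"].to_numpy(),
            spectra=df[wl_cols].to_numpy(dtype=float),
            wavelengths_nm=wavelengths,
            class_labels=None if np.all(labels < 0) else labels,
        )


def otsu_threshold(gray: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of the value range.

    Foreground is ``gray > threshold``.  A constant image has no threshold
    and raises ``ValueError``.
    """
    gray = np.asarray(gray, dtype=float)
    if np.unique(gray).size < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    return float(filters.threshold_otsu(gray, nbins=256))


def clean_mask(mask: np.ndarray, se_radius: int = 2) -> np.ndarray:
    """Morphological opening then closing with a disk structuring element."""
    if se_radius < 1:
        raise ValueError("se_radius must be >= 1")
    selem = morphology.disk(se_radius)
    opened = morphology.opening(np.asarray(mask, dtype=bool), selem)
    return morphology.closing(opened, selem).astype(bool)


def label_and_number(mask: np.ndarray, min_area: int = 20) -> np.ndarray:
    """Label 8-connected components, renumbered deterministically.

    Components with area >= ``min_area`` get ids 1..K in raster order of
    each component's topmost-then-leftmost pixel; smaller components are
    dropped to background (0).
    """
    mask = np.asarray(mask, dtype=bool)
    raw_labels = measure.label(mask, connectivity=2)
    out = np.zeros_like(raw_labels, dtype=np.int32)
    anchors = []  # (row, col, raw_label) of each kept component's first pixel
    for region in measure.regionprops(raw_labels):
        if region.area < min_area:
            continue
        # coords are sorted row-major, so the first is topmost-then-leftmost
        r, c = region.coords[0]
        anchors.append((int(r), int(c), region.label))
    anchors.sort()
    for new_id, (_, _, raw) in enumerate(anchors, start=1):
        out[raw_labels == raw] = new_id
    return out


def extract_spectra(
    cube: HyperCube,
    labels: np.ndarray,
    class_of_seed: Mapping[int, int] | None = None,
) -> SeedSpectraTable:
    """Mean spectrum per labeled seed, rows ordered by seed id."""
    labels = np.asarray(labels)
    if labels.shape != cube.data.shape[:2]:
        raise ValueError(
            f"label map shape {labels.shape} != cube spatial shape "
            f"{cube.data.shape[:2]}"
        )
    seed_ids = np.unique(labels)
    seed_ids = seed_ids[seed_ids > 0]
    n_bands = cube.n_bands
    spectra = np.empty((seed_ids.size, n_bands), dtype=float)
    counts = np.empty(seed_ids.size, dtype=int)
    flat = cube.data.reshape(-1, n_bands)
    flat_labels = labels.ravel()
    for row, sid in enumerate(seed_ids):
        member = flat_labels == sid
        counts[row] = int(member.sum())
        spectra[row] = flat[member].mean(axis=0)
    class_labels = None
    if class_of_seed is not None:
        class_labels = np.array([class_of_seed[int(s)] for s in seed_ids], dtype=int)
    return SeedSpectraTable(
        seed_ids=seed_ids,
        spectra=spectra,
        wavelengths_nm=cube.wavelengths_nm.copy(),
        class_labels=class_labels,
        pixel_counts=counts,
    )
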