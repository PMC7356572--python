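"""Spectral Angle Mapper (SAM) similarity and semi-automatic labeling.

SAM treats two spectral signatures as vectors and measures the angle
between them; it is invariant to positive scaling, so illumination
amplitude differences do not affect it.  The labeling tool grows a class
mask from a manually chosen reference pixel by marking every pixel whose
angle to the seed spectrum is within a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hsio import BinaryMask, HSCube

__all__ = ["LabeledSpectraSet", "sam_angle", "sam_angles", "grow_labels"]

LESION_CLASSES = ("benign", "malignant")
ALL_CLASSES = ("skin", "benign", "malignant")


@dataclass
class LabeledSpectraSet:
    """Labeled pixel spectra with provenance.

    spectra   : (n, bands) reflectance matrix on one wavelength grid
    classes   : per-row class, one of 'skin' | 'benign' | 'malignant'
    patient_id: per-row patient identifier
    image_id  : per-row image identifier
    """

    spectra: np.ndarray
    classes: np.ndarray
    patient_id: np.ndarray
    image_id: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        self.patient_id = np.asarray(self.patient_id, dtype=object)
        self.image_id = np.asarray(self.image_id, dtype=object)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        n = self.spectra.shape[0]
        if not (len(self.classes) == len(self.patient_id) == len(self.image_id) == n):
            raise ValueError("row metadata must match spectra row count")
        if self.spectra.ndim != 2 or self.spectra.shape[1] != self.wavelengths_nm.size:
            raise ValueError("spectra must be n x bands matching the wavelength grid")
        bad = set(self.classes) - set(ALL_CLASSES)
        if bad:
            raise ValueError(f"unknown classes: {sorted(bad)}")

    def __len__(self) -> int:
        return self.spectra.shape[0]

    def subset(self, index: np.ndarray) -> "LabeledSpectraSet":
        return LabeledSpectraSet(
            spectra=self.spectra[index],
            classes=self.classes[index],
            patient_id=self.patient_id[index],
            image_id=self.image_id[index],
            wavelengths_nm=self.wavelengths_nm,
        )

    def of_class(self, cls: str) -> np.ndarray:
        return self.spectra[self.classes == cls]

    def to_csv(self, path) -> None:
        cols = {f"b{i}": self.spectra[:, i] for i in range(self.spectra.shape[1])}
        df = pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "image_id": self.image_id,
                "class": self.classes,
                **cols,
            }
        )
        header_wl = ",".join(f"{w:.6f}" for w in self.wavelengths_nm)
        with open(path, "w") as fh:
            fh.write(f"# wavelengths_nm: {header_wl}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabeledSpectraSet":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# wavelengths_nm:"):
                raise ValueError("labeled-spectra CSV missing wavelength header line")
            wavelengths = np.array(
                [float(t) for t in first.split(":", 1)[1].split(",")]
            )
            df = pd.read_csv(fh)
        band_cols = [c for c in df.columns if c.startswith("b")]
        return cls(
            spectra=df[band_cols].to_numpy(dtype=float),
            classes=df["class"].to_numpy(),
            patient_id=df["patient_id"].to_numpy(),
            image_id=df["image_id"].to_numpy(),
            wavelengths_nm=wavelengths,
        )


def sam_angle(s1: np.ndarray, s2: np.ndarray) -> float:
    """Spectral angle between two signatures, in radians, in [0, pi]."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("spectra must share length")
    n1 = np.linalg.norm(s1)
    n2 = np.linalg.norm(s2)
    if n1 == 0 or n2 == 0:
        raise ValueError("SAM undefined for a zero spectrum")
    cos = np.clip(np.dot(s1, s2) / (n1 * n2), -1.0, 1.0)
    return float(np.arccos(cos))


def sam_angles(spectra: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Vectorized SAM of each row of ``spectra`` against one reference."""
    spectra = np.asarray(spectra, dtype=float)
    reference = np.asarray(reference, dtype=float)
    norms = np.linalg.norm(spectra, axis=1)
    ref_norm = np.linalg.norm(reference)
    if ref_norm == 0 or np.any(norms == 0):
        raise ValueError("SAM undefined for a zero spectrum")
    cos = np.clip(spectra @ reference / (norms * ref_norm), -1.0, 1.0)
    return np.arccos(cos)


def grow_labels(
    cube: HSCube, seed: tuple[int, int], threshold: float
) -> BinaryMask:
    """Mask of every pixel whose SAM angle to the seed spectrum is within
    ``threshold`` radians.  The seed pixel is always marked (angle 0).

    The test is global over the image, not spatially connected: the tool
    labels the most spectrally similar pixels wherever they sit.
    """
    row, col = seed
    rows, cols, _ = cube.shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise ValueError(f"seed {seed} outside the {rows}x{cols} grid")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ref = cube.values[row, col].astype(float)
    angles = sam_angles(cube.pixels(), ref).reshape(rows, cols)
    return BinaryMask(values=angles <= threshold)
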