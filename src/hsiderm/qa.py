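"""Acquisition-repeatability QA.

When the same lesion is captured twice, the two cubes should agree voxel
by voxel.  The absolute relative difference percentage quantifies this:

    RD(%) = |x - y| * 100 / ((mean(x) + mean(y)) / 2)

applied voxelwise with the global means of the two full arrays in the
denominator; its mean over voxels (RDmean) is the summary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsio import BinaryMask, HSCube

__all__ = ["RepeatabilityReport", "relative_difference", "masked_spectral_stats", "scatter_pairs"]


@dataclass(frozen=True)
class RepeatabilityReport:
    rd_map: np.ndarray  # per-voxel RD, percent
    rd_mean: float  # percent
    n_voxels: int


def relative_difference(x: np.ndarray, y: np.ndarray) -> RepeatabilityReport:
    """Voxelwise absolute relative difference between two repeat captures."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("arrays must share shape")
    denom = (x.mean() + y.mean()) / 2.0
    if denom <= 0:
        raise ValueError("mean(x) + mean(y) must be positive")
    rd_map = np.abs(x - y) * 100.0 / denom
    return RepeatabilityReport(rd_map=rd_map, rd_mean=float(rd_map.mean()), n_voxels=x.size)


def masked_spectral_stats(cube: HSCube, mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Per-band mean and population variance over the masked pixels."""
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape must match cube spatial grid")
    if mask.n_positive == 0:
        raise ValueError("mask selects no pixels")
    spectra = cube.values[mask.values]  # (n_masked, bands)
    return spectra.mean(axis=0), spectra.var(axis=0)  # ddof=0: population


def scatter_pairs(a: HSCube, b: HSCube) -> np.ndarray:
    """Paired voxel values of two same-shape cubes as an (n, 2) array,
    row-major pixel order then band."""
    if a.shape != b.shape:
        raise ValueError("cubes must share shape")
    return np.column_stack([a.values.ravel(), b.values.ravel()])
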