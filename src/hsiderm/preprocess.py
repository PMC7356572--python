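"""Pre-processing chain for raw hyperspectral captures.

Four stages, applied in order: radiometric calibration against white/dark
reference frames, trimming of low-response edge bands, spectral smoothing
(centered moving average), and per-signature min-max normalization.  After
the chain only the *shape* of each spectral signature is retained, which
makes downstream comparisons insensitive to non-uniform illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from .hsio import CubeState, HSCube, ReferenceFrames

__all__ = [
    "PreprocessConfig",
    "calibrate",
    "trim_bands",
    "smooth_spectra",
    "normalize_minmax",
    "preprocess_chain",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the pre-processing chain.

    drop_first / drop_last
        Edge bands removed for poor sensor response (defaults 4 and 5:
        a 125-band capture becomes 116 bands).
    smooth_window
        Width of the centered moving average along the spectral axis;
        must be odd.  1 disables smoothing.
    normalize
        Map every pixel spectrum to [0, 1] (min-max) when on.
    clamp_negative
        Clamp calibrated reflectance below 0 (raw < dark) to 0.
    """

    drop_first: int = 4
    drop_last: int = 5
    smooth_window: int = 5
    normalize: bool = True
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if self.drop_first < 0 or self.drop_last < 0:
            raise ValueError("band drops must be non-negative")


def calibrate(
    raw: HSCube, refs: ReferenceFrames, clamp_negative: bool = True
) -> tuple[HSCube, int]:
    """Radiometric calibration: reflectance = (raw - dark)/(white - dark).

    Voxels where white equals dark (dead sensor elements) are set to 0
    rather than raising; their count is returned alongside the cube so a
    caller can flag a bad capture.
    """
    if raw.shape != refs.white.shape:
        raise ValueError("raw cube and reference frames must share shape")
    if not np.array_equal(raw.wavelengths_nm, refs.white.wavelengths_nm):
        raise ValueError("raw cube and reference frames must share the wavelength grid")
    denom = refs.white.values.astype(np.float64) - refs.dark.values.astype(np.float64)
    numer = raw.values.astype(np.float64) - refs.dark.values.astype(np.float64)
    dead = denom == 0
    n_dead = int(dead.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.where(dead, 0.0, numer / np.where(dead, 1.0, denom))
    if clamp_negative:
        refl = np.maximum(refl, 0.0)
    cube = HSCube(
        values=refl.astype(np.float32),
        wavelengths_nm=raw.wavelengths_nm,
        state=CubeState.CALIBRATED,
    )
    return cube, n_dead


def trim_bands(cube: HSCube, cfg: PreprocessConfig = PreprocessConfig()) -> HSCube:
    """Drop the first ``drop_first`` and last ``drop_last`` bands."""
    if cfg.drop_first + cfg.drop_last >= cube.n_bands:
        raise ValueError(
            f"cannot drop {cfg.drop_first}+{cfg.drop_last} bands from a "
            f"{cube.n_bands}-band cube"
        )
    stop = cube.n_bands - cfg.drop_last
    return HSCube(
        values=cube.values[:, :, cfg.drop_first : stop],
        wavelengths_nm=cube.wavelengths_nm[cfg.drop_first : stop],
        state=cube.state,
    )


def smooth_spectra(cube: HSCube, cfg: PreprocessConfig = PreprocessConfig()) -> HSCube:
    """Centered moving average along the spectral axis, per pixel.

    At the spectral edges the window is truncated to the in-range bands,
    so a constant spectrum passes through unchanged everywhere.
    """
    w = cfg.smooth_window
    if w > cube.n_bands:
        raise ValueError("smooth_window exceeds band count")
    if w == 1:
        return cube
    kernel = np.ones(w)
    sums = convolve1d(cube.values.astype(np.float64), kernel, axis=2, mode="constant")
    counts = convolve1d(np.ones(cube.n_bands), kernel, mode="constant")
    return HSCube(
        values=(sums / counts).astype(np.float32),
        wavelengths_nm=cube.wavelengths_nm,
        state=cube.state,
    )


def normalize_minmax(cube: HSCube) -> HSCube:
    """Per-pixel min-max normalization to [0, 1].

    Flat spectra (max == min) map to all-zeros by convention.
    """
    v = cube.values.astype(np.float64)
    lo = v.min(axis=2, keepdims=True)
    hi = v.max(axis=2, keepdims=True)
    span = hi - lo
    flat = span == 0
    out = np.where(flat, 0.0, (v - lo) / np.where(flat, 1.0, span))
    return HSCube(
        values=out.astype(np.float32),
        wavelengths_nm=cube.wavelengths_nm,
        state=CubeState.PREPROCESSED,
    )


def preprocess_chain(
    raw: HSCube, refs: ReferenceFrames, cfg: PreprocessConfig = PreprocessConfig()
) -> HSCube:
    """calibrate -> trim_bands -> smooth_spectra -> normalize_minmax."""
    cube, _ = calibrate(raw, refs, clamp_negative=cfg.clamp_negative)
    refs_trim_cfg = cfg
    cube = trim_bands(cube, refs_trim_cfg)
    cube = smooth_spectra(cube, cfg)
    if cfg.normalize:
        cube = normalize_minmax(cube)
    return cube
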