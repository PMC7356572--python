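"""Synthetic dermatologic hyperspectral scenes with known ground truth.

The generator emulates the data a snapshot VNIR dermatology camera
produces: a 50x50 px, 125-band (450-950 nm) raw cube of a skin patch
with an optional compact pigmented lesion, plus the white/dark reference
frames captured alongside it.

The per-pixel reflectance model is phenomenological, not radiative
transfer: a logistic rise from a visible-range base to a NIR plateau,
minus Gaussian oxy-hemoglobin absorption dips at 542 and 576 nm,
attenuated by a melanin power law exp(-m (500/lambda)^3).  Three default
skin modes differ chiefly in melanin content (light / medium / dark
phototypes); benign lesions are darker and redder than skin, and
malignant lesions darker and spectrally flatter still.  Raw counts
follow the camera's forward model — reflectance x (white - dark) + dark
with a smooth multiplicative illumination gradient — so radiometric
calibration inverts the generator exactly up to the injected noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hsio import BinaryMask, CubeState, HSCube, InstrumentProfile, ReferenceFrames
from .labeling import LabeledSpectraSet

__all__ = [
    "SpectralModelParams",
    "SceneConfig",
    "Scene",
    "SKIN_MODES",
    "LESION_MODES",
    "make_spectrum",
    "make_scene",
    "make_dataset",
]


@dataclass(frozen=True)
class SpectralModelParams:
    """Parameters of the phenomenological skin-reflectance model.

    base_level / nir_plateau : reflectance floor and NIR ceiling
    slope_center_nm / slope_width_nm : position and width of the
        logistic rise between them
    dip_depth_542 / dip_depth_576 : hemoglobin absorption dip depths
    melanin_scale : strength of the exp(-m (500/lambda)^3) attenuation
    """

    base_level: float
    nir_plateau: float
    slope_center_nm: float
    slope_width_nm: float
    dip_depth_542: float
    dip_depth_576: float
    melanin_scale: float


# Three skin phototype modes (differing mainly in melanin) and the two
# lesion classes.  Lesions are darker, with a red-shifted rise; the
# malignant mode is flatter and more strongly melanin-attenuated.
SKIN_MODES: tuple[SpectralModelParams, ...] = (
    SpectralModelParams(0.30, 0.70, 585.0, 38.0, 0.09, 0.07, 0.10),
    SpectralModelParams(0.22, 0.62, 615.0, 48.0, 0.05, 0.04, 0.55),
    SpectralModelParams(0.16, 0.52, 645.0, 58.0, 0.025, 0.02, 1.25),
)
LESION_MODES: dict[str, SpectralModelParams] = {
    "benign": SpectralModelParams(0.10, 0.45, 675.0, 62.0, 0.04, 0.03, 1.9),
    "malignant": SpectralModelParams(0.06, 0.32, 725.0, 85.0, 0.015, 0.01, 2.9),
}

_REFLECTANCE_EPS = 1e-3


def make_spectrum(params: SpectralModelParams, wavelengths_nm: np.ndarray) -> np.ndarray:
    """Noise-free reflectance spectrum of one tissue mode, in (0, 1)."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-(lam - params.slope_center_nm) / params.slope_width_nm))
    curve = params.base_level + (params.nir_plateau - params.base_level) * rise
    curve = curve - params.dip_depth_542 * np.exp(-0.5 * ((lam - 542.0) / 12.0) ** 2)
    curve = curve - params.dip_depth_576 * np.exp(-0.5 * ((lam - 576.0) / 10.0) ** 2)
    curve = curve * np.exp(-params.melanin_scale * (500.0 / lam) ** 3)
    return np.clip(curve, _REFLECTANCE_EPS, 1.0 - _REFLECTANCE_EPS)


@dataclass(frozen=True)
class SceneConfig:
    """One capture: which skin phototype, whether a lesion is present and
    where, illumination non-uniformity amplitude, and sensor noise."""

    profile: InstrumentProfile = InstrumentProfile()
    skin_type: int = 0  # index into SKIN_MODES
    lesion_class: str = "none"  # none | benign | malignant
    lesion_radius_px: float = 10.0
    lesion_center: tuple[int, int] | None = None  # None -> grid center
    illumination_gradient: float = 0.1
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.skin_type < len(SKIN_MODES):
            raise ValueError(f"skin_type must index the {len(SKIN_MODES)} default modes")
        if self.lesion_class not in ("none", *LESION_MODES):
            raise ValueError(f"unknown lesion_class {self.lesion_class!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Scene:
    raw: HSCube
    refs: ReferenceFrames
    ground_truth: BinaryMask
    lesion_class: str
    reflectance: np.ndarray  # noisy per-pixel reflectance actually imaged


def _lesion_footprint(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    rows, cols = cfg.profile.spatial_rows, cfg.profile.spatial_cols
    cy, cx = cfg.lesion_center if cfg.lesion_center is not None else (rows // 2, cols // 2)
    r = cfg.lesion_radius_px
    # elliptical blob with a low-order harmonic boundary jitter
    aspect = rng.uniform(0.7, 1.0)
    theta0 = rng.uniform(0, 2 * np.pi)
    phases = rng.uniform(0, 2 * np.pi, size=2)
    amps = rng.uniform(0.03, 0.10, size=2)
    max_r = r * (1 + amps.sum())
    if cy - max_r < 0 or cy + max_r > rows - 1 or cx - max_r < 0 or cx + max_r > cols - 1:
        raise ValueError("lesion does not fit inside the grid")
    yy, xx = np.mgrid[0:rows, 0:cols]
    dy, dx = (yy - cy).astype(float), (xx - cx).astype(float)
    # rotate into the ellipse frame
    u = np.cos(theta0) * dx + np.sin(theta0) * dy
    v = -np.sin(theta0) * dx + np.cos(theta0) * dy
    dist = np.sqrt((u / 1.0) ** 2 + (v / aspect) ** 2)
    ang = np.arctan2(v, u)
    boundary = r * (1 + amps[0] * np.sin(2 * ang + phases[0]) + amps[1] * np.sin(3 * ang + phases[1]))
    return dist <= boundary


def make_scene(cfg: SceneConfig = SceneConfig()) -> Scene:
    """Generate one seeded capture: raw cube, reference frames, and the
    ground-truth lesion mask."""
    rng = np.random.default_rng(cfg.seed)
    profile = cfg.profile
    rows, cols = profile.spatial_rows, profile.spatial_cols
    lam = profile.wavelengths()

    if cfg.lesion_class == "none":
        footprint = np.zeros((rows, cols), dtype=bool)
    else:
        footprint = _lesion_footprint(cfg, rng)

    skin_spec = make_spectrum(SKIN_MODES[cfg.skin_type], lam)
    reflectance = np.broadcast_to(skin_spec, (rows, cols, lam.size)).copy()
    if footprint.any():
        reflectance[footprint] = make_spectrum(LESION_MODES[cfg.lesion_class], lam)
    reflectance = reflectance + rng.normal(0.0, cfg.noise_sd, size=reflectance.shape)
    reflectance = np.clip(reflectance, _REFLECTANCE_EPS, 1.0 - _REFLECTANCE_EPS)

    # smooth multiplicative illumination field (planar tilt), applied to
    # the white frame and the raw capture alike
    yy, xx = np.mgrid[0:rows, 0:cols]
    tilt = (yy / max(rows - 1, 1) - 0.5) + (xx / max(cols - 1, 1) - 0.5)
    illum = 1.0 + cfg.illumination_gradient * tilt  # in [1 - g, 1 + g]

    dark_counts = 100.0 + rng.normal(0.0, 2.0, size=(rows, cols, lam.size))
    # white tile ~99% reflective, high flat counts with a gentle spectral roll-off
    white_base = 3000.0 * (0.85 + 0.15 * np.exp(-0.5 * ((lam - 700.0) / 250.0) ** 2))
    white_counts = dark_counts + illum[:, :, None] * white_base
    raw_counts = dark_counts + reflectance * (white_counts - dark_counts)

    refs = ReferenceFrames(
        white=HSCube(white_counts, lam, CubeState.RAW),
        dark=HSCube(dark_counts, lam, CubeState.RAW),
    )
    return Scene(
        raw=HSCube(raw_counts, lam, CubeState.RAW),
        refs=refs,
        ground_truth=BinaryMask(footprint),
        lesion_class=cfg.lesion_class,
        reflectance=reflectance,
    )


def make_dataset(
    n_patients: int,
    images_per_patient: int = 1,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
    n_lesion_px: int = 100,
    n_skin_px: int = 100,
    profile: InstrumentProfile = InstrumentProfile(),
) -> tuple[list[Scene], LabeledSpectraSet]:
    """A cohort of seeded scenes plus a labeled-spectra table.

    Each patient keeps one skin phototype across their images; lesion
    classes are drawn from ``class_mix`` (default roughly the benign /
    malignant patient balance of a mixed clinical cohort, 43% / 57%).
    Labeled rows are *preprocessed* spectra sampled from the ground-truth
    lesion footprint and from the surrounding skin, tagged with patient
    and image identifiers.
    """
    from .preprocess import PreprocessConfig, preprocess_chain

    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if class_mix is None:
        class_mix = {"benign": 27 / 63, "malignant": 36 / 63}
    classes = list(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    pre_cfg = PreprocessConfig()
    scenes: list[Scene] = []
    spectra_rows, row_classes, row_patients, row_images = [], [], [], []
    wavelengths_out: np.ndarray | None = None

    for p in range(n_patients):
        patient_id = f"P{p:03d}"
        skin_type = int(rng.integers(0, len(SKIN_MODES)))
        for i in range(images_per_patient):
            image_id = f"{patient_id}_C{i + 1}"
            lesion_class = classes[int(rng.choice(len(classes), p=probs))]
            cfg = SceneConfig(
                profile=profile,
                skin_type=skin_type,
                lesion_class=lesion_class,
                lesion_radius_px=float(rng.uniform(7.0, 12.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            scene = make_scene(cfg)
            scenes.append(scene)

            pre = preprocess_chain(scene.raw, scene.refs, pre_cfg)
            wavelengths_out = pre.wavelengths_nm
            gt = scene.ground_truth.values
            lesion_idx = np.flatnonzero(gt.ravel())
            skin_idx = np.flatnonzero(~gt.ravel())
            pix = pre.pixels()
            take_lesion = rng.choice(
                lesion_idx, size=min(n_lesion_px, lesion_idx.size), replace=False
            )
            take_skin = rng.choice(
                skin_idx, size=min(n_skin_px, skin_idx.size), replace=False
            )
            for idx, cls in ((take_lesion, lesion_class), (take_skin, "skin")):
                for j in idx:
                    spectra_rows.append(pix[j])
                    row_classes.append(cls)
                    row_patients.append(patient_id)
                    row_images.append(image_id)

    labeled = LabeledSpectraSet(
        spectra=np.array(spectra_rows),
        classes=np.array(row_classes, dtype=object),
        patient_id=np.array(row_patients, dtype=object),
        image_id=np.array(row_images, dtype=object),
        wavelengths_nm=wavelengths_out,
    )
    return scenes, labeled
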