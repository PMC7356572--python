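"""Two-class (lesion vs. skin) segmentation of a preprocessed cube.

The cube's pixel spectra are clustered with K-means; each cluster is then
assigned to PSL or normal skin by Spectral Angle Mapper comparison
against the reference library, either of its centroid (per-centroid) or
of all its member pixels (per-pixel, summing the angles per library
entry).  A morphological closing plus small-component removal cleans the
resulting lesion mask.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from skimage.morphology import closing, footprint_rectangle, remove_small_objects
from sklearn.cluster import KMeans

from .hsio import CubeState, HSCube
from .labeling import sam_angles
from .library import ReferenceLibrary

__all__ = [
    "AssignMethod",
    "ClusterMap",
    "TwoClassMap",
    "SegmentationConfig",
    "kmeans_cluster",
    "assign_per_centroid",
    "assign_per_pixel",
    "postprocess_map",
    "segment_psl",
]


class AssignMethod(str, enum.Enum):
    PER_CENTROID = "per_centroid"
    PER_PIXEL = "per_pixel"


@dataclass
class ClusterMap:
    assignments: np.ndarray  # rows x cols, int in [0, K)
    centroids: np.ndarray  # K x bands
    K: int
    seed: int


@dataclass
class TwoClassMap:
    """Per-pixel PSL/skin map; True marks PSL pixels."""

    values: np.ndarray  # rows x cols bool, True = psl
    method: AssignMethod
    postprocessed: bool = False

    @property
    def n_psl(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class SegmentationConfig:
    """K=7 with per-pixel assignment is the validated default."""

    K: int = 7
    method: AssignMethod = AssignMethod.PER_PIXEL
    selem_size: int = 3
    min_component_px: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.selem_size % 2 == 0:
            raise ValueError("selem_size must be odd")


def kmeans_cluster(cube: HSCube, K: int, seed: int = 0) -> ClusterMap:
    """Seeded K-means over the cube's pixel spectra.

    Centroids are reordered by mean reflectance (ascending) and the
    assignment map relabeled accordingly, so cluster indices are
    reproducible; the indices themselves carry no class meaning.
    """
    rows, cols, _ = cube.shape
    n_pixels = rows * cols
    if K > n_pixels:
        raise ValueError("K exceeds pixel count")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(cube.pixels())
    order = np.argsort(km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(K)
    assignments = relabel[km.labels_].reshape(rows, cols)
    return ClusterMap(
        assignments=assignments,
        centroids=km.cluster_centers_[order],
        K=K,
        seed=seed,
    )


def _entry_class_is_psl(cls: str) -> bool:
    return cls in ("benign", "malignant")


def assign_per_centroid(clusters: ClusterMap, lib: ReferenceLibrary) -> TwoClassMap:
    """Label each cluster with the class of its SAM-nearest library entry.

    Ties break toward skin: on an ambiguous spectrum the conservative
    call is normal skin, avoiding inflated lesion area.
    """
    if len(lib) == 0:
        raise ValueError("empty reference library")
    psl_clusters = np.zeros(clusters.K, dtype=bool)
    for c in range(clusters.K):
        angles = sam_angles(lib.spectra, clusters.centroids[c])
        psl_clusters[c] = _argmin_is_psl(angles, lib.classes)
    return TwoClassMap(
        values=psl_clusters[clusters.assignments], method=AssignMethod.PER_CENTROID
    )


def assign_per_pixel(
    cube: HSCube, clusters: ClusterMap, lib: ReferenceLibrary
) -> TwoClassMap:
    """Label each cluster by the library entry with the smallest summed SAM
    over the cluster's member pixels.

    The sum is taken per library entry (not per class) so a class is not
    favored merely for having more entries.  Empty clusters are skipped.
    """
    if len(lib) == 0:
        raise ValueError("empty reference library")
    pixels = cube.pixels()
    flat = clusters.assignments.ravel()
    # angle of every pixel to every entry: (n_pixels, n_entries)
    angle_table = np.column_stack([sam_angles(pixels, ref) for ref in lib.spectra])
    psl_clusters = np.zeros(clusters.K, dtype=bool)
    for c in range(clusters.K):
        member = flat == c
        if not member.any():
            continue
        sums = angle_table[member].sum(axis=0)
        psl_clusters[c] = _argmin_is_psl(sums, lib.classes)
    return TwoClassMap(
        values=psl_clusters[clusters.assignments], method=AssignMethod.PER_PIXEL
    )


def _argmin_is_psl(scores: np.ndarray, classes: list[str]) -> bool:
    best = scores.min()
    winners = [classes[i] for i in np.flatnonzero(scores == best)]
    if any(not _entry_class_is_psl(cls) for cls in winners):
        return False  # tie toward skin
    return True


def postprocess_map(two_class: TwoClassMap, cfg: SegmentationConfig) -> TwoClassMap:
    """Morphological closing (dilation then erosion, square element) of the
    PSL layer, then removal of PSL connected components (8-connectivity)
    smaller than ``min_component_px``."""
    if two_class.postprocessed:
        raise ValueError("map already postprocessed")
    selem = footprint_rectangle((cfg.selem_size, cfg.selem_size))
    closed = closing(two_class.values, selem)
    # drop components strictly smaller than min_component_px
    cleaned = remove_small_objects(closed, max_size=cfg.min_component_px - 1, connectivity=2)
    return TwoClassMap(values=cleaned, method=two_class.method, postprocessed=True)


def segment_psl(
    cube: HSCube, lib: ReferenceLibrary, cfg: SegmentationConfig = SegmentationConfig()
) -> TwoClassMap:
    """Full segmentation: K-means -> SAM cluster assignment -> cleanup.

    Zero PSL pixels is a legal outcome (a lesion-free capture); callers
    decide whether to request reacquisition.
    """
    if cube.state is not CubeState.PREPROCESSED:
        raise ValueError("segmentation expects a preprocessed cube")
    clusters = kmeans_cluster(cube, cfg.K, cfg.seed)
    if cfg.method is AssignMethod.PER_PIXEL:
        two_class = assign_per_pixel(cube, clusters, lib)
    else:
        two_class = assign_per_centroid(clusters, lib)
    return postprocess_map(two_class, cfg)
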