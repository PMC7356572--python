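"""Reference spectral library construction.

The segmentation stage compares clusters against a small library of
reference signatures built from the labeled training set: the benign and
malignant entries are per-class means, and normal skin — which varies
with skin phototype — is summarized by the centroids of a K-means
clustering of the skin rows.  With the default three skin groups the
library holds five signatures.

The number of skin groups is chosen by running K-means over a range of K
and scoring each partition with three internal indices: silhouette and
Calinski-Harabasz (higher is better) and Davies-Bouldin (lower is
better).  Each index votes for its best K; the consensus is the most
frequent vote, ties resolved toward the smallest K.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .labeling import LabeledSpectraSet

__all__ = ["ReferenceLibrary", "KSelectionResult", "evaluate_k", "build_reference_library"]

INDEX_NAMES = ("silhouette", "calinski_harabasz", "davies_bouldin")


@dataclass
class ReferenceLibrary:
    """Named, class-tagged mean spectra on one wavelength grid.

    entries: list of (name, class, spectrum) with class in
    {'skin', 'benign', 'malignant'}; spectra on preprocessed [0, 1] scale.
    """

    entries: list[tuple[str, str, np.ndarray]]
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        names = [name for name, _, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("library entry names must be unique")
        for name, cls, spec in self.entries:
            if cls not in ("skin", "benign", "malignant"):
                raise ValueError(f"unknown class {cls!r} for entry {name!r}")
            if np.asarray(spec).shape != self.wavelengths_nm.shape:
                raise ValueError(f"entry {name!r} not on the library wavelength grid")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def spectra(self) -> np.ndarray:
        return np.vstack([np.asarray(s, dtype=float) for _, _, s in self.entries])

    @property
    def classes(self) -> list[str]:
        return [cls for _, cls, _ in self.entries]


@dataclass(frozen=True)
class KSelectionResult:
    per_method: dict[str, int]  # index name -> its optimal K
    consensus: int
    index_values: dict[str, dict[int, float]]  # index name -> {K: value}


def evaluate_k(
    data: np.ndarray, k_range: tuple[int, int] = (2, 7), seed: int = 0
) -> KSelectionResult:
    """Score seeded K-means partitions of ``data`` over an inclusive K range
    with the three internal cluster-validity indices and vote on K."""
    data = np.asarray(data, dtype=float)
    k_min, k_max = k_range
    if k_min < 2:
        raise ValueError("k_range minimum must be >= 2")
    if data.shape[0] <= k_max:
        raise ValueError("need more rows than the largest K")
    if np.allclose(data, data[0]):
        raise ValueError("degenerate data: all rows identical")

    index_values: dict[str, dict[int, float]] = {name: {} for name in INDEX_NAMES}
    for k in range(k_min, k_max + 1):
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(data)
        if len(np.unique(labels)) < 2:
            continue  # collapsed partition: indices undefined
        index_values["silhouette"][k] = float(silhouette_score(data, labels))
        index_values["calinski_harabasz"][k] = float(calinski_harabasz_score(data, labels))
        index_values["davies_bouldin"][k] = float(davies_bouldin_score(data, labels))

    per_method = {
        "silhouette": _argbest(index_values["silhouette"], maximize=True),
        "calinski_harabasz": _argbest(index_values["calinski_harabasz"], maximize=True),
        "davies_bouldin": _argbest(index_values["davies_bouldin"], maximize=False),
    }
    votes = Counter(per_method.values())
    top = max(votes.values())
    consensus = min(k for k, c in votes.items() if c == top)
    return KSelectionResult(per_method=per_method, consensus=consensus, index_values=index_values)


def _argbest(values: dict[int, float], maximize: bool) -> int:
    # ties toward smallest K
    best = max(values.values()) if maximize else min(values.values())
    return min(k for k, v in values.items() if v == best)


def build_reference_library(
    train: LabeledSpectraSet, k_skin: int = 3, seed: int = 0
) -> ReferenceLibrary:
    """Per-class mean signatures for the lesion classes plus ``k_skin``
    K-means centroids of the normal-skin rows.

    Skin centroids are ordered by mean reflectance so entry names are
    reproducible across runs with the same seed.
    """
    if k_skin < 1:
        raise ValueError("k_skin must be >= 1")
    for cls in ("skin", "benign", "malignant"):
        if not np.any(train.classes == cls):
            raise ValueError(f"training set lacks class {cls!r}")
    skin = train.of_class("skin")
    if k_skin == 1:
        centroids = skin.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k_skin, n_init=10, random_state=seed).fit(skin)
        centroids = km.cluster_centers_
    centroids = centroids[np.argsort(centroids.mean(axis=1))]
    entries: list[tuple[str, str, np.ndarray]] = [
        (f"skin_{i + 1}", "skin", centroids[i]) for i in range(k_skin)
    ]
    entries.append(("benign", "benign", train.of_class("benign").mean(axis=0)))
    entries.append(("malignant", "malignant", train.of_class("malignant").mean(axis=0)))
    return ReferenceLibrary(entries=entries, wavelengths_nm=train.wavelengths_nm)
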