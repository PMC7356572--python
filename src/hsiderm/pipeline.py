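"""End-to-end framework: preprocess -> segment -> classify -> decide.

A raw capture is calibrated and normalized, the lesion is segmented from
the surrounding skin, only the lesion pixels are sent to the supervised
classifier, and the lesion-level call is made from the fraction of
pixels predicted malignant: above the 40% risk threshold the lesion is
flagged malignant.  A capture in which no lesion pixels are found is not
an error — the system asks for a new acquisition.

Also here: the patient-stratified train/validation/test split, which
guarantees no patient contributes pixels to more than one set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classification import POSITIVE_CLASS, TrainedModel, predict
from .hsio import HSCube, ReferenceFrames
from .labeling import LabeledSpectraSet
from .library import ReferenceLibrary
from .preprocess import PreprocessConfig, preprocess_chain
from .segmentation import SegmentationConfig, TwoClassMap, segment_psl

__all__ = [
    "SplitSpec",
    "LesionDecision",
    "patient_stratified_split",
    "lesion_decision",
    "run_framework",
]

# default split fractions mirror a ~72/12/16 pixel partition
DEFAULT_FRACTIONS = (0.72, 0.12, 0.16)


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS  # train, val, test
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("all fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class LesionDecision:
    """Lesion-level output of the framework.

    status 'reacquire' means the segmentation found no lesion pixels and
    the capture should be repeated.  When status is 'ok', lesion_class is
    'malignant' iff malignant_fraction strictly exceeds the threshold.
    """

    status: str  # ok | reacquire
    lesion_class: str  # benign | malignant | none
    malignant_fraction: float
    mean_malignant_score: float
    n_psl_pixels: int
    threshold: float = 0.40
    pixel_labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    pixel_scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    two_class_map: TwoClassMap | None = None

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "lesion_class": self.lesion_class,
            "malignant_fraction": self.malignant_fraction,
            "mean_malignant_score": self.mean_malignant_score,
            "n_psl_pixels": self.n_psl_pixels,
            "threshold": self.threshold,
        }


def patient_stratified_split(
    data: LabeledSpectraSet, spec: SplitSpec = SplitSpec()
) -> tuple[LabeledSpectraSet, LabeledSpectraSet, LabeledSpectraSet]:
    """Split by patient so the three sets share no patients.

    Patients are shuffled with the spec seed and assigned greedily to the
    set whose pixel count is furthest below its target fraction.  The
    validation and test sets are seeded first with one patient carrying
    each lesion class (when such patients exist), so both non-training
    sets contain both classes whenever feasible.
    """
    patients = np.array(sorted(set(map(str, data.patient_id))))
    if patients.size < 3:
        raise ValueError("patient-stratified split needs >= 3 patients")
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(patients)

    pid = data.patient_id.astype(str)
    sizes = {p: int(np.sum(pid == p)) for p in patients}
    classes_of = {
        p: set(data.classes[pid == p]) & {"benign", "malignant"} for p in patients
    }
    total = len(data)
    targets = [f * total for f in spec.fractions]
    assigned: list[list[str]] = [[], [], []]
    counts = [0, 0, 0]
    remaining = list(patients)

    # seed each set with both lesion classes when feasible, training first
    # (it must carry every class to build a library / fit a classifier)
    for set_idx in (0, 1, 2):
        for cls in ("benign", "malignant"):
            have = set().union(*(classes_of[p] for p in assigned[set_idx])) if assigned[set_idx] else set()
            if cls in have:
                continue
            candidate = next((p for p in remaining if cls in classes_of[p]), None)
            if candidate is not None:
                assigned[set_idx].append(candidate)
                counts[set_idx] += sizes[candidate]
                remaining.remove(candidate)

    for p in remaining:
        deficit = [targets[i] - counts[i] for i in range(3)]
        i = int(np.argmax(deficit))
        assigned[i].append(p)
        counts[i] += sizes[p]

    out = []
    for members in assigned:
        mask = np.isin(pid, members)
        out.append(data.subset(mask))
    return tuple(out)


def lesion_decision(pixel_labels, threshold: float = 0.40) -> LesionDecision:
    """Lesion-level call from per-pixel class predictions.

    Empty input -> status 'reacquire'.  Otherwise the malignant pixel
    fraction is compared *strictly* against the risk threshold.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    labels = np.asarray(pixel_labels, dtype=object)
    if labels.size == 0:
        return LesionDecision(
            status="reacquire",
            lesion_class="none",
            malignant_fraction=0.0,
            mean_malignant_score=float("nan"),
            n_psl_pixels=0,
            threshold=threshold,
        )
    fraction = float(np.mean(labels == POSITIVE_CLASS))
    cls = POSITIVE_CLASS if fraction > threshold else "benign"
    return LesionDecision(
        status="ok",
        lesion_class=cls,
        malignant_fraction=fraction,
        mean_malignant_score=float("nan"),
        n_psl_pixels=int(labels.size),
        threshold=threshold,
        pixel_labels=labels,
    )


def run_framework(
    raw: HSCube,
    refs: ReferenceFrames,
    lib: ReferenceLibrary,
    model: TrainedModel,
    pre_cfg: PreprocessConfig = PreprocessConfig(),
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    threshold: float = 0.40,
) -> LesionDecision:
    """Full in-situ pipeline on one raw capture.

    Classification runs only on the pixels the segmentation marked as
    lesion; the decision carries the two-class map, per-pixel labels and
    scores for inspection.
    """
    pre = preprocess_chain(raw, refs, pre_cfg)
    if pre.wavelengths_nm.shape != lib.wavelengths_nm.shape or not np.allclose(
        pre.wavelengths_nm, lib.wavelengths_nm, atol=1e-4
    ):
        raise ValueError("library wavelength grid does not match the preprocessed cube")
    two_class = segment_psl(pre, lib, seg_cfg)
    psl_spectra = pre.pixels()[two_class.values.ravel()]
    labels, scores = predict(model, psl_spectra)
    decision = lesion_decision(labels, threshold)
    decision.pixel_scores = scores
    decision.two_class_map = two_class
    if decision.status == "ok":
        decision.mean_malignant_score = float(scores.mean())
    return decision
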