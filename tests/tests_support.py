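"""Shared helpers for the test suite."""

import numpy as np

from hsiderm.labeling import LabeledSpectraSet


def noisy_two_patient_split(seed=3, n_per_class=30, bands=6):
    """Overlapping two-class spectra on patient-disjoint train/val sets,
    hard enough that validation AUC varies with hyperparameters."""
    rng = np.random.default_rng(seed)

    def build(patients):
        benign = rng.normal(0.35, 0.25, (n_per_class, bands))
        malignant = rng.normal(0.6, 0.25, (n_per_class, bands))
        n = 2 * n_per_class
        return LabeledSpectraSet(
            spectra=np.vstack([benign, malignant]),
            classes=np.array(
                ["benign"] * n_per_class + ["malignant"] * n_per_class, dtype=object
            ),
            patient_id=np.array(
                [patients[i % len(patients)] for i in range(n)], dtype=object
            ),
            image_id=np.array([f"I{i}" for i in range(n)], dtype=object),
            wavelengths_nm=np.linspace(450, 950, bands),
        )

    return build(("A", "B")), build(("C", "D"))
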