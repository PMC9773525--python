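"""Disease classifier: symptom-status encoding -> probability distribution over diseases.

A two-layer feed-forward network (one rectified hidden layer plus softmax
output) over the 3n one-hot symptom-status encoding. The classifier is trained
once on fully-revealed records — every recorded symptom takes its recorded
status, everything else stays *unknown* — and is then frozen while the
investigation policies train, so credit assignment for investigation quality
stays with the policies. Unknown statuses at diagnosis time keep their own
indicator rather than collapsing to false: the agent's partial observation is
information the classifier should see.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier

from .dataset import DiagnosisDataset, PatientRecord
from .environment import STATUS_FALSE, STATUS_TRUE, encode_symptom_status

__all__ = ["DiseaseClassifier", "train_classifier", "predict_disease", "encode_record"]


def encode_record(record: PatientRecord, vocabulary: Sequence[str]) -> np.ndarray:
    """Fully-revealed 3n status encoding of a record (unrecorded symptoms unknown)."""
    pos = {s: i for i, s in enumerate(vocabulary)}
    status = np.zeros(len(vocabulary), dtype=np.int8)
    for s, v in record.symptom_status().items():
        status[pos[s]] = STATUS_TRUE if v else STATUS_FALSE
    return encode_symptom_status(status)


@dataclass
class DiseaseClassifier:
    """Frozen disease predictor over a fixed disease vocabulary."""

    symptom_vocabulary: list[str]
    disease_vocabulary: list[str]
    model: MLPClassifier | None
    train_accuracy: float
    _class_to_disease: list[int] = field(default_factory=list)

    def predict_proba(self, encoding: np.ndarray) -> np.ndarray:
        """Probabilities over the full disease vocabulary (unseen diseases get 0)."""
        encoding = np.asarray(encoding, dtype=np.float64)
        if encoding.shape[-1] != 3 * len(self.symptom_vocabulary):
            raise ValueError(
                f"encoding length {encoding.shape[-1]} does not match "
                f"3 * |symptoms| = {3 * len(self.symptom_vocabulary)}"
            )
        single = encoding.ndim == 1
        X = np.atleast_2d(encoding)
        probs = np.zeros((X.shape[0], len(self.disease_vocabulary)))
        if self.model is None:
            # degenerate single-class dataset: constant predictor
            probs[:, self._class_to_disease[0]] = 1.0
        else:
            p = self.model.predict_proba(X)
            for col, disease_idx in enumerate(self._class_to_disease):
                probs[:, disease_idx] = p[:, col]
        return probs[0] if single else probs


def _episode_reveal_encoding(
    record: PatientRecord,
    pos: dict[str, int],
    n_symptoms: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulated mid-dialogue observation of a record.

    Keeps the self-report, reveals each implicit symptom with probability 1/2,
    and adds a Poisson number of denials (unrecorded symptoms marked false) —
    the statuses an investigating agent actually produces, since the simulator
    denies every unrecorded symptom.
    """
    status = np.zeros(n_symptoms, dtype=np.int8)
    for s, v in record.explicit_symptoms.items():
        status[pos[s]] = STATUS_TRUE if v else STATUS_FALSE
    for s, v in record.implicit_symptoms.items():
        if rng.random() < 0.5:
            status[pos[s]] = STATUS_TRUE if v else STATUS_FALSE
    n_denials = int(rng.poisson(3.0))
    if n_denials:
        unknown = np.nonzero(status == 0)[0]
        denied = rng.choice(unknown, size=min(n_denials, len(unknown)),
                            replace=False)
        status[denied] = STATUS_FALSE
    return encode_symptom_status(status)


def train_classifier(
    dataset: DiagnosisDataset,
    epochs: int = 30,
    seed: int = 0,
    hidden: int = 256,
    reveal: str = "full",
) -> DiseaseClassifier:
    """Supervised fit on record encodings; deterministic given seed.

    ``reveal="full"`` trains on fully-revealed records only. ``reveal="episode"``
    additionally augments each record with a simulated partial observation
    (see :func:`_episode_reveal_encoding`), matching the statuses the
    investigating agent presents at diagnosis time.
    """
    if not dataset.records:
        raise ValueError("cannot train a classifier on an empty dataset")
    if reveal not in ("full", "episode"):
        raise ValueError("reveal must be 'full' or 'episode'")
    vocab = dataset.symptom_vocabulary
    disease_pos = {d: i for i, d in enumerate(dataset.disease_vocabulary)}
    X = np.stack([encode_record(r, vocab) for r in dataset.records])
    y = np.array([disease_pos[r.disease] for r in dataset.records])
    if reveal == "episode":
        pos = {s: i for i, s in enumerate(vocab)}
        rng = np.random.default_rng(seed)
        X_aug = np.stack([
            _episode_reveal_encoding(r, pos, len(vocab), rng)
            for r in dataset.records
        ])
        X = np.concatenate([X, X_aug])
        y = np.concatenate([y, y])

    classes = np.unique(y)
    if len(classes) == 1:
        warnings.warn(
            "training dataset contains a single disease; classifier degenerates "
            "to a constant predictor",
            UserWarning,
        )
        return DiseaseClassifier(
            symptom_vocabulary=list(vocab),
            disease_vocabulary=list(dataset.disease_vocabulary),
            model=None,
            train_accuracy=1.0,
            _class_to_disease=[int(classes[0])],
        )

    model = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="relu",
        solver="adam",
        max_iter=epochs,
        random_state=seed,
        alpha=1e-4,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    acc = float(np.mean(model.predict(X) == y))
    return DiseaseClassifier(
        symptom_vocabulary=list(vocab),
        disease_vocabulary=list(dataset.disease_vocabulary),
        model=model,
        train_accuracy=acc,
        _class_to_disease=[int(c) for c in model.classes_],
    )


def predict_disease(
    model: DiseaseClassifier, encoding: np.ndarray
) -> list[tuple[str, float]]:
    """Full disease ranking (descending probability; ties by vocabulary index)."""
    probs = model.predict_proba(encoding)
    n = len(probs)
    order = np.lexsort((np.arange(n), -probs))
    return [(model.disease_vocabulary[i], float(probs[i])) for i in order]
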