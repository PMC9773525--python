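"""Shared fixtures: hand-checkable toy graphs, printed case-study records, builders."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from symdiag.association import build_cooccurrence
from symdiag.dataset import DiagnosisDataset, PatientRecord

# Vocabulary covering the published case-study dialogues used as fixtures.
CASE_VOCABULARY = [
    "arm pain",
    "loss of sensation",
    "hand or finger pain",
    "wrist pain",
    "neck pain",
    "sharp abdominal pain",
    "pain during pregnancy",
    "facial pain",
    "fatigue",
    "ache all over",
    "headache",
    "back pain",
    "paresthesia",
    "leg pain",
    "skin itching",
    "skin lesion",
    "skin rash",
    "eye pain",
    "anxiety and nervousness",
    "lower body pain",
    "lower back pain",
    "excessive urination at night",
    "shoulder cramps or spasms",
    "abnormal appearing skin",
    "difficulty in breathing",
    "shortness of breath",
    "vomiting",
    "nausea",
    "cough",
]

CASE_DISEASES = {
    "carpal tunnel syndrome": "group_6",
    "adhesive capsulitis of the shoulder": "group_6",
    "gas gangrene": "group_1",
    "chancroid": "group_1",
    "fluid overload": "group_7",
}


def make_case_dataset() -> DiagnosisDataset:
    """The two published diagnosis test cases (ids 13947 and 22285) as records."""
    rec_13947 = PatientRecord(
        record_id="13947",
        disease="carpal tunnel syndrome",
        group="group_6",
        explicit_symptoms={"arm pain": True},
        implicit_symptoms={
            "loss of sensation": True,
            "hand or finger pain": True,
            "wrist pain": True,
            "neck pain": True,
        },
    )
    rec_22285 = PatientRecord(
        record_id="22285",
        disease="gas gangrene",
        group="group_1",
        explicit_symptoms={"wrist pain": True},
        implicit_symptoms={
            "sharp abdominal pain": True,
            "pain during pregnancy": True,
            "facial pain": True,
            "fatigue": True,
        },
    )
    return DiagnosisDataset(
        records=[rec_13947, rec_22285],
        symptom_vocabulary=list(CASE_VOCABULARY),
        disease_vocabulary=list(CASE_DISEASES),
        group_map=dict(CASE_DISEASES),
    )


@pytest.fixture
def case_dataset() -> DiagnosisDataset:
    return make_case_dataset()


@pytest.fixture
def case_graph(case_dataset):
    return build_cooccurrence(case_dataset)


def make_four_record_dataset() -> DiagnosisDataset:
    """True-symptom sets {A,B}, {A,B,C}, {A,C}, {B,C}: pair counts all equal 2.

    Symptom D never occurs, exercising the zero-row convention.
    """
    sets = [["A", "B"], ["A", "B", "C"], ["A", "C"], ["B", "C"]]
    records = [
        PatientRecord(
            record_id=f"r{i}",
            disease="d0",
            group="g0",
            explicit_symptoms={s[0]: True},
            implicit_symptoms={x: True for x in s[1:]},
        )
        for i, s in enumerate(sets)
    ]
    return DiagnosisDataset(
        records=records,
        symptom_vocabulary=["A", "B", "C", "D"],
        disease_vocabulary=["d0"],
        group_map={"d0": "g0"},
    )


@pytest.fixture
def four_record_dataset() -> DiagnosisDataset:
    return make_four_record_dataset()


@pytest.fixture
def four_record_graph(four_record_dataset):
    return build_cooccurrence(four_record_dataset)


def make_separable_dataset(
    n_groups: int = 3,
    diseases_per_group: int = 3,
    records_per_disease: int = 40,
    seed: int = 0,
) -> DiagnosisDataset:
    """Fully separable corpus: every disease owns a disjoint 3-symptom profile.

    Each record self-reports one profile symptom and hides the other two as
    implicit truths, so a greedy oracle diagnoses with certainty.
    """
    rng = np.random.default_rng(seed)
    n_diseases = n_groups * diseases_per_group
    symptoms = [f"s_{i:03d}" for i in range(3 * n_diseases)]
    diseases, group_map, profiles = [], {}, {}
    for g in range(n_groups):
        for d in range(diseases_per_group):
            idx = g * diseases_per_group + d
            name = f"dis_{g}_{d}"
            diseases.append(name)
            group_map[name] = f"grp_{g}"
            profiles[name] = symptoms[3 * idx : 3 * idx + 3]
    records = []
    for r in range(n_diseases * records_per_disease):
        disease = diseases[r % n_diseases]
        profile = list(profiles[disease])
        pick = int(rng.integers(0, 3))
        explicit = {profile[pick]: True}
        implicit = {s: True for i, s in enumerate(profile) if i != pick}
        records.append(PatientRecord(
            record_id=f"sep_{r:05d}",
            disease=disease,
            group=group_map[disease],
            explicit_symptoms=explicit,
            implicit_symptoms=implicit,
        ))
    return DiagnosisDataset(
        records=records,
        symptom_vocabulary=symptoms,
        disease_vocabulary=diseases,
        group_map=group_map,
    )


@pytest.fixture(scope="session")
def separable_dataset() -> DiagnosisDataset:
    return make_separable_dataset()


@pytest.fixture(scope="session")
def transcripts_path() -> Path:
    return Path(__file__).parent / "data" / "transcripts.json"
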