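"""Patient-record data model, on-disk dataset format, and synthetic corpus generator.

A diagnosis corpus is a collection of patient records, each carrying a disease
label, the disease's group (medical department), the symptoms the patient
volunteers at the start of a consultation (*explicit* symptoms, the self-report)
and the symptoms only discoverable by questioning (*implicit* symptoms), each
with a true/false status.

The synthetic generator emulates the structure of the public SD benchmark
corpus: 9 disease groups of 10 diseases each over a 266-symptom vocabulary,
one self-reported symptom per record and 2.6 implicit symptoms on average.
Each disease owns a fixed symptom profile drawn from its group's symptom pool;
cross-disease overlap (shared "common" symptoms) is the main source of
diagnostic confusion and is controlled by ``group_symptom_overlap``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "PatientRecord",
    "DiagnosisDataset",
    "GeneratorConfig",
    "DatasetStatistics",
    "DatasetFormatError",
    "GeneratorConfigError",
    "generate_synthetic_dataset",
    "read_dataset",
    "write_dataset",
    "split_dataset",
    "dataset_statistics",
]


class DatasetFormatError(ValueError):
    """Raised when an on-disk dataset or a record violates the format contract."""


class GeneratorConfigError(ValueError):
    """Raised for an inconsistent synthetic-generator configuration."""


@dataclass(frozen=True)
class PatientRecord:
    """One diagnosis case.

    ``explicit_symptoms`` is the patient self-report (PSR); ``implicit_symptoms``
    are discoverable only by querying. Both map symptom identifier -> bool
    status. The two key sets are disjoint and at least one explicit symptom is
    always present.
    """

    record_id: str
    disease: str
    group: str
    explicit_symptoms: dict[str, bool]
    implicit_symptoms: dict[str, bool]

    def symptom_status(self) -> dict[str, bool]:
        """Merged explicit + implicit status map."""
        merged = dict(self.explicit_symptoms)
        merged.update(self.implicit_symptoms)
        return merged

    def true_symptoms(self) -> set[str]:
        """All symptoms (explicit or implicit) recorded with status true."""
        return {s for s, v in self.symptom_status().items() if v}

    def true_implicit_symptoms(self) -> set[str]:
        return {s for s, v in self.implicit_symptoms.items() if v}

    def self_report(self) -> set[str]:
        """Status-true explicit symptoms (the PSR anchor set)."""
        return {s for s, v in self.explicit_symptoms.items() if v}


@dataclass
class DiagnosisDataset:
    """Ordered records plus the vocabularies that define index positions.

    Vocabulary orderings are part of the persisted format: symptom index
    positions feed the state encoding and the co-occurrence table, so they must
    be stable across save/load.
    """

    records: list[PatientRecord]
    symptom_vocabulary: list[str]
    disease_vocabulary: list[str]
    group_map: dict[str, str]

    @property
    def groups(self) -> list[str]:
        """Group identifiers ordered by first appearance in the disease vocabulary."""
        seen: list[str] = []
        for d in self.disease_vocabulary:
            g = self.group_map[d]
            if g not in seen:
                seen.append(g)
        return seen

    def validate(self) -> None:
        if len(set(self.symptom_vocabulary)) != len(self.symptom_vocabulary):
            raise DatasetFormatError("duplicate entries in symptom vocabulary")
        if len(set(self.disease_vocabulary)) != len(self.disease_vocabulary):
            raise DatasetFormatError("duplicate entries in disease vocabulary")
        missing = set(self.disease_vocabulary) - set(self.group_map)
        if missing:
            raise DatasetFormatError(f"diseases without group assignment: {sorted(missing)}")
        vocab = set(self.symptom_vocabulary)
        seen_ids: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen_ids:
                raise DatasetFormatError(f"duplicate record id {rec.record_id!r}")
            seen_ids.add(rec.record_id)
            if rec.disease not in self.group_map:
                raise DatasetFormatError(
                    f"record {rec.record_id!r}: unknown disease {rec.disease!r}"
                )
            if rec.group != self.group_map[rec.disease]:
                raise DatasetFormatError(
                    f"record {rec.record_id!r}: group {rec.group!r} does not match "
                    f"disease group {self.group_map[rec.disease]!r}"
                )
            overlap = set(rec.explicit_symptoms) & set(rec.implicit_symptoms)
            if overlap:
                raise DatasetFormatError(
                    f"record {rec.record_id!r}: symptoms both explicit and implicit: "
                    f"{sorted(overlap)}"
                )
            if not rec.explicit_symptoms:
                raise DatasetFormatError(f"record {rec.record_id!r}: no explicit symptom")
            unknown = (set(rec.explicit_symptoms) | set(rec.implicit_symptoms)) - vocab
            if unknown:
                raise DatasetFormatError(
                    f"record {rec.record_id!r}: symptoms not in vocabulary: {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiagnosisDataset):
            return NotImplemented
        return (
            self.records == other.records
            and self.symptom_vocabulary == other.symptom_vocabulary
            and self.disease_vocabulary == other.disease_vocabulary
            and self.group_map == other.group_map
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-corpus configuration; defaults emulate the SD benchmark statistics.

    ``mean_explicit``/``mean_implicit`` are expected per-record symptom counts
    (records always keep at least one explicit symptom). ``group_symptom_overlap``
    is the fraction of the vocabulary shared across all group pools — shared
    common symptoms create the cross-disease confusion real corpora show.
    ``negative_implicit_rate`` is the fraction of implicit entries recorded with
    status false (negated findings); 0 by default.
    """

    n_groups: int = 9
    diseases_per_group: int = 10
    n_symptoms: int = 266
    group_symptom_overlap: float = 0.15
    mean_explicit: float = 1.0
    mean_implicit: float = 2.6
    disease_symptom_profile_size: int = 12
    negative_implicit_rate: float = 0.0
    n_records: int = 30000
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_groups", "diseases_per_group", "n_symptoms",
                     "disease_symptom_profile_size", "n_records"):
            if getattr(self, name) <= 0:
                raise GeneratorConfigError(f"{name} must be positive")
        for name in ("group_symptom_overlap", "negative_implicit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorConfigError(f"{name} must lie in [0, 1]")
        if self.mean_explicit < 1.0:
            raise GeneratorConfigError("mean_explicit must be >= 1")
        if self.mean_implicit < 0.0:
            raise GeneratorConfigError("mean_implicit must be nonnegative")
        if self.disease_symptom_profile_size < self.mean_explicit + self.mean_implicit:
            raise GeneratorConfigError(
                "disease_symptom_profile_size smaller than mean_explicit + mean_implicit"
            )
        n_common = int(round(self.group_symptom_overlap * self.n_symptoms))
        per_group = (self.n_symptoms - n_common) // self.n_groups
        if per_group + n_common < self.disease_symptom_profile_size:
            raise GeneratorConfigError(
                "group symptom pools smaller than disease_symptom_profile_size"
            )


def _count_around(mean: float, rng: np.random.Generator, minimum: int) -> int:
    # 1 + Poisson(mean - 1) keeps the exact configured mean while enforcing the
    # minimum; for mean == minimum the count is deterministic.
    lam = mean - minimum
    if lam <= 0:
        return minimum
    return minimum + int(rng.poisson(lam))


def generate_synthetic_dataset(config: GeneratorConfig) -> DiagnosisDataset:
    """Generate a deterministic synthetic diagnosis corpus.

    Every disease gets a fixed symptom profile sampled once (without
    replacement) from its group pool; every record samples its explicit and
    implicit symptoms from its disease's profile, with counts drawn around the
    configured means. Record counts per disease are balanced. The output is a
    pure function of the config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    symptoms = [f"symptom_{i:03d}" for i in range(config.n_symptoms)]
    perm = rng.permutation(config.n_symptoms)
    n_common = int(round(config.group_symptom_overlap * config.n_symptoms))
    common = perm[:n_common]
    rest = perm[n_common:]
    per_group = len(rest) // config.n_groups

    diseases: list[str] = []
    group_map: dict[str, str] = {}
    profiles: dict[str, list[str]] = {}
    for g in range(config.n_groups):
        group_id = f"group_{g}"
        own = rest[g * per_group:(g + 1) * per_group]
        pool = np.concatenate([own, common])
        for d in range(config.diseases_per_group):
            disease_id = f"disease_{g}_{d:02d}"
            diseases.append(disease_id)
            group_map[disease_id] = group_id
            picked = rng.choice(pool, size=config.disease_symptom_profile_size,
                                replace=False)
            profiles[disease_id] = [symptoms[i] for i in picked]

    records: list[PatientRecord] = []
    n_diseases = len(diseases)
    for r in range(config.n_records):
        disease = diseases[r % n_diseases]
        profile = profiles[disease]
        n_exp = _count_around(config.mean_explicit, rng, minimum=1)
        n_imp = _count_around(config.mean_implicit, rng, minimum=0)
        n_exp = min(n_exp, len(profile))
        n_imp = min(n_imp, len(profile) - n_exp)
        chosen = rng.choice(len(profile), size=n_exp + n_imp, replace=False)
        explicit = {profile[i]: True for i in chosen[:n_exp]}
        implicit = {}
        for i in chosen[n_exp:]:
            status = not (config.negative_implicit_rate > 0.0
                          and rng.random() < config.negative_implicit_rate)
            implicit[profile[i]] = status
        records.append(PatientRecord(
            record_id=f"rec_{r:06d}",
            disease=disease,
            group=group_map[disease],
            explicit_symptoms=explicit,
            implicit_symptoms=implicit,
        ))

    dataset = DiagnosisDataset(
        records=records,
        symptom_vocabulary=symptoms,
        disease_vocabulary=diseases,
        group_map=group_map,
    )
    dataset.validate()
    return dataset


def _dataset_to_obj(dataset: DiagnosisDataset) -> dict:
    return {
        "symptoms": list(dataset.symptom_vocabulary),
        "diseases": [
            {"id": d, "group": dataset.group_map[d]} for d in dataset.disease_vocabulary
        ],
        "records": [
            {
                "record_id": rec.record_id,
                "disease": rec.disease,
                "explicit": dict(rec.explicit_symptoms),
                "implicit": dict(rec.implicit_symptoms),
            }
            for rec in dataset.records
        ],
    }


def write_dataset(dataset: DiagnosisDataset, path: str | Path) -> None:
    """Write the canonical (key-sorted) JSON serialization; diff-able and hashable."""
    dataset.validate()
    text = json.dumps(_dataset_to_obj(dataset), sort_keys=True, ensure_ascii=False,
                      separators=(",", ": "), indent=1)
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_dataset(path: str | Path) -> DiagnosisDataset:
    """Read a dataset file; round-trips with :func:`write_dataset`."""
    try:
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise DatasetFormatError(f"malformed JSON in {path}: {exc}") from exc
    for key in ("symptoms", "diseases", "records"):
        if key not in obj:
            raise DatasetFormatError(f"missing top-level key {key!r} in {path}")
    group_map = {d["id"]: d["group"] for d in obj["diseases"]}
    records = []
    for raw in obj["records"]:
        try:
            rec = PatientRecord(
                record_id=raw["record_id"],
                disease=raw["disease"],
                group=group_map.get(raw["disease"], ""),
                explicit_symptoms={s: bool(v) for s, v in raw["explicit"].items()},
                implicit_symptoms={s: bool(v) for s, v in raw["implicit"].items()},
            )
        except KeyError as exc:
            raise DatasetFormatError(f"record missing field {exc} in {path}") from exc
        records.append(rec)
    dataset = DiagnosisDataset(
        records=records,
        symptom_vocabulary=list(obj["symptoms"]),
        disease_vocabulary=[d["id"] for d in obj["diseases"]],
        group_map=group_map,
    )
    dataset.validate()
    return dataset


def split_dataset(
    dataset: DiagnosisDataset, train_fraction: float, seed: int
) -> tuple[DiagnosisDataset, DiagnosisDataset]:
    """Deterministic shuffled train/test partition sharing the full vocabularies."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset.records))
    n_train = int(len(order) * train_fraction)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])

    def subset(idx: list[int]) -> DiagnosisDataset:
        return DiagnosisDataset(
            records=[dataset.records[i] for i in idx],
            symptom_vocabulary=list(dataset.symptom_vocabulary),
            disease_vocabulary=list(dataset.disease_vocabulary),
            group_map=dict(dataset.group_map),
        )

    return subset(train_idx), subset(test_idx)


@dataclass(frozen=True)
class DatasetStatistics:
    """Corpus summary counts (diseases, groups, symptoms, per-record means)."""

    n_records: int
    n_diseases: int
    n_groups: int
    n_symptoms: int
    mean_explicit: Optional[float]
    mean_implicit: Optional[float]
    records_per_group: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_diseases": self.n_diseases,
            "n_groups": self.n_groups,
            "n_symptoms": self.n_symptoms,
            "mean_explicit": self.mean_explicit,
            "mean_implicit": self.mean_implicit,
            "records_per_group": dict(self.records_per_group),
        }


def dataset_statistics(dataset: DiagnosisDataset) -> DatasetStatistics:
    """Summary counts; means are None for an empty record list."""
    per_group: dict[str, int] = {g: 0 for g in dataset.groups}
    for rec in dataset.records:
        per_group[rec.group] = per_group.get(rec.group, 0) + 1
    n = len(dataset.records)
    mean_exp = mean_imp = None
    if n:
        mean_exp = sum(len(r.explicit_symptoms) for r in dataset.records) / n
        mean_imp = sum(len(r.implicit_symptoms) for r in dataset.records) / n
    return DatasetStatistics(
        n_records=n,
        n_diseases=len(dataset.disease_vocabulary),
        n_groups=len(dataset.groups),
        n_symptoms=len(dataset.symptom_vocabulary),
        mean_explicit=mean_exp,
        mean_implicit=mean_imp,
        records_per_group=per_group,
    )
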