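"""Labeled gesture samples and dataset containers.

A :class:`GestureSample` carries a landmark set and/or its 29-element
feature vector together with its gesture label (0-5), palsy grade, subject
id, and provenance.  Provenance distinguishes original frames from rotated
augmentation copies and names the original they came from, which is what
the group-aware cross-validation splitter keys on.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, N_FEATURES
from .landmarks import InvalidLandmarksError, LandmarkSet

__all__ = [
    "GESTURE_NAMES",
    "N_CLASSES",
    "PALSY_GRADES",
    "Provenance",
    "GestureSample",
    "GestureDataset",
]

N_CLASSES = 6
GESTURE_NAMES: tuple[str, ...] = (
    "rest",
    "eyebrow_elevation",
    "eye_closure",
    "wide_open_smile",
    "closed_mouth_smile",
    "pucker",
)

#: Severity annotation bands, mildest to most affected.
PALSY_GRADES: tuple[str, ...] = (
    "normal", "near-normal", "mild", "moderate", "severe", "complete",
)


@dataclasses.dataclass(frozen=True)
class Provenance:
    """Where a sample came from: its original frame id and, for augmented
    copies, the signed rotation angle applied (0 for originals)."""

    original_id: str
    angle_deg: float = 0.0

    @property
    def is_original(self) -> bool:
        return self.angle_deg == 0.0


@dataclasses.dataclass(frozen=True)
class GestureSample:
    label: int
    grade: str
    subject: str
    provenance: Provenance
    landmarks: LandmarkSet | None = None
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 <= int(self.label) < N_CLASSES):
            raise ValueError(f"gesture label must be 0..{N_CLASSES - 1}, got {self.label}")
        if self.features is not None:
            fv = np.asarray(self.features, dtype=float)
            if fv.shape != (N_FEATURES,):
                raise InvalidLandmarksError(
                    f"feature vector must have length {N_FEATURES}, got {fv.shape}"
                )
            object.__setattr__(self, "features", fv)

    def replace(self, **kw) -> "GestureSample":
        return dataclasses.replace(self, **kw)


class GestureDataset:
    """An ordered collection of gesture samples."""

    def __init__(self, samples: Iterable[GestureSample] = ()):
        self.samples: list[GestureSample] = list(samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[GestureSample]:
        return iter(self.samples)

    def __getitem__(self, idx) -> GestureSample:
        return self.samples[idx]

    def subset(self, indices: Sequence[int]) -> "GestureDataset":
        return GestureDataset(self.samples[i] for i in indices)

    def filter_grade(self, grade: str) -> "GestureDataset":
        return GestureDataset(s for s in self.samples if s.grade == grade)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    @property
    def grades(self) -> list[str]:
        return [s.grade for s in self.samples]

    @property
    def groups(self) -> list[str]:
        """Group key for CV: all rotated copies share their original's id."""
        return [s.provenance.original_id for s in self.samples]

    def feature_matrix(self) -> np.ndarray:
        if any(s.features is None for s in self.samples):
            raise ValueError("dataset contains samples without extracted features")
        return np.stack([s.features for s in self.samples])

    def class_counts(self) -> dict[int, int]:
        counts = dict.fromkeys(range(N_CLASSES), 0)
        for s in self.samples:
            counts[s.label] += 1
        return counts

    # ------------------------------------------------------------------
    # feature-table interchange (CSV via pandas; ARFF lives in .arff)

    def to_frame(self) -> pd.DataFrame:
        X = self.feature_matrix()
        df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
        df["label"] = self.labels
        df["grade"] = self.grades
        df["subject"] = [s.subject for s in self.samples]
        df["provenance"] = [
            f"{s.provenance.original_id}@{s.provenance.angle_deg:g}" for s in self.samples
        ]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GestureDataset":
        missing = [c for c in FEATURE_NAMES if c not in df.columns]
        if missing:
            raise ValueError(f"feature table is missing columns {missing}")
        samples = []
        for _, row in df.iterrows():
            prov = str(row.get("provenance", ""))
            if "@" in prov:
                oid, angle = prov.rsplit("@", 1)
                provenance = Provenance(oid, float(angle))
            else:
                provenance = Provenance(prov or str(row.name))
            samples.append(
                GestureSample(
                    label=int(row["label"]),
                    grade=str(row.get("grade", "")),
                    subject=str(row.get("subject", "")),
                    provenance=provenance,
                    features=row[list(FEATURE_NAMES)].to_numpy(dtype=float),
                )
            )
        return cls(samples)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GestureDataset":
        return cls.from_frame(pd.read_csv(path))

    # ------------------------------------------------------------------
    # landmark-record interchange (JSON)

    def to_landmark_records(self) -> list[dict]:
        from .landmarks import landmarks_to_dict

        records = []
        for s in self.samples:
            if s.landmarks is None:
                raise ValueError("dataset contains samples without landmarks")
            rec = landmarks_to_dict(s.landmarks, label=s.label, grade=s.grade,
                                    subject=s.subject)
            rec["provenance"] = {
                "original_id": s.provenance.original_id,
                "angle_deg": s.provenance.angle_deg,
            }
            records.append(rec)
        return records

    @classmethod
    def from_landmark_records(cls, records: list[dict]) -> "GestureDataset":
        from .landmarks import landmarks_from_dict

        samples = []
        for i, rec in enumerate(records):
            prov = rec.get("provenance", {})
            samples.append(
                GestureSample(
                    label=int(rec["label"]),
                    grade=str(rec.get("grade", "")),
                    subject=str(rec.get("subject", "")),
                    provenance=Provenance(
                        str(prov.get("original_id", rec.get("subject", str(i)))),
                        float(prov.get("angle_deg", 0.0)),
                    ),
                    landmarks=landmarks_from_dict(rec),
                )
            )
        return cls(samples)
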