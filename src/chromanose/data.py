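"""Core sample/dataset containers shared by every stage of the pipeline.

A *sample* is one colorimetric measurement: the 3N-dimensional color-change
profile of an N-spot dye array exposed to a minced-meat headspace, together
with its adulteration level (pork mass fraction in beef, in [0, 1]) and the
three-way category label used for classification.

Feature ordering is channel-major throughout the package: all ΔR values for
spots 1..N (row-major grid order), then all ΔG, then all ΔB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

#: Fixed category ordering; also the tie-break order used by every classifier.
CLASS_ORDER: tuple[str, str, str] = ("pure_beef", "mixture", "pure_pork")

_CHANNELS = "RGB"
_META_COLUMNS = ("sample_id", "level", "category")


def category_for_level(level: float) -> str:
    """Map an adulteration fraction to its category label.

    0 is pure beef, 1 is pure pork, everything strictly between is a
    beef–pork mixture.
    """
    if not 0.0 <= level <= 1.0:
        raise DomainError(f"adulteration level must lie in [0, 1], got {level!r}")
    if level == 0.0:
        return "pure_beef"
    if level == 1.0:
        return "pure_pork"
    return "mixture"


def feature_columns(n_spots: int = 12) -> list[str]:
    """Channel-major feature-column names: dye01_dR..dyeNN_dR, then G, then B."""
    return [f"dye{d:02d}_d{ch}" for ch in _CHANNELS for d in range(1, n_spots + 1)]


@dataclass
class Sample:
    """One measured (or simulated) sensor-array response."""

    sample_id: str
    values: np.ndarray  # length 3*n_spots, channel-major, entries in [0, 255]
    level: float
    category: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size % 3 != 0:
            raise DomainError(
                f"profile length must be a multiple of 3, got {self.values.size}"
            )
        expected = category_for_level(self.level)
        if not self.category:
            self.category = expected
        elif self.category != expected:
            raise DomainError(
                f"category {self.category!r} inconsistent with level {self.level}"
                f" (expected {expected!r})"
            )

    @property
    def n_spots(self) -> int:
        return self.values.size // 3


@dataclass
class Dataset:
    """An ordered collection of samples with homogeneous feature arity."""

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        arities = {s.n_spots for s in self.samples}
        if len(arities) > 1:
            raise DomainError(f"mixed spot counts in dataset: {sorted(arities)}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def n_spots(self) -> int:
        if not self.samples:
            raise DomainError("empty dataset has no spot count")
        return self.samples[0].n_spots

    @property
    def X(self) -> np.ndarray:
        """Feature matrix, one row per sample (n_samples × 3N)."""
        return np.vstack([s.values for s in self.samples])

    @property
    def levels(self) -> np.ndarray:
        return np.array([s.level for s in self.samples])

    @property
    def categories(self) -> list[str]:
        return [s.category for s in self.samples]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset(self, ids: Iterable[str]) -> "Dataset":
        wanted = set(ids)
        return Dataset([s for s in self.samples if s.sample_id in wanted])

    def to_frame(self) -> pd.DataFrame:
        cols = feature_columns(self.n_spots)
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "category", self.categories)
        df.insert(0, "level", self.levels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        missing_meta = [c for c in _META_COLUMNS if c not in df.columns]
        if missing_meta:
            raise FormatError(f"missing metadata columns: {missing_meta}")
        feat_cols = [c for c in df.columns if c not in _META_COLUMNS]
        if not feat_cols or len(feat_cols) % 3 != 0:
            raise FormatError(
                f"feature column count must be a positive multiple of 3, "
                f"got {len(feat_cols)}: cannot form ΔR/ΔG/ΔB blocks"
            )
        n_spots = len(feat_cols) // 3
        expected = feature_columns(n_spots)
        missing = sorted(set(expected) - set(feat_cols))
        extra = sorted(set(feat_cols) - set(expected))
        if missing or extra:
            raise FormatError(
                f"feature columns do not match the {n_spots}-spot schema; "
                f"missing={missing}, unexpected={extra}"
            )
        samples = [
            Sample(
                sample_id=str(row["sample_id"]),
                values=row[expected].to_numpy(dtype=float),
                level=float(row["level"]),
                category=str(row["category"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(samples)


def one_hot(labels: Sequence[str], class_order: Sequence[str] = CLASS_ORDER) -> np.ndarray:
    """0/1 class-coding matrix (n_samples × n_classes) in ``class_order``."""
    index = {c: j for j, c in enumerate(class_order)}
    unknown = [lab for lab in labels if lab not in index]
    if unknown:
        raise DomainError(f"labels not in class order {tuple(class_order)}: {unknown}")
    T = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        T[i, index[lab]] = 1.0
    return T
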