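"""Specimen records and datasets of 3D landmark configurations.

Coordinates are stored as ``(n_landmarks, 3)`` float arrays in mm; a missing
point is a row of NaN (a point is either fully present or fully missing —
partial coordinates are normalised to missing on construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .scheme import GROUPS, SEX_VALUES, LandmarkScheme


class ValidationError(ValueError):
    """A record or dataset violates its scheme contract."""


@dataclass
class SpecimenRecord:
    """One specimen: identifier, metadata and a landmark configuration."""
    specimen_id: str
    group: str
    sex: str
    coords: np.ndarray  # (k, 3), NaN rows mark missing landmarks
    imputed: Optional[np.ndarray] = None  # bool mask of imputed points

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(
                f"{self.specimen_id}: coords must be (k, 3), got {self.coords.shape}")
        if self.group not in GROUPS:
            raise ValidationError(
                f"{self.specimen_id}: unknown group label {self.group!r}")
        if self.sex not in SEX_VALUES:
            raise ValidationError(f"{self.specimen_id}: unknown sex {self.sex!r}")
        # normalise partially-recorded points to fully missing
        partial = np.isnan(self.coords).any(axis=1)
        self.coords[partial] = np.nan
        finite = self.coords[~partial]
        if not np.isfinite(finite).all():
            raise ValidationError(f"{self.specimen_id}: non-finite coordinates")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.coords).any(axis=1)

    @property
    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean())

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def copy(self) -> "SpecimenRecord":
        return replace(self, coords=self.coords.copy(),
                       imputed=None if self.imputed is None else self.imputed.copy())


@dataclass
class Dataset:
    """Specimen records sharing one landmark scheme."""
    scheme: LandmarkScheme
    records: list[SpecimenRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate specimen_id(s): {dupes}")
        k = len(self.scheme)
        for r in self.records:
            if r.coords.shape[0] != k:
                raise ValidationError(
                    f"{r.specimen_id}: {r.coords.shape[0]} landmarks, scheme has {k}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def groups(self) -> np.ndarray:
        return np.array([r.group for r in self.records])

    def coords_array(self) -> np.ndarray:
        """All configurations stacked as (n, k, 3)."""
        return np.stack([r.coords for r in self.records])

    def subset(self, *, groups: Optional[Sequence[str]] = None,
               exclude_ids: Sequence[str] = ()) -> "Dataset":
        """Record-order-preserving subset by group membership / exclusions."""
        exclude = set(exclude_ids)
        missing = exclude - set(self.specimen_ids)
        if missing:
            raise ValidationError(f"exclusions name unknown specimens: {sorted(missing)}")
        recs = [r for r in self.records
                if (groups is None or r.group in groups)
                and r.specimen_id not in exclude]
        return Dataset(self.scheme, recs)

    def merge_groups(self, merges: dict[str, str]) -> np.ndarray:
        """Group labels after applying merges (e.g. MUPswf/MUPmor -> MUP)."""
        return np.array([merges.get(r.group, r.group) for r in self.records])

    def get(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)
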