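"""Landmark scheme: the template describing every recorded point.

A scheme is an ordered list of landmark definitions.  Each point is either a
fixed (anatomically homologous) landmark or a curve semi-landmark, and is
either a midline point or one member of a left/right antimere pair.  The
cranial scheme used throughout this package has 239 points: 57 fixed
landmarks and 182 curve semi-landmarks, of which 45 lie on the midsagittal
plane and 194 form 97 bilateral pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np

Kind = Literal["fixed", "curve_semilandmark"]
Laterality = Literal["midline", "left", "right"]

GROUPS = ("EUP", "MUPswf", "MUPmor", "LUPswf", "LUPita",
          "AmNat", "EuS", "Inuit", "OcPap")
FOSSIL_GROUPS = GROUPS[:5]
EXTANT_GROUPS = GROUPS[5:]
SEX_VALUES = ("M", "F", "M?", "F?", "unknown")


@dataclass(frozen=True)
class LandmarkDef:
    """One entry of a landmark scheme."""
    landmark_id: int
    name: str
    kind: Kind
    laterality: Laterality
    pair_id: Optional[int] = None   # shared by the two antimeres of a pair
    curve_id: Optional[int] = None  # semi-landmark curve membership


class LandmarkScheme:
    """Ordered landmark template shared by every specimen of a dataset.

    Validates on construction: pairings must be a perfect left/right
    matching (an involution with one left and one right member per pair),
    and semi-landmarks of a curve must occupy consecutive positions.
    """

    def __init__(self, entries: Iterable[LandmarkDef]):
        self.entries: list[LandmarkDef] = list(entries)
        self._validate()
        # index helpers
        self.midline_indices = np.array(
            [e.landmark_id for e in self.entries if e.laterality == "midline"],
            dtype=int)
        self._antimere = self._build_antimere_map()

    def _validate(self) -> None:
        ids = [e.landmark_id for e in self.entries]
        if ids != list(range(len(ids))):
            raise ValueError("landmark_ids must be 0..n-1 in order")
        pairs: dict[int, list[LandmarkDef]] = {}
        for e in self.entries:
            if e.laterality == "midline":
                if e.pair_id is not None:
                    raise ValueError(f"midline landmark {e.landmark_id} has a pair_id")
            else:
                if e.pair_id is None:
                    raise ValueError(f"bilateral landmark {e.landmark_id} lacks a pair_id")
                pairs.setdefault(e.pair_id, []).append(e)
        for pid, members in pairs.items():
            if len(members) != 2 or {m.laterality for m in members} != {"left", "right"}:
                raise ValueError(
                    f"pair {pid} is not one left + one right landmark "
                    f"(got {[(m.landmark_id, m.laterality) for m in members]})")
        # curve semi-landmarks consecutive within curve_id
        seen: dict[int, int] = {}
        for e in self.entries:
            if e.curve_id is not None:
                last = seen.get(e.curve_id)
                if last is not None and e.landmark_id != last + 1:
                    raise ValueError(f"curve {e.curve_id} is not consecutively ordered")
                seen[e.curve_id] = e.landmark_id

    def _build_antimere_map(self) -> np.ndarray:
        """antimere[i] = index of i's pair partner, or i itself for midline."""
        amap = np.arange(len(self.entries))
        by_pair: dict[int, list[int]] = {}
        for e in self.entries:
            if e.pair_id is not None:
                by_pair.setdefault(e.pair_id, []).append(e.landmark_id)
        for a, b in by_pair.values():
            amap[a], amap[b] = b, a
        return amap

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, LandmarkScheme) and self.entries == other.entries

    @property
    def n_midline(self) -> int:
        return int(len(self.midline_indices))

    @property
    def n_pairs(self) -> int:
        return (len(self) - self.n_midline) // 2

    @property
    def n_fixed(self) -> int:
        return sum(e.kind == "fixed" for e in self.entries)

    @property
    def n_semilandmarks(self) -> int:
        return sum(e.kind == "curve_semilandmark" for e in self.entries)

    @property
    def antimere(self) -> np.ndarray:
        """Involution over landmark indices mapping each point to its antimere."""
        return self._antimere

    def relabel_permutation(self) -> np.ndarray:
        """Permutation swapping left/right labels (identity on midline)."""
        return self._antimere.copy()


def default_scheme() -> LandmarkScheme:
    """The packaged 239-point cranial scheme.

    57 fixed landmarks + 182 curve semi-landmarks; 45 midline points and
    97 bilateral pairs.  Layout (a deterministic function of these counts):

    - midline: 13 fixed craniometric points and one midsagittal curve of 32
      semi-landmarks (curve 0), occupying the first 45 slots;
    - bilateral: 22 fixed pairs, then 75 semi-landmark pairs organised as
      five bilateral curves of 15 pairs each (curves 1..5, left run followed
      by the mirrored right run so each run is consecutive).
    """
    entries: list[LandmarkDef] = []
    i = 0
    for j in range(13):
        entries.append(LandmarkDef(i, f"mid_fixed_{j}", "fixed", "midline"))
        i += 1
    for j in range(32):
        entries.append(LandmarkDef(i, f"mid_curve_{j}", "curve_semilandmark",
                                   "midline", curve_id=0))
        i += 1
    pid = 0
    for j in range(22):
        for side in ("left", "right"):
            entries.append(LandmarkDef(i, f"fixed_{j}_{side[0]}", "fixed", side,
                                       pair_id=pid))
            i += 1
        pid += 1
    # 5 bilateral curves x 15 pairs: left run consecutive, then right run
    for c in range(5):
        base_pid = pid
        for j in range(15):
            entries.append(LandmarkDef(i, f"curve{c + 1}_{j}_l",
                                       "curve_semilandmark", "left",
                                       pair_id=base_pid + j, curve_id=1 + 2 * c))
            i += 1
        for j in range(15):
            entries.append(LandmarkDef(i, f"curve{c + 1}_{j}_r",
                                       "curve_semilandmark", "right",
                                       pair_id=base_pid + j, curve_id=2 + 2 * c))
            i += 1
        pid += 15
    scheme = LandmarkScheme(entries)
    assert len(scheme) == 239 and scheme.n_midline == 45
    assert scheme.n_pairs == 97 and scheme.n_fixed == 57
    return scheme
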