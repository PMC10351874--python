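"""Enumeration and canonical naming of muscle and feature subsets.

Eight sEMG channels are considered: tibialis anterior (TA), soleus (SO),
medial gastrocnemius (MG) and peroneus longus (PL) on the lower leg, and
rectus femoris (RF), vastus medialis (VM), biceps femoris (BF) and gluteus
maximus (GMax) on the upper leg.  Five time-domain features are considered:
IEMG, MAV, RMS, WL and WAMP.  The analysis is exhaustive over all non-empty
subsets of each: 2^8 - 1 = 255 muscle combinations and 2^5 - 1 = 31 feature
combinations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

from .errors import IdentifierError, ValidationError

MUSCLES: tuple[str, ...] = ("TA", "SO", "MG", "PL", "RF", "VM", "BF", "GMax")
LOWER_LEG: frozenset[str] = frozenset({"TA", "SO", "MG", "PL"})
UPPER_LEG: frozenset[str] = frozenset({"RF", "VM", "BF", "GMax"})
FEATURES: tuple[str, ...] = ("IEMG", "MAV", "RMS", "WL", "WAMP")


def _canonical(members: Sequence[str], universe: tuple[str, ...], kind: str) -> tuple[str, ...]:
    seen = set()
    for m in members:
        if m not in universe:
            raise IdentifierError(f"unknown {kind} name: {m!r}")
        seen.add(m)
    if not seen:
        raise ValidationError(f"{kind} set must be non-empty")
    return tuple(m for m in universe if m in seen)


@dataclass(frozen=True)
class MuscleSet:
    """A non-empty subset of the eight muscles, in canonical order."""

    members: tuple[str, ...]

    def __init__(self, members: Sequence[str]):
        object.__setattr__(self, "members", _canonical(members, MUSCLES, "muscle"))

    @property
    def name(self) -> str:
        return "+".join(self.members)

    @property
    def n_lower(self) -> int:
        return sum(1 for m in self.members if m in LOWER_LEG)

    @property
    def n_upper(self) -> int:
        return sum(1 for m in self.members if m in UPPER_LEG)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @classmethod
    def parse(cls, name: str) -> "MuscleSet":
        """Parse a '+'-joined name; embedded spaces are ignored."""
        return cls([p for p in name.replace(" ", "").split("+") if p])


@dataclass(frozen=True)
class FeatureSet:
    """A non-empty subset of the five time-domain features, in canonical order."""

    members: tuple[str, ...]

    def __init__(self, members: Sequence[str]):
        object.__setattr__(self, "members", _canonical(members, FEATURES, "feature"))

    @property
    def name(self) -> str:
        return "+".join(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @classmethod
    def parse(cls, name: str) -> "FeatureSet":
        return cls([p for p in name.replace(" ", "").split("+") if p])


def enumerate_subsets(items: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets of ``items`` in (size, lexicographic-by-position) order.

    For the 8 muscles this yields exactly 255 subsets
    (sizes 1..8: 8, 28, 56, 70, 56, 28, 8, 1); for the 5 features, 31.
    """
    if not 1 <= len(items) <= 16:
        raise ValidationError("item list must contain between 1 and 16 items")
    if len(set(items)) != len(items):
        raise ValidationError("item list contains duplicates")
    out: list[tuple[str, ...]] = []
    for size in range(1, len(items) + 1):
        out.extend(itertools.combinations(items, size))
    return out


def all_muscle_sets() -> list[MuscleSet]:
    """The 255 muscle combinations in canonical enumeration order."""
    return [MuscleSet(s) for s in enumerate_subsets(MUSCLES)]


def all_feature_sets() -> list[FeatureSet]:
    """The 31 feature combinations in canonical enumeration order."""
    return [FeatureSet(s) for s in enumerate_subsets(FEATURES)]


def classify_legs(ms: MuscleSet) -> tuple[int, int]:
    """Counts of (lower-leg, upper-leg) muscles in ``ms``.

    Lower leg: TA, SO, MG, PL.  Upper leg: RF, VM, BF, GMax.
    """
    return ms.n_lower, ms.n_upper
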