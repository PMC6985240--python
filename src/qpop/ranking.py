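"""Exhaustive enumeration and ranking of k-drug combinations.

A combination is a size-k drug subset together with one non-zero coded
level per member; an 11-drug panel with 2 non-zero levels therefore has
C(11,5) * 2^5 = 14,784 five-drug and C(11,3) * 2^3 = 1,320 three-drug
combinations.  Every combination is scored by the predicted viability of
its implied dose vector (members at their levels, everything else at
vehicle) and ranked ascending: rank 1 = lowest predicted viability = most
efficacious.  Ties keep enumeration order, so ranks are deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .panel import DoseVector
from .surface import QuadraticSurface, predict_many

__all__ = [
    "CombinationAssignment",
    "CombinationRanking",
    "Regimen",
    "enumerate_combinations",
    "count_combinations",
    "rank_combinations",
    "locate_regimen",
    "top_combinations",
]

TIE_RULE = "enumeration-order"


@dataclass(frozen=True)
class CombinationAssignment:
    """A drug subset with one non-zero level per member."""

    members: tuple[int, ...]  # panel indices, strictly increasing
    levels: tuple[int, ...]  # one non-zero coded level per member

    def __post_init__(self):
        if len(self.members) != len(self.levels):
            raise ValidationError("members and levels must align")
        if len(self.members) == 0:
            raise ValidationError("combination needs at least one member")
        if any(b <= a for a, b in zip(self.members, self.members[1:])):
            raise ValidationError("members must be strictly increasing panel indices")
        if any(lv < 1 for lv in self.levels):
            raise ValidationError("combination levels must be non-zero")

    @property
    def k(self) -> int:
        return len(self.members)

    def dose_vector(self, n: int) -> DoseVector:
        levels = [0] * n
        for m, lv in zip(self.members, self.levels):
            levels[m] = lv
        return DoseVector(tuple(levels))


@dataclass
class CombinationRanking:
    """Complete ranking of all (subset, level-assignment) combinations."""

    surface: QuadraticSurface
    k: int
    assignments: list[CombinationAssignment]
    scores: np.ndarray  # predicted viability, enumeration order
    order: np.ndarray  # order[r-1] = enumeration index at rank r
    tie_rule_id: str = TIE_RULE
    _rank_of: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self._rank_of is None:
            rank_of = np.empty(len(self.order), dtype=int)
            rank_of[self.order] = np.arange(1, len(self.order) + 1)
            self._rank_of = rank_of

    def __len__(self) -> int:
        return len(self.assignments)

    def entry(self, rank: int) -> tuple[CombinationAssignment, float, int]:
        if not 1 <= rank <= len(self):
            raise ValidationError(f"rank {rank} outside 1..{len(self)}")
        idx = int(self.order[rank - 1])
        return self.assignments[idx], float(self.scores[idx]), rank

    def entries(self):
        for r in range(1, len(self) + 1):
            yield self.entry(r)

    def rank_of_assignment(self, a: CombinationAssignment) -> int:
        try:
            idx = self.assignments.index(a)
        except ValueError:
            raise ValidationError(f"assignment {a} not in ranking") from None
        return int(self._rank_of[idx])


@dataclass(frozen=True)
class Regimen:
    """A named drug set, optionally with fixed level assignment."""

    name: str
    members: tuple[str, ...]
    levels: tuple[int, ...] | None = None

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"regimen {self.name!r}: duplicate members")
        if self.levels is not None and len(self.levels) != len(self.members):
            raise ValidationError(f"regimen {self.name!r}: levels must align with members")


def count_combinations(n: int, k: int, L: int) -> int:
    """C(n,k) * L^k."""
    return math.comb(n, k) * L**k


def enumerate_combinations(n: int, k: int, L: int) -> list[CombinationAssignment]:
    """All (subset, level) assignments in deterministic lexicographic order.

    Ordered by member-index tuple first, then by level tuple; exactly
    ``C(n,k) * L^k`` distinct entries.
    """
    if n < 1 or L < 1:
        raise ValidationError("need n >= 1 and L >= 1")
    if not 1 <= k <= n:
        raise ValidationError(f"combination size k={k} outside 1..{n}")
    out = []
    for members in itertools.combinations(range(n), k):
        for levels in itertools.product(range(1, L + 1), repeat=k):
            out.append(CombinationAssignment(members, levels))
    return out


def rank_combinations(surface: QuadraticSurface, k: int) -> CombinationRanking:
    """Score and rank every k-drug combination on the fitted surface.

    Ascending by predicted viability; ties broken by enumeration order
    (stable sort), so output is reproducible across runs and platforms.
    """
    panel = surface.panel
    assignments = enumerate_combinations(panel.n, k, panel.L)
    levels = np.zeros((len(assignments), panel.n), dtype=int)
    for row, a in zip(levels, assignments):
        row[list(a.members)] = a.levels
    scores = predict_many(surface, levels)
    order = np.argsort(scores, kind="stable")
    return CombinationRanking(
        surface=surface, k=k, assignments=assignments, scores=scores, order=order
    )


def locate_regimen(
    ranking: CombinationRanking, regimen: Regimen
) -> tuple[int, list[tuple[CombinationAssignment, float, int]]]:
    """Rank of a named regimen within a ranking.

    With explicit levels, returns that single assignment's rank; otherwise
    the best (lowest) rank over all level assignments of the member set,
    together with every matched entry.
    """
    panel = ranking.surface.panel
    idx = sorted(panel.index_of(m) for m in regimen.members)
    if len(idx) != ranking.k:
        raise ValidationError(
            f"regimen {regimen.name!r} has {len(idx)} members, ranking is for k={ranking.k}"
        )
    if regimen.levels is not None:
        by_name = dict(zip(regimen.members, regimen.levels))
        ordered_levels = tuple(by_name[panel.names[i]] for i in idx)
        a = CombinationAssignment(tuple(idx), ordered_levels)
        r = ranking.rank_of_assignment(a)
        s = float(ranking.scores[ranking.order[r - 1]])
        return r, [(a, s, r)]
    member_set = tuple(idx)
    matched = []
    for levels in itertools.product(range(1, panel.L + 1), repeat=ranking.k):
        a = CombinationAssignment(member_set, levels)
        r = ranking.rank_of_assignment(a)
        s = float(ranking.scores[ranking.order[r - 1]])
        matched.append((a, s, r))
    matched.sort(key=lambda t: t[2])
    return matched[0][2], matched


def top_combinations(
    ranking: CombinationRanking, m: int
) -> list[tuple[CombinationAssignment, float, int]]:
    """First m entries of the ranking (rank 1 = most efficacious)."""
    if not 1 <= m <= len(ranking):
        raise ValidationError(f"m={m} outside 1..{len(ranking)}")
    return [ranking.entry(r) for r in range(1, m + 1)]
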