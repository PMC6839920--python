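"""Pedigree structures: individuals, family topology, and validation.

Affection status drives the shared-autozygosity logic downstream: segments
homozygous in all affected siblings but not their unaffected siblings are the
candidate regions for a recessive allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .errors import ValidationError

SEXES = ("male", "female", "unknown")
AFFECTION = ("affected", "unaffected", "unknown")


@dataclass(frozen=True)
class Individual:
    sample_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"
    affected: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if (self.father_id is None) != (self.mother_id is None):
            raise ValidationError(
                f"{self.sample_id}: parent ids must be both present or both missing"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"invalid sex {self.sex!r}")
        if self.affected not in AFFECTION:
            raise ValidationError(f"invalid affection status {self.affected!r}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class Pedigree:
    """An ordered, validated collection of individuals in one family.

    Validation enforces unique sample ids, resolvable parent references and
    acyclicity (no individual is its own ancestor), checked by topological
    sort over the parent->child relation.
    """

    def __init__(self, members: Iterable[Individual], family_id: str = "FAM1"):
        self.family_id = family_id
        self._members: dict[str, Individual] = {}
        for ind in members:
            if ind.sample_id in self._members:
                raise ValidationError(f"duplicate sample id {ind.sample_id!r}")
            self._members[ind.sample_id] = ind
        for ind in self._members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self._members:
                    raise ValidationError(
                        f"{ind.sample_id}: parent {pid!r} not in pedigree"
                    )
        self._topo_order = self._topological_sort()

    def _topological_sort(self) -> list[str]:
        # Kahn's algorithm over parent -> child edges; leftover nodes mean a cycle.
        indeg = {
            sid: sum(p is not None for p in (ind.father_id, ind.mother_id))
            for sid, ind in self._members.items()
        }
        children: dict[str, list[str]] = {sid: [] for sid in self._members}
        for sid, ind in self._members.items():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    children[pid].append(sid)
        queue = sorted(sid for sid, d in indeg.items() if d == 0)
        order = []
        while queue:
            sid = queue.pop(0)
            order.append(sid)
            for child in children[sid]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if len(order) != len(self._members):
            raise ValidationError("pedigree contains a cycle")
        return order

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._members

    def __getitem__(self, sample_id: str) -> Individual:
        try:
            return self._members[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in pedigree") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return (
            self.family_id == other.family_id
            and list(self._members.values()) == list(other._members.values())
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self._members)

    @property
    def topological_order(self) -> list[str]:
        """Founders first; every parent precedes its children."""
        return list(self._topo_order)

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self if ind.is_founder]

    @property
    def affected_ids(self) -> list[str]:
        return [ind.sample_id for ind in self if ind.affected == "affected"]

    @property
    def unaffected_ids(self) -> list[str]:
        return [ind.sample_id for ind in self if ind.affected == "unaffected"]

    def unaffected_sibling_ids(self) -> list[str]:
        """Unaffected full siblings of the affected individuals."""
        pairs = {
            (self[a].father_id, self[a].mother_id)
            for a in self.affected_ids
            if not self[a].is_founder
        }
        return [
            ind.sample_id
            for ind in self
            if ind.affected == "unaffected"
            and (ind.father_id, ind.mother_id) in pairs
        ]

    def parents_of_affected(self) -> Optional[tuple[str, str]]:
        """The (father, mother) pair shared by all affected; None otherwise."""
        pairs = {
            (self[a].father_id, self[a].mother_id)
            for a in self.affected_ids
            if not self[a].is_founder
        }
        if len(pairs) == 1:
            return pairs.pop()  # type: ignore[return-value]
        return None
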