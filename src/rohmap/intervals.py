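"""Genomic interval primitives: segments and segment-set algebra.

Every coordinate inside the package is 0-based half-open (BED convention).
User-facing VCF- or table-style coordinates are 1-based inclusive; the pair
:func:`to_internal` / :func:`to_display` is the single conversion point and is
used by every reader and writer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

from .errors import ValidationError


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start_1based - 1, end_1based


def to_display(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start + 1, end


@dataclass(frozen=True)
class Segment:
    """A half-open genomic interval with optional per-sample provenance.

    ``start``/``end`` are 0-based half-open; ``n_markers`` is the number of
    genotyped markers supporting the segment when it came out of a run scan.
    """

    chrom: str
    start: int
    end: int
    sample_id: Optional[str] = None
    n_markers: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("segment chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"segment requires 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def _coalesce(
    ivals: Sequence[tuple[int, int]], max_gap: int = 0
) -> list[tuple[int, int]]:
    """Union sorted intervals, merging any pair separated by <= max_gap bp."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s - out[-1][1] <= max_gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect_lists(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract_lists(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


class SegmentSet:
    """An ordered collection of segments supporting interval algebra.

    Segments are kept sorted by (chrom, start, end).  Set-algebra results
    (union/intersect/subtract) are coalesced and disjoint; per-sample
    provenance is dropped by algebra because the result no longer belongs to a
    single scan.
    """

    def __init__(self, segments: Iterable[Segment] = ()) -> None:
        self._segments: tuple[Segment, ...] = tuple(
            sorted(segments, key=Segment.sort_key)
        )

    @classmethod
    def from_tuples(
        cls, tuples: Iterable[tuple], sample_id: Optional[str] = None
    ) -> "SegmentSet":
        return cls(
            Segment(chrom, s, e, sample_id=sample_id) for chrom, s, e in tuples
        )

    @property
    def segments(self) -> tuple[Segment, ...]:
        return self._segments

    def __iter__(self) -> Iterator[Segment]:
        return iter(self._segments)

    def __len__(self) -> int:
        return len(self._segments)

    def __bool__(self) -> bool:
        return bool(self._segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentSet):
            return NotImplemented
        return self._segments == other._segments

    def __repr__(self) -> str:
        return f"SegmentSet({len(self._segments)} segments, {self.total_bp} bp)"

    def chroms(self) -> list[str]:
        return sorted({seg.chrom for seg in self._segments})

    def _by_chrom(self) -> dict[str, list[tuple[int, int]]]:
        d: dict[str, list[tuple[int, int]]] = {}
        for seg in self._segments:
            d.setdefault(seg.chrom, []).append((seg.start, seg.end))
        return d

    @property
    def total_bp(self) -> int:
        total = 0
        for ivals in self._by_chrom().values():
            total += sum(e - s for s, e in _coalesce(ivals))
        return total

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 0-based position."""
        return any(
            seg.chrom == chrom and seg.start <= pos < seg.end
            for seg in self._segments
        )

    def coalesced(self) -> "SegmentSet":
        """Union of this set's own segments (disjoint, provenance dropped)."""
        segs = []
        for chrom, ivals in sorted(self._by_chrom().items()):
            segs.extend(Segment(chrom, s, e) for s, e in _coalesce(ivals))
        return SegmentSet(segs)

    def union(self, other: "SegmentSet") -> "SegmentSet":
        return SegmentSet(list(self._segments) + list(other._segments)).coalesced()

    def intersect(self, other: "SegmentSet") -> "SegmentSet":
        mine = self.coalesced()._by_chrom()
        theirs = other.coalesced()._by_chrom()
        segs = []
        for chrom in sorted(set(mine) & set(theirs)):
            segs.extend(
                Segment(chrom, s, e)
                for s, e in _intersect_lists(mine[chrom], theirs[chrom])
            )
        return SegmentSet(segs)

    def subtract(self, other: "SegmentSet") -> "SegmentSet":
        mine = self.coalesced()._by_chrom()
        theirs = other.coalesced()._by_chrom()
        segs = []
        for chrom, ivals in sorted(mine.items()):
            segs.extend(
                Segment(chrom, s, e)
                for s, e in _subtract_lists(ivals, theirs.get(chrom, []))
            )
        return SegmentSet(segs)

    def merge(self, max_gap_bp: int) -> "SegmentSet":
        """Union segments separated by at most ``max_gap_bp``.

        Provenance survives a merge only when it is uniform among the merged
        segments; marker counts are summed when all contributors carry one.
        This operation is idempotent for a fixed gap.
        """
        if max_gap_bp < 0:
            raise ValidationError("max_gap_bp must be >= 0")
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self._segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        out: list[Segment] = []
        for chrom in sorted(by_chrom):
            group: list[Segment] = []
            for seg in sorted(by_chrom[chrom], key=Segment.sort_key):
                if group and seg.start - max(g.end for g in group) <= max_gap_bp:
                    group.append(seg)
                else:
                    if group:
                        out.append(_merge_group(group))
                    group = [seg]
            if group:
                out.append(_merge_group(group))
        return SegmentSet(out)

    def filter_min_length(self, min_bp: int) -> "SegmentSet":
        return SegmentSet(seg for seg in self._segments if seg.length >= min_bp)


def _merge_group(group: list[Segment]) -> Segment:
    sample_ids = {g.sample_id for g in group}
    counts = [g.n_markers for g in group]
    return Segment(
        chrom=group[0].chrom,
        start=min(g.start for g in group),
        end=max(g.end for g in group),
        sample_id=sample_ids.pop() if len(sample_ids) == 1 else None,
        n_markers=sum(counts) if all(c is not None for c in counts) else None,
    )
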