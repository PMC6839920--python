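"""Runs-of-homozygosity detection and shared-autozygosity mapping.

A run of homozygosity (ROH) is a maximal stretch of consecutive markers whose
genotype calls are (almost) all homozygous; in offspring of consanguineous
matings long ROH mark autozygous tracts.  Candidate regions for a recessive
disease allele are those autozygous in every affected sibling and in no
unaffected sibling.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .intervals import Segment, SegmentSet
from .variants import AnnotatedVariant, GenotypePanel


@dataclass(frozen=True)
class RohParams:
    """Tolerances of the run-based ROH scan.

    ``max_het``/``max_missing`` are per-run budgets absorbing genotyping
    error; ``min_markers`` and ``min_length_bp`` suppress short chance runs.
    Defaults suit array densities of roughly 50-100 markers per Mb.
    """

    min_markers: int = 50
    min_length_bp: int = 1_000_000
    max_het: int = 1
    max_missing: int = 5

    def __post_init__(self) -> None:
        if min(self.min_markers, self.max_het, self.max_missing) < 0:
            raise ValidationError("ROH parameters must be >= 0")
        if self.min_length_bp <= 0:
            raise ValidationError("min_length_bp must be > 0")


def _maximal_runs(codes: np.ndarray, max_het: int, max_missing: int) -> list[tuple[int, int]]:
    """All maximal index runs [l, r) with <= max_het hets and <= max_missing
    missing calls (two-pointer scan; runs may overlap on shared budget)."""
    n = len(codes)
    runs: list[tuple[int, int]] = []
    r = 0
    het = mis = 0
    prev_end = 0
    for l in range(n):
        if r < l:
            r = l
        while r < n:
            c = codes[r]
            nh = het + (c == 1)
            nm = mis + (c == -1)
            if nh > max_het or nm > max_missing:
                break
            het, mis = nh, nm
            r += 1
        if r > l and r > prev_end:
            runs.append((l, r))
            prev_end = r
        if r > l:
            c = codes[l]
            het -= c == 1
            mis -= c == -1
    return runs


def detect_roh(
    panel: GenotypePanel, sample_id: str, params: RohParams | None = None
) -> SegmentSet:
    """Detect runs of homozygosity for one sample.

    Maximal marker runs satisfying the het/missing budgets are kept when they
    contain at least ``min_markers`` markers and span at least
    ``min_length_bp``; surviving runs are converted to half-open segments
    ``[pos(first)-1, pos(last))`` and coalesced, so the output is sorted and
    non-overlapping.
    """
    params = params or RohParams()
    codes_all = panel.codes_for(sample_id)
    segs: list[Segment] = []
    for chrom, pos, idx in panel.by_chrom():
        codes = codes_all[idx]
        kept: list[tuple[int, int]] = []
        for l, r in _maximal_runs(codes, params.max_het, params.max_missing):
            if r - l < params.min_markers:
                continue
            start, end = int(pos[l]) - 1, int(pos[r - 1])
            if end - start < params.min_length_bp:
                continue
            kept.append((start, end))
        # coalesce overlapping surviving runs into disjoint segments
        merged: list[tuple[int, int]] = []
        for s, e in sorted(kept):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            n_markers = int(((pos > s) & (pos <= e)).sum())
            segs.append(Segment(chrom, s, e, sample_id=sample_id, n_markers=n_markers))
    return SegmentSet(segs)


def shared_loh(
    roh_by_sample: Mapping[str, SegmentSet],
    affected_ids: Sequence[str],
    unaffected_ids: Sequence[str] = (),
    min_shared_bp: int = 0,
    require_all_unaffected: bool = False,
) -> SegmentSet:
    """Regions homozygous in all affected samples and not in unaffected ones.

    Per-base intersection of the affected ROH sets, minus the unaffected ROH
    (the union by default — any unaffected homozygosity disqualifies a region;
    with ``require_all_unaffected`` the intersection is subtracted instead),
    then pieces shorter than ``min_shared_bp`` are dropped.
    """
    if not affected_ids:
        raise ValidationError("at least one affected sample is required")
    missing = [s for s in list(affected_ids) + list(unaffected_ids) if s not in roh_by_sample]
    if missing:
        raise ValidationError(f"no ROH set for samples: {missing}")
    shared = reduce(
        lambda a, b: a.intersect(b),
        (roh_by_sample[s] for s in affected_ids[1:]),
        roh_by_sample[affected_ids[0]].coalesced(),
    )
    if unaffected_ids:
        sets = [roh_by_sample[s] for s in unaffected_ids]
        excl = reduce(
            lambda a, b: a.intersect(b) if require_all_unaffected else a.union(b),
            sets[1:],
            sets[0].coalesced(),
        )
        shared = shared.subtract(excl)
    return shared.filter_min_length(min_shared_bp)


def merge_segments(segments: SegmentSet, max_gap_bp: int) -> SegmentSet:
    """Union segments on one track whose gap is at most ``max_gap_bp``.

    Long autozygous tracts often come out of array-based scans fragmented by
    isolated discordant calls; sequencing shows more continuity, which this
    gap-tolerant merge restores.  Idempotent for a fixed gap.
    """
    return segments.merge(max_gap_bp)


@dataclass(frozen=True)
class HetWindow:
    """Heterozygosity tally in one genomic window (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_het: int
    n_hom: int

    @property
    def avg_het(self) -> Optional[float]:
        """Fraction of variant calls that are heterozygous; None when the
        window holds no variant calls."""
        denom = self.n_het + self.n_hom
        return self.n_het / denom if denom else None


def window_heterozygosity(
    variant_calls: Sequence[AnnotatedVariant],
    sample_id: str,
    region: tuple[str, int, int],
    window_bp: int = 100_000,
) -> list[HetWindow]:
    """Tile a region with fixed windows and tally het/hom variant calls.

    ``region`` is (chrom, start, end), 0-based half-open; windows are anchored
    at the region start and the last window is truncated at the region end.
    ``n_het`` counts code-1 calls, ``n_hom`` code-2 calls; hom-ref sites carry
    no variant evidence and are excluded, so windows without variants report a
    missing (None) average rather than 0.
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be > 0")
    chrom, start, end = region
    if not (0 <= start < end):
        raise ValidationError("region requires 0 <= start < end")
    n_windows = -(-(end - start) // window_bp)
    n_het = np.zeros(n_windows, dtype=int)
    n_hom = np.zeros(n_windows, dtype=int)
    for v in variant_calls:
        if v.chrom != chrom:
            continue
        p = v.pos - 1  # to 0-based
        if not (start <= p < end):
            continue
        code = v.genotypes.get(sample_id, -1)
        w = (p - start) // window_bp
        if code == 1:
            n_het[w] += 1
        elif code == 2:
            n_hom[w] += 1
    return [
        HetWindow(
            chrom,
            start + w * window_bp,
            min(start + (w + 1) * window_bp, end),
            int(n_het[w]),
            int(n_hom[w]),
        )
        for w in range(n_windows)
    ]
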