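"""Dense genotype panels and annotated variants.

Genotype codes follow one convention everywhere:
``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

GENOTYPE_CODES = (-1, 0, 1, 2)

CONSEQUENCES = (
    "missense",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift",
    "inframe_indel",
    "splice_acceptor",
    "splice_donor",
    "synonymous",
    "intronic",
    "other",
)

#: Consequence classes treated as potentially protein-disrupting by the
#: default filter cascade ("non-synonymous" in the broad sense, including
#: splice-site alleles).
FUNCTIONAL_CLASSES = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift",
        "inframe_indel",
        "splice_acceptor",
        "splice_donor",
    }
)


@dataclass
class AnnotatedVariant:
    """One biallelic variant with functional annotation and genotypes.

    ``pos`` is 1-based (VCF convention).  ``pop_afs`` maps database name
    (e.g. ``ExAC``, ``1KG``, ``TOPMED``) to allele frequency; absent keys mean
    the variant is not reported in that database.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    consequence: Optional[str] = None
    cds_pos: Optional[int] = None
    protein_pos: Optional[int] = None
    pop_afs: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError("variant pos is 1-based, must be >= 1")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValidationError("ref must differ from alt")
        if "," in self.alt:
            raise ValidationError("AnnotatedVariant is biallelic; decompose first")
        for db, af in self.pop_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValidationError(f"AF for {db} out of [0,1]: {af}")
        for sid, code in self.genotypes.items():
            if code not in GENOTYPE_CODES:
                raise ValidationError(f"bad genotype code {code} for {sid}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class GenotypePanel:
    """Dense genotype codes at ordered markers for a set of samples.

    Markers are (chrom, pos, marker_id) with 1-based positions, strictly
    sorted by (chrom, pos).  ``calls`` is an int8 matrix of shape
    (n_markers, n_samples).
    """

    def __init__(
        self,
        markers: Sequence[tuple[str, int, str]],
        samples: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        self.markers = list(markers)
        self.samples = list(samples)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.markers), len(self.samples)):
            raise ValidationError(
                f"calls shape {calls.shape} != ({len(self.markers)}, {len(self.samples)})"
            )
        if not np.isin(calls, GENOTYPE_CODES).all():
            raise ValidationError("genotype codes must be in {-1,0,1,2}")
        keys = [(chrom, pos) for chrom, pos, _ in self.markers]
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise ValidationError("markers must be strictly sorted by (chrom, pos)")
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None

    def codes_for(self, sample_id: str) -> np.ndarray:
        return self.calls[:, self.sample_index(sample_id)]

    def by_chrom(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """Yield (chrom, positions, row-index array) per chromosome, in order."""
        out = []
        chroms = [c for c, _, _ in self.markers]
        pos = np.array([p for _, p, _ in self.markers], dtype=np.int64)
        i = 0
        while i < len(chroms):
            j = i
            while j < len(chroms) and chroms[j] == chroms[i]:
                j += 1
            out.append((chroms[i], pos[i:j], np.arange(i, j)))
            i = j
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
        )
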