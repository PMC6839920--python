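"""Small population-genetic computations.

Cohort allele frequency from a carrier screen, Hardy-Weinberg expected
genotype frequencies, and Wright's path-counting inbreeding coefficient for
arbitrary (acyclic) pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .errors import ValidationError
from .pedigree import Pedigree
from .variants import AnnotatedVariant


@dataclass(frozen=True)
class GenotypeCounts:
    n_homref: int
    n_het: int
    n_homalt: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_homref, self.n_het, self.n_homalt, self.n_missing) < 0:
            raise ValidationError("genotype counts must be >= 0")

    @property
    def n_typed(self) -> int:
        return self.n_homref + self.n_het + self.n_homalt


def allele_frequency(counts: GenotypeCounts) -> float:
    """Alt allele frequency; missing genotypes excluded from the denominator."""
    if counts.n_typed == 0:
        raise ValidationError("no typed individuals")
    return (counts.n_het + 2 * counts.n_homalt) / (2 * counts.n_typed)


class HweFrequencies(NamedTuple):
    f_homref: float
    f_het: float
    f_homalt: float


def hwe_expected(q: float) -> HweFrequencies:
    """Hardy-Weinberg genotype frequencies at alt-allele frequency ``q``."""
    if not (0.0 <= q <= 1.0):
        raise ValidationError(f"allele frequency out of [0,1]: {q}")
    p = 1.0 - q
    return HweFrequencies(p * p, 2.0 * p * q, q * q)


def _ancestor_paths(ped: Pedigree, start: str) -> list[tuple[str, tuple[str, ...]]]:
    """All paths from ``start`` up to each of its ancestors (and itself).

    Returns (ancestor_id, path) pairs where path includes ``start`` and the
    ancestor; each step follows one parent link, so paths are simple chains.
    """
    out: list[tuple[str, tuple[str, ...]]] = []

    def walk(node: str, path: tuple[str, ...]) -> None:
        out.append((node, path))
        ind = ped[node]
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None:
                walk(pid, path + (pid,))

    walk(start, (start,))
    return out


def inbreeding_coefficient(pedigree: Pedigree, individual: str) -> float:
    """Wright's inbreeding coefficient F by path counting.

    F = sum over common ancestors A and pairs of parent-to-A paths sharing no
    individual but A of (1/2)^(n1+n2+1) * (1 + F_A), with ancestor inbreeding
    F_A computed recursively (memoized).  Founders (and offspring of unrelated
    parents) have F = 0.
    """
    memo: dict[str, float] = {}

    def f_of(sid: str) -> float:
        if sid in memo:
            return memo[sid]
        ind = pedigree[sid]
        if ind.is_founder:
            memo[sid] = 0.0
            return 0.0
        assert ind.father_id is not None and ind.mother_id is not None
        paths_f = _ancestor_paths(pedigree, ind.father_id)
        paths_m = _ancestor_paths(pedigree, ind.mother_id)
        total = 0.0
        for anc_f, path1 in paths_f:
            for anc_m, path2 in paths_m:
                if anc_f != anc_m:
                    continue
                # paths may share only the common ancestor itself
                if set(path1[:-1]) & set(path2[:-1]):
                    continue
                n1 = len(path1) - 1
                n2 = len(path2) - 1
                total += 0.5 ** (n1 + n2 + 1) * (1.0 + f_of(anc_f))
        memo[sid] = total
        return total

    if individual not in pedigree:
        raise KeyError(f"individual {individual!r} not in pedigree")
    return f_of(individual)


@dataclass(frozen=True)
class ScreenResult:
    counts: GenotypeCounts
    allele_freq: float
    allele_freq_percent: str  # 4 significant digits, e.g. "0.025%"

    @property
    def n_homalt(self) -> int:
        return self.counts.n_homalt


def screen_summary(
    genotypes: "Iterable[int] | AnnotatedVariant",
) -> ScreenResult:
    """Tally a carrier screen and report the cohort allele frequency.

    Accepts either an iterable of genotype codes or an
    :class:`AnnotatedVariant` whose per-sample genotypes are the screen.
    """
    if isinstance(genotypes, AnnotatedVariant):
        codes = list(genotypes.genotypes.values())
    else:
        codes = list(genotypes)
    counts = GenotypeCounts(
        n_homref=sum(c == 0 for c in codes),
        n_het=sum(c == 1 for c in codes),
        n_homalt=sum(c == 2 for c in codes),
        n_missing=sum(c == -1 for c in codes),
    )
    af = allele_frequency(counts)
    return ScreenResult(counts, af, f"{af * 100:.4g}%")
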