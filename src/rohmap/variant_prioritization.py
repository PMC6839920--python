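"""Recessive-model rare-variant filter cascade with a full audit trail.

The cascade reduces annotated variants to candidates compatible with a
recessive trait in a sibship: functional (non-synonymous in the broad sense),
rare in every configured population database, homozygous-alt in all affected
siblings and at most heterozygous in unaffected siblings, and optionally
restricted to shared-autozygosity regions.  Each filter is an independent
predicate, so the surviving set does not depend on filter order; the trail
records, per variant, which filter removed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .intervals import SegmentSet
from .pedigree import Pedigree
from .variants import AnnotatedVariant, FUNCTIONAL_CLASSES

VariantKey = tuple[str, int, str, str]


@dataclass
class FilterTrail:
    """Ordered per-variant verdicts; once a filter fails, later filters are
    recorded as not-evaluated."""

    variant_key: VariantKey
    verdicts: list[tuple[str, str, str]] = field(default_factory=list)

    def record(self, filter_name: str, passed: bool, detail: str = "") -> None:
        status = "pass" if passed else "fail"
        if any(v[1] == "fail" for v in self.verdicts):
            status = "not-evaluated"
        self.verdicts.append((filter_name, status, detail))

    @property
    def survived(self) -> bool:
        return all(status == "pass" for _, status, _ in self.verdicts)

    @property
    def failing_filter(self) -> Optional[str]:
        for name, status, _ in self.verdicts:
            if status == "fail":
                return name
        return None


@dataclass(frozen=True)
class CascadeConfig:
    max_maf: float = 0.01
    databases: tuple[str, ...] = ("ExAC", "1KG", "TOPMED")
    functional_classes: frozenset = FUNCTIONAL_CLASSES
    missing_af_policy: str = "treat_as_rare"  # or "fail"
    unannotated_policy: str = "fail"  # or "pass"
    require_region_overlap: bool = True
    max_unaffected_code: int = 1  # unaffected siblings at most het

    def __post_init__(self) -> None:
        if not (0.0 < self.max_maf <= 1.0):
            raise ValidationError("max_maf must be in (0, 1]")
        if self.missing_af_policy not in ("treat_as_rare", "fail"):
            raise ValidationError(f"bad missing_af_policy {self.missing_af_policy!r}")
        if self.unannotated_policy not in ("pass", "fail"):
            raise ValidationError(f"bad unannotated_policy {self.unannotated_policy!r}")


def _apply(
    variants: Sequence[AnnotatedVariant],
    trails: dict[VariantKey, FilterTrail],
    name: str,
    predicate,
) -> list[AnnotatedVariant]:
    survivors = []
    for v in variants:
        trail = trails.setdefault(v.key, FilterTrail(v.key))
        passed, detail = predicate(v)
        trail.record(name, passed, detail)
        if passed:
            survivors.append(v)
    return survivors


def filter_functional(
    variants: Sequence[AnnotatedVariant],
    config: CascadeConfig | None = None,
    trails: Optional[dict[VariantKey, FilterTrail]] = None,
) -> tuple[list[AnnotatedVariant], dict[VariantKey, FilterTrail]]:
    """Keep variants whose consequence is in the functional class set."""
    config = config or CascadeConfig()
    trails = trails if trails is not None else {}

    def pred(v: AnnotatedVariant):
        if v.consequence is None:
            return config.unannotated_policy == "pass", "unannotated"
        ok = v.consequence in config.functional_classes
        return ok, v.consequence

    return _apply(variants, trails, "functional", pred), trails


def filter_rare(
    variants: Sequence[AnnotatedVariant],
    config: CascadeConfig | None = None,
    trails: Optional[dict[VariantKey, FilterTrail]] = None,
) -> tuple[list[AnnotatedVariant], dict[VariantKey, FilterTrail]]:
    """Keep variants with AF strictly below ``max_maf`` in every configured
    database; a missing AF passes or fails per ``missing_af_policy``."""
    config = config or CascadeConfig()
    trails = trails if trails is not None else {}

    def pred(v: AnnotatedVariant):
        for db in config.databases:
            if db not in v.pop_afs:
                if config.missing_af_policy == "fail":
                    return False, f"no AF in {db}"
                continue
            if not (v.pop_afs[db] < config.max_maf):
                return False, f"{db} AF {v.pop_afs[db]:.4g} >= {config.max_maf:.4g}"
        return True, ""

    return _apply(variants, trails, "rare", pred), trails


def filter_recessive_pattern(
    variants: Sequence[AnnotatedVariant],
    pedigree: Pedigree,
    config: CascadeConfig | None = None,
    trails: Optional[dict[VariantKey, FilterTrail]] = None,
) -> tuple[list[AnnotatedVariant], dict[VariantKey, FilterTrail]]:
    """Keep variants homozygous-alt in every affected sibling and at most
    heterozygous in every unaffected sibling; a missing genotype in any
    required sample fails (conservative)."""
    config = config or CascadeConfig()
    trails = trails if trails is not None else {}
    affected = pedigree.affected_ids
    unaffected = pedigree.unaffected_sibling_ids()
    required = affected + unaffected

    def pred(v: AnnotatedVariant):
        absent = [s for s in required if s not in v.genotypes]
        if absent:
            raise ValidationError(
                f"variant {v.key}: no genotype entry for pedigree samples {absent}"
            )
        for s in required:
            if v.genotypes[s] == -1:
                return False, f"missing genotype for {s}"
        for s in affected:
            if v.genotypes[s] != 2:
                return False, f"affected {s} not hom-alt ({v.genotypes[s]})"
        for s in unaffected:
            if v.genotypes[s] > config.max_unaffected_code:
                return False, f"unaffected {s} exceeds het ({v.genotypes[s]})"
        return True, ""

    return _apply(variants, trails, "recessive_pattern", pred), trails


def restrict_to_regions(
    variants: Sequence[AnnotatedVariant],
    shared_loh_segments: SegmentSet,
    trails: Optional[dict[VariantKey, FilterTrail]] = None,
) -> tuple[list[AnnotatedVariant], dict[VariantKey, FilterTrail]]:
    """Keep variants whose (half-open converted) position falls inside any
    shared-autozygosity segment."""
    trails = trails if trails is not None else {}

    def pred(v: AnnotatedVariant):
        ok = shared_loh_segments.contains(v.chrom, v.pos - 1)
        return ok, "" if ok else "outside shared-LOH regions"

    return _apply(variants, trails, "region_overlap", pred), trails


def parental_segregation_check(
    variant: AnnotatedVariant, pedigree: Pedigree
) -> tuple[str, str]:
    """Check that both parents of the affected sibship are het carriers.

    Returns (verdict, detail): ``consistent`` when both parents are coded 1,
    ``inconsistent`` otherwise, ``untestable`` when a parental genotype is
    missing.  Reported alongside the cascade, not used as a hard filter.
    """
    parents = pedigree.parents_of_affected()
    if parents is None:
        return "untestable", "affected siblings do not share a single parent pair"
    codes = {p: variant.genotypes.get(p, -1) for p in parents}
    if any(c == -1 for c in codes.values()):
        return "untestable", f"parental genotype missing: {codes}"
    if all(c == 1 for c in codes.values()):
        return "consistent", "both parents heterozygous carriers"
    return "inconsistent", f"parental genotypes {codes}"


@dataclass
class CandidateReport:
    survivors: list[AnnotatedVariant]
    trails: dict[VariantKey, FilterTrail]
    segregation: dict[VariantKey, tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        """One row per input variant: annotations, verdicts, segregation."""
        rows = []
        surviving = {v.key for v in self.survivors}
        for key, trail in self.trails.items():
            row: dict = {
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "survived": key in surviving,
                "failing_filter": trail.failing_filter or "",
            }
            for name, status, detail in trail.verdicts:
                row[f"filter_{name}"] = status
            verdict = self.segregation.get(key)
            row["segregation"] = verdict[0] if verdict else ""
            rows.append(row)
        return pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)


def run_prioritization(
    variants: Sequence[AnnotatedVariant],
    pedigree: Pedigree,
    shared_loh_segments: Optional[SegmentSet] = None,
    config: CascadeConfig | None = None,
) -> CandidateReport:
    """Apply the full cascade in fixed order and report survivors + trails.

    Order: functional -> rare -> recessive pattern -> region restriction.
    The filters are independent predicates, so the survivor set is invariant
    under reordering; the order only affects which filter a failure is
    charged to.  Survivors are returned sorted by (chrom, pos) with a
    parental segregation verdict each.
    """
    config = config or CascadeConfig()
    trails: dict[VariantKey, FilterTrail] = {}
    survivors, trails = filter_functional(variants, config, trails)
    survivors, trails = filter_rare(survivors, config, trails)
    survivors, trails = filter_recessive_pattern(survivors, pedigree, config, trails)
    if config.require_region_overlap:
        if shared_loh_segments is None:
            raise ValidationError(
                "require_region_overlap is set but no shared-LOH segments given"
            )
        survivors, trails = restrict_to_regions(survivors, shared_loh_segments, trails)
    # complete trails for variants knocked out early: mark skipped stages
    stage_names = ["functional", "rare", "recessive_pattern"] + (
        ["region_overlap"] if config.require_region_overlap else []
    )
    for v in variants:
        trail = trails[v.key]
        seen = {name for name, _, _ in trail.verdicts}
        for name in stage_names:
            if name not in seen:
                trail.record(name, True, "")  # becomes not-evaluated after a fail
    survivors = sorted(survivors, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    segregation = {
        v.key: parental_segregation_check(v, pedigree) for v in survivors
    }
    return CandidateReport(survivors, trails, segregation)
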