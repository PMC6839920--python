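"""Synthetic consanguineous-pedigree datasets with known ground truth.

Gene dropping: founders receive two uniquely labelled haplotypes each; every
meiosis places crossovers as a Poisson process (Haldane model, no
interference) and transmits a mosaic of the parent's two haplotypes.  An
offspring is autozygous wherever its two haplotype labels coincide.  The
default pedigree makes the two parents first cousins (shared grandparental
couple), with three affected and two unaffected children, and plants a single
rare homozygous missense variant inside a tract autozygous in all affected
children — a guaranteed-positive control for the downstream filter cascade.

All stochastic operations are pure functions of (inputs, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import PlantingError, ValidationError
from .intervals import Segment, SegmentSet
from .pedigree import Individual, Pedigree
from .variants import AnnotatedVariant, GenotypePanel, FUNCTIONAL_CLASSES

# A haplotype is a list of (start, end, label) tracts covering [0, L).
Tract = tuple[int, int, int]
Haplotype = list[Tract]

_MAX_SEED = 2**31


@dataclass(frozen=True)
class CausalVariantSpec:
    """Profile of the planted recessive variant.

    Defaults emulate an ultra-rare coding missense allele: population AFs all
    below 1%, CDS offset 230 (codon 77, second base).
    """

    chrom: Optional[str] = None  # None: choose the largest eligible tract
    pos: Optional[int] = None  # 1-based; relocated if not eligible
    ref: str = "G"
    alt: str = "A"
    gene: str = "GENE_CAUSAL"
    consequence: str = "missense"
    cds_pos: int = 230
    protein_pos: int = 77
    pop_afs: dict[str, float] = field(
        default_factory=lambda: {"ExAC": 0.00014, "1KG": 0.0, "TOPMED": 0.0002}
    )


@dataclass(frozen=True)
class SimulationConfig:
    pedigree_template: str = "first_cousin_parents"
    n_affected_offspring: int = 3
    n_unaffected_offspring: int = 2
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 25_000_000,
            "chr2": 25_000_000,
            "chr3": 25_000_000,
            "chr4": 25_000_000,
        }
    )
    marker_density: float = 100.0  # markers per Mb
    background_variant_rate: float = 0.5  # coding-region variants per Mb
    causal_variant: Optional[CausalVariantSpec] = field(
        default_factory=CausalVariantSpec
    )
    recomb_rate: float = 0.01  # Morgans per Mb (1 cM/Mb)
    genotyping_error_rate: float = 0.0
    #: minimum length of the tract the causal variant is planted in; real
    #: autozygous disease segments in first-cousin offspring span megabases,
    #: and shorter tracts would be invisible to ROH scans at array density
    min_causal_tract_bp: int = 2_000_000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("marker_density", "background_variant_rate", "recomb_rate",
                     "genotyping_error_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.causal_variant is not None and self.n_affected_offspring < 1:
            raise ValidationError(
                "planting a causal variant requires at least one affected offspring"
            )
        if self.causal_variant is not None:
            for db, af in self.causal_variant.pop_afs.items():
                if af >= 0.01:
                    raise ValidationError(
                        f"causal variant must be rare; {db} AF {af} >= 0.01"
                    )

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValidationError("seed is mandatory for stochastic operations")
        return self.seed


def build_looped_pedigree(config: SimulationConfig) -> Pedigree:
    """Nuclear family whose parents are first cousins.

    The loop runs through one shared grandparental couple (G1 x G2): their
    children C1 and C2 marry unrelated founders SP1 and SP2, producing the
    father FA and mother MO of the sibship.  Affected children are P1..Pn,
    unaffected S1..Sm.
    """
    if config.pedigree_template != "first_cousin_parents":
        raise ValidationError(
            f"unknown pedigree template {config.pedigree_template!r}; "
            "pass a custom Pedigree directly to gene_drop"
        )
    members = [
        Individual("G1", sex="male"),
        Individual("G2", sex="female"),
        Individual("SP1", sex="female"),
        Individual("SP2", sex="male"),
        Individual("C1", "G1", "G2", sex="male"),
        Individual("C2", "G1", "G2", sex="female"),
        Individual("FA", "C1", "SP1", sex="male", affected="unaffected"),
        Individual("MO", "SP2", "C2", sex="female", affected="unaffected"),
    ]
    for i in range(config.n_affected_offspring):
        members.append(Individual(f"P{i + 1}", "FA", "MO", affected="affected"))
    for i in range(config.n_unaffected_offspring):
        members.append(Individual(f"S{i + 1}", "FA", "MO", affected="unaffected"))
    return Pedigree(members, family_id="SIMFAM")


# ---------------------------------------------------------------------------
# haplotype mechanics

def _gamete(
    parent_haps: tuple[Haplotype, Haplotype],
    chrom_len: int,
    recomb_rate: float,
    rng: np.random.Generator,
) -> Haplotype:
    """One meiotic product: Poisson crossovers, random starting phase."""
    n_x = rng.poisson(recomb_rate * chrom_len / 1e6)
    xs = np.unique(rng.integers(1, chrom_len, size=n_x)) if n_x else np.array([], int)
    phase = int(rng.integers(2))
    bounds = [0, *xs.tolist(), chrom_len]
    out: Haplotype = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if lo >= hi:
            continue
        source = parent_haps[(phase + k) % 2]
        for s, e, lab in source:
            cs, ce = max(s, lo), min(e, hi)
            if cs < ce:
                if out and out[-1][2] == lab and out[-1][1] == cs:
                    out[-1] = (out[-1][0], ce, lab)
                else:
                    out.append((cs, ce, lab))
    return out


def _drop_haplotypes(
    pedigree: Pedigree, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, dict[str, tuple[Haplotype, Haplotype]]]:
    """Assign founder labels and transmit mosaics through every meiosis."""
    founder_ids = [ind.sample_id for ind in pedigree.founders]
    label_of = {
        (sid, j): 2 * i + j for i, sid in enumerate(founder_ids) for j in (0, 1)
    }
    haps: dict[str, dict[str, tuple[Haplotype, Haplotype]]] = {}
    for sid in pedigree.topological_order:
        ind = pedigree[sid]
        haps[sid] = {}
        for chrom, L in config.chrom_lengths.items():
            if ind.is_founder:
                haps[sid][chrom] = (
                    [(0, L, label_of[(sid, 0)])],
                    [(0, L, label_of[(sid, 1)])],
                )
            else:
                haps[sid][chrom] = (
                    _gamete(haps[ind.father_id][chrom], L, config.recomb_rate, rng),
                    _gamete(haps[ind.mother_id][chrom], L, config.recomb_rate, rng),
                )
    return haps


def _labels_at(hap: Haplotype, positions: np.ndarray) -> np.ndarray:
    """Haplotype label under each 1-based position (vectorized)."""
    ends = np.array([e for _, e, _ in hap], dtype=np.int64)
    labels = np.array([lab for _, _, lab in hap], dtype=np.int64)
    # position p (1-based) occupies internal coordinate p-1
    return labels[np.searchsorted(ends, positions - 1, side="right")]


def _label_at(hap: Haplotype, pos: int) -> int:
    return int(_labels_at(hap, np.array([pos]))[0])


def _autozygous_tracts(
    pair: tuple[Haplotype, Haplotype]
) -> list[tuple[int, int, int]]:
    """Intervals where both haplotype labels coincide, with the shared label."""
    h0, h1 = pair
    out: list[tuple[int, int, int]] = []
    i = j = 0
    while i < len(h0) and j < len(h1):
        s = max(h0[i][0], h1[j][0])
        e = min(h0[i][1], h1[j][1])
        if s < e and h0[i][2] == h1[j][2]:
            if out and out[-1][1] == s and out[-1][2] == h0[i][2]:
                out[-1] = (out[-1][0], e, out[-1][2])
            else:
                out.append((s, e, h0[i][2]))
        if h0[i][1] < h1[j][1]:
            i += 1
        else:
            j += 1
    return out


# ---------------------------------------------------------------------------
# dataset assembly

@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must rediscover."""

    autozygous_segments: dict[str, SegmentSet]
    causal_variant: Optional[AnnotatedVariant] = None
    causal_region: Optional[Segment] = None
    relocated: bool = False
    #: per-offspring labelled autozygous tracts: sid -> chrom -> [(s, e, label)]
    labeled_tracts: dict[str, dict[str, list[tuple[int, int, int]]]] = field(
        default_factory=dict
    )

    def autozygous_fraction(self, sample_id: str, genome_bp: int) -> float:
        return self.autozygous_segments[sample_id].total_bp / genome_bp


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    panel: GenotypePanel
    variants: list[AnnotatedVariant]
    truth: GroundTruth
    config: SimulationConfig
    haplotypes: dict[str, dict[str, tuple[Haplotype, Haplotype]]] = field(
        default_factory=dict, repr=False
    )

    @property
    def offspring_ids(self) -> list[str]:
        return self.pedigree.affected_ids + self.pedigree.unaffected_sibling_ids()


_CONSEQUENCE_CHOICES = (
    "missense", "synonymous", "intronic", "stop_gained",
    "frameshift", "splice_acceptor", "splice_donor", "other",
)
_CONSEQUENCE_PROBS = (0.30, 0.25, 0.20, 0.05, 0.05, 0.05, 0.05, 0.05)
_BASES = np.array(list("ACGT"))


def gene_drop(
    pedigree: Pedigree, config: SimulationConfig, seed: Optional[int] = None
) -> tuple[GenotypePanel, list[AnnotatedVariant], GroundTruth]:
    """Drop haplotypes through the pedigree; emit markers, variants, truth.

    Marker alt-allele frequencies are drawn Uniform(0.05, 0.5) so founders are
    reliably heterozygous and homozygosity runs carry signal.  Background
    coding variants receive genotypes by transmission from randomly chosen
    carrier founder haplotypes.  Ground truth (autozygous tracts per
    offspring) is recorded before any error injection.
    """
    if seed is None:
        seed = config.require_seed()
    rng = np.random.default_rng(seed)
    haps = _drop_haplotypes(pedigree, config, rng)
    n_founder_haps = 2 * len(pedigree.founders)
    samples = pedigree.sample_ids

    markers: list[tuple[str, int, str]] = []
    call_blocks: list[np.ndarray] = []
    variants: list[AnnotatedVariant] = []
    for chrom, L in config.chrom_lengths.items():
        n = int(round(config.marker_density * L / 1e6))
        positions = np.unique(rng.integers(1, L + 1, size=n)) if n else np.array([], int)
        p = rng.uniform(0.05, 0.5, size=len(positions))
        alleles = rng.random((len(positions), n_founder_haps)) < p[:, None]
        block = np.empty((len(positions), len(samples)), dtype=np.int8)
        for si, sid in enumerate(samples):
            h0, h1 = haps[sid][chrom]
            lab0 = _labels_at(h0, positions)
            lab1 = _labels_at(h1, positions)
            rows = np.arange(len(positions))
            block[:, si] = alleles[rows, lab0].astype(np.int8) + alleles[
                rows, lab1
            ].astype(np.int8)
        call_blocks.append(block)
        markers.extend(
            (chrom, int(pos), f"{chrom}_m{k}") for k, pos in enumerate(positions)
        )

        # background coding/intronic variants
        n_bg = rng.poisson(config.background_variant_rate * L / 1e6)
        bg_pos = np.unique(rng.integers(1, L + 1, size=n_bg)) if n_bg else []
        for pos in bg_pos:
            common = rng.random() < 0.6
            af = rng.uniform(0.01, 0.5) if common else rng.uniform(1e-4, 0.0099)
            pop_afs = {
                db: float(np.clip(af * rng.uniform(0.8, 1.25), 0.0, 1.0))
                for db in ("ExAC", "1KG", "TOPMED")
                if rng.random() < 0.9
            }
            csq = str(rng.choice(_CONSEQUENCE_CHOICES, p=_CONSEQUENCE_PROBS))
            coding = csq not in ("intronic", "other")
            cds = int(rng.integers(1, 1500)) if coding else None
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            carrier = rng.random(n_founder_haps) < af
            genotypes = {}
            for sid in samples:
                h0, h1 = haps[sid][chrom]
                genotypes[sid] = int(
                    carrier[_label_at(h0, int(pos))] + carrier[_label_at(h1, int(pos))]
                )
            variants.append(
                AnnotatedVariant(
                    chrom=chrom,
                    pos=int(pos),
                    ref=str(ref),
                    alt=str(alt),
                    gene=f"G{chrom.removeprefix('chr')}_{int(pos) // 1_000_000}",
                    consequence=csq,
                    cds_pos=cds,
                    protein_pos=math.ceil(cds / 3) if cds else None,
                    pop_afs=pop_afs,
                    genotypes=genotypes,
                )
            )

    panel = GenotypePanel(markers, samples, np.vstack(call_blocks))
    truth = _truth_from_haplotypes(pedigree, config, haps)
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return panel, variants, truth


def _truth_from_haplotypes(
    pedigree: Pedigree,
    config: SimulationConfig,
    haps: dict[str, dict[str, tuple[Haplotype, Haplotype]]],
) -> GroundTruth:
    offspring = pedigree.affected_ids + pedigree.unaffected_sibling_ids()
    truth = GroundTruth(autozygous_segments={}, labeled_tracts={})
    for sid in offspring:
        segs = []
        tracts: dict[str, list[tuple[int, int, int]]] = {}
        for chrom in config.chrom_lengths:
            tr = _autozygous_tracts(haps[sid][chrom])
            tracts[chrom] = tr
            segs.extend(Segment(chrom, s, e, sample_id=sid) for s, e, _ in tr)
        truth.autozygous_segments[sid] = SegmentSet(segs)
        truth.labeled_tracts[sid] = tracts
    return truth


def _candidate_tracts(
    truth: GroundTruth, affected: Sequence[str], unaffected: Sequence[str]
) -> list[tuple[int, Segment]]:
    """Tracts autozygous for one shared label in every affected offspring and
    clear of any unaffected autozygosity, as (label, segment) pairs."""

    def label_sets(sid: str) -> dict[int, SegmentSet]:
        by_label: dict[int, list[Segment]] = {}
        for chrom, tracts in truth.labeled_tracts[sid].items():
            for s, e, lab in tracts:
                by_label.setdefault(lab, []).append(Segment(chrom, s, e))
        return {lab: SegmentSet(segs) for lab, segs in by_label.items()}

    per_affected = [label_sets(sid) for sid in affected]
    shared_labels = set(per_affected[0])
    for d in per_affected[1:]:
        shared_labels &= set(d)
    unaffected_auto = SegmentSet()
    for sid in unaffected:
        unaffected_auto = unaffected_auto.union(truth.autozygous_segments[sid])
    candidates: list[tuple[int, Segment]] = []
    for lab in sorted(shared_labels):
        inter = per_affected[0][lab]
        for d in per_affected[1:]:
            inter = inter.intersect(d[lab])
        for seg in inter.subtract(unaffected_auto):
            candidates.append((lab, seg))
    return candidates


def plant_causal_variant(
    dataset: SimulatedDataset,
    spec: Optional[CausalVariantSpec] = None,
    min_tract_bp: int = 0,
) -> SimulatedDataset:
    """Plant the recessive causal variant inside a shared autozygous tract.

    The eligible region is, per shared founder label, the intersection of the
    affected offspring's autozygous tracts carrying that label, minus any
    tract autozygous in an unaffected sibling.  If the requested position is
    not eligible the variant is relocated to the nearest eligible tract (the
    move is recorded on the ground truth).  By construction every affected
    child is hom-alt, both parents are heterozygous carriers, and unaffected
    siblings are het or hom-ref.
    """
    spec = spec or dataset.config.causal_variant or CausalVariantSpec()
    ped = dataset.pedigree
    affected = ped.affected_ids
    unaffected = ped.unaffected_sibling_ids()
    if not affected:
        raise ValidationError("cannot plant a causal variant without affected offspring")
    candidates = _candidate_tracts(dataset.truth, affected, unaffected)
    if min_tract_bp:
        long_enough = [c for c in candidates if c[1].length >= min_tract_bp]
        candidates = long_enough or candidates
    if not candidates:
        raise PlantingError(
            "no tract is autozygous in all affected offspring and clear of "
            "unaffected autozygosity; rerun the simulation with a new seed"
        )

    requested = (
        (spec.chrom, spec.pos) if spec.chrom is not None and spec.pos is not None
        else None
    )
    relocated = False
    chosen = None
    if requested is not None:
        chrom, pos = requested
        p0 = pos - 1
        for lab, seg in candidates:
            if seg.chrom == chrom and seg.start <= p0 < seg.end:
                chosen = (lab, seg, pos)
                break
        if chosen is None:
            relocated = True
            same = [(lab, seg) for lab, seg in candidates if seg.chrom == chrom]
            pool = same or candidates
            lab, seg = min(
                pool,
                key=lambda c: min(abs(c[1].start - p0), abs(c[1].end - 1 - p0)),
            )
            chosen = (lab, seg, (seg.start + seg.end) // 2 + 1)
    else:
        lab, seg = max(candidates, key=lambda c: c[1].length)
        chosen = (lab, seg, (seg.start + seg.end) // 2 + 1)

    lab, seg, pos = chosen
    genotypes = {}
    for sid in ped.sample_ids:
        h0, h1 = dataset.haplotypes[sid][seg.chrom]
        genotypes[sid] = int(
            (_label_at(h0, pos) == lab) + (_label_at(h1, pos) == lab)
        )
    causal = AnnotatedVariant(
        chrom=seg.chrom,
        pos=pos,
        ref=spec.ref,
        alt=spec.alt,
        gene=spec.gene,
        consequence=spec.consequence,
        cds_pos=spec.cds_pos,
        protein_pos=spec.protein_pos,
        pop_afs=dict(spec.pop_afs),
        genotypes=genotypes,
    )
    variants = sorted(
        dataset.variants + [causal], key=lambda v: (v.chrom, v.pos)
    )
    truth = replace(
        dataset.truth,
        causal_variant=causal,
        causal_region=Segment(seg.chrom, seg.start, seg.end),
        relocated=relocated,
    )
    return replace(dataset, variants=variants, truth=truth)


def inject_genotyping_error(
    panel: GenotypePanel, rate: float, seed: int
) -> GenotypePanel:
    """Independently corrupt each call with probability ``rate``.

    A corrupted call is replaced by a uniform choice among the other three
    codes in {-1, 0, 1, 2}.
    """
    if not (0.0 <= rate < 1.0):
        raise ValidationError(f"error rate must be in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    calls = panel.calls.copy()
    if rate > 0.0:
        mask = rng.random(calls.shape) < rate
        offset = rng.integers(1, 4, size=calls.shape)
        idx = calls.astype(np.int16) + 1  # codes -1..2 -> 0..3
        new = ((idx + offset) % 4 - 1).astype(np.int8)
        calls[mask] = new[mask]
    return GenotypePanel(panel.markers, panel.samples, calls)


def _passes_cascade_predicates(
    v: AnnotatedVariant, affected: Sequence[str], unaffected: Sequence[str]
) -> bool:
    """Would this variant pass the functional+rare+recessive predicates?"""
    if v.consequence not in FUNCTIONAL_CLASSES:
        return False
    if any(af >= 0.01 for af in v.pop_afs.values()):
        return False
    if any(v.genotypes.get(s) != 2 for s in affected):
        return False
    if any(not (0 <= v.genotypes.get(s, -1) <= 1) for s in unaffected):
        return False
    return True


def simulate(config: SimulationConfig, max_tries: int = 1024) -> SimulatedDataset:
    """Full dataset generation with deterministic retry.

    On a scaled genome (the default is 100 Mb at 1 cM/Mb, about one Morgan)
    many haplotype drops yield no tract autozygous in all affected children
    — a small genome carries only a handful of independently segregating
    blocks, so three-way same-label sharing is a rare event per drop even
    though it is near-certain at whole-genome scale.  Sub-seeds derived
    deterministically from the base seed are therefore tried in fixed order;
    feasibility is checked on the haplotype drop alone (cheap) before markers
    and variants are generated, and a drop is also rejected when a background
    variant coincidentally satisfies the recessive cascade (which would break
    the guaranteed-positive-control contract).  Genotyping error is injected
    into the marker panel last, after ground truth is frozen; the causal
    variant lives in the variant list, not the panel, and is therefore never
    corrupted.
    """
    base = config.require_seed()
    ped = build_looped_pedigree(config)
    affected = ped.affected_ids
    unaffected = ped.unaffected_sibling_ids()
    last_error: Optional[Exception] = None
    for i in range(max_tries):
        sub = (base + 9973 * i) % _MAX_SEED
        # cheap feasibility check: haplotypes only, no markers or variants.
        # gene_drop consumes its rng in the same order, so the same sub-seed
        # reproduces exactly these haplotypes.
        haps = _drop_haplotypes(ped, config, np.random.default_rng(sub))
        if config.causal_variant is not None:
            truth0 = _truth_from_haplotypes(ped, config, haps)
            tracts = _candidate_tracts(truth0, affected, unaffected)
            if not any(
                seg.length >= config.min_causal_tract_bp for _, seg in tracts
            ):
                last_error = PlantingError(
                    "no shared autozygous tract of sufficient length"
                )
                continue
        panel, variants, truth = gene_drop(ped, config, seed=sub)
        dataset = SimulatedDataset(ped, panel, variants, truth, config, haps)
        if config.causal_variant is not None:
            dataset = plant_causal_variant(
                dataset, config.causal_variant, config.min_causal_tract_bp
            )
            confounders = [
                v
                for v in dataset.variants
                if v is not dataset.truth.causal_variant
                and _passes_cascade_predicates(v, affected, unaffected)
            ]
            if confounders:
                last_error = PlantingError(
                    f"background variant mimics the recessive pattern: "
                    f"{[v.key for v in confounders]}"
                )
                continue
        if config.genotyping_error_rate > 0:
            dataset = replace(
                dataset,
                panel=inject_genotyping_error(
                    dataset.panel,
                    config.genotyping_error_rate,
                    seed=(sub + 1) % _MAX_SEED,
                ),
            )
        return dataset
    raise PlantingError(
        f"no valid dataset in {max_tries} attempts from seed {base}: {last_error}"
    )


def autozygous_fraction_replicates(
    n_replicates: int, config: SimulationConfig, seed: int
) -> np.ndarray:
    """Autozygous genome fraction of one first-cousin offspring, replicated.

    Each replicate re-drops haplotypes through a fresh pedigree (haplotypes
    only; no markers or variants), so replicates are independent draws whose
    mean converges to the pedigree's analytic inbreeding coefficient.
    """
    cfg = replace(
        config, n_affected_offspring=1, n_unaffected_offspring=0, causal_variant=None
    )
    ped = build_looped_pedigree(cfg)
    genome = sum(cfg.chrom_lengths.values())
    rng = np.random.default_rng(seed)
    out = np.empty(n_replicates)
    for k in range(n_replicates):
        haps = _drop_haplotypes(ped, cfg, rng)
        auto = 0
        for chrom in cfg.chrom_lengths:
            auto += sum(e - s for s, e, _ in _autozygous_tracts(haps["P1"][chrom]))
        out[k] = auto / genome
    return out


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Emit PED + VCF + panel TSV + ground-truth BED/JSON into a directory."""
    from . import formats_io  # local import to avoid a cycle at import time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    formats_io.write_ped(dataset.pedigree, outdir / "family.ped")
    formats_io.write_vcf(
        dataset.variants, dataset.pedigree.sample_ids, outdir / "variants.vcf"
    )
    formats_io.write_panel_tsv(dataset.panel, outdir / "panel.tsv")
    all_auto = SegmentSet(
        seg
        for segs in dataset.truth.autozygous_segments.values()
        for seg in segs
    )
    formats_io.write_bed(all_auto, outdir / "truth_autozygous.bed")
    truth_json = {
        "relocated": dataset.truth.relocated,
        "causal_variant": (
            {
                "chrom": dataset.truth.causal_variant.chrom,
                "pos": dataset.truth.causal_variant.pos,
                "ref": dataset.truth.causal_variant.ref,
                "alt": dataset.truth.causal_variant.alt,
                "gene": dataset.truth.causal_variant.gene,
                "genotypes": dataset.truth.causal_variant.genotypes,
            }
            if dataset.truth.causal_variant is not None
            else None
        ),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=2) + "\n")
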