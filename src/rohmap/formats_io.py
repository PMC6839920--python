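"""Readers and writers for the standard formats the pipeline touches.

PED (6-column), a VCF v4.2 subset (GT format field, configurable INFO keys),
BED3+name(+marker count), TSV genotype panels and YAML configs.  All files are
plain text.  Internal coordinates are 0-based half-open; conversion to and
from 1-based display coordinates goes through :mod:`rohmap.intervals`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .errors import FormatError, ValidationError
from .intervals import Segment, SegmentSet, to_internal
from .pedigree import Individual, Pedigree
from .variants import AnnotatedVariant, GenotypePanel

PathLike = Union[str, Path]

_SEX_CODES = {"1": "male", "2": "female"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_AFF_CODES = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
_AFF_OUT = {"affected": "2", "unaffected": "1", "unknown": "0"}


# ---------------------------------------------------------------------------
# PED

def read_ped(path: PathLike) -> Pedigree:
    """Read a 6-column PED file into a validated :class:`Pedigree`.

    Columns: family, sample, father, mother, sex (1=male, 2=female, 0=unknown),
    phenotype (2=affected, 1=unaffected, 0/-9=unknown).  ``0`` marks a missing
    parent.
    """
    members = []
    family_ids = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            fam, sid, father, mother, sex, pheno = fields
            family_ids.add(fam)
            members.append(
                Individual(
                    sample_id=sid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODES.get(sex, "unknown"),
                    affected=_AFF_CODES.get(pheno, "unknown"),
                )
            )
    if not members:
        raise FormatError(f"{path}: empty PED file")
    if len(family_ids) > 1:
        raise FormatError(f"{path}: multiple family ids {sorted(family_ids)}")
    try:
        return Pedigree(members, family_id=family_ids.pop())
    except ValidationError as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_ped(pedigree: Pedigree, path: PathLike) -> None:
    with open(path, "w") as fh:
        for ind in pedigree:
            fh.write(
                "\t".join(
                    [
                        pedigree.family_id,
                        ind.sample_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_OUT[ind.sex],
                        _AFF_OUT[ind.affected],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF subset

@dataclass
class InfoFieldMap:
    """Names of the INFO keys carrying each annotation."""

    gene: str = "GENE"
    consequence: str = "CSQ"
    cds_pos: str = "CDS_POS"
    protein_pos: str = "PROT_POS"
    pop_afs: dict[str, str] = field(
        default_factory=lambda: {
            "ExAC": "AF_EXAC",
            "1KG": "AF_1KG",
            "TOPMED": "AF_TOPMED",
        }
    )


def _info_scalar(value, alt_index: int, n_alts: int):
    """Pick the per-alt entry of an INFO value.

    Scalar values are duplicated across decomposed alts; tuple values of
    length n_alts are split positionally.
    """
    if isinstance(value, tuple):
        if len(value) == n_alts:
            value = value[alt_index]
        else:
            value = value[0] if value else None
    return value


def read_vcf_subset(
    path: PathLike,
    info_field_map: Optional[InfoFieldMap] = None,
    pedigree: Optional[Pedigree] = None,
) -> list[AnnotatedVariant]:
    """Read a VCF into :class:`AnnotatedVariant` records.

    Multi-allelic records are decomposed into one biallelic record per ALT;
    genotype codes count copies of that ALT, and any GT containing ``.`` maps
    to ``-1``.  Missing INFO keys become missing fields, never errors.  When a
    pedigree is supplied, samples in the VCF header that are not in the
    pedigree trigger a warning (not an error).
    """
    fmap = info_field_map or InfoFieldMap()
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if pedigree is not None:
        unknown = [s for s in samples if s not in pedigree]
        if unknown:
            warnings.warn(
                f"{path}: samples not in pedigree: {unknown}", stacklevel=2
            )
    out: list[AnnotatedVariant] = []
    for rec in vcf:
        alts = rec.ALT or []
        n_alts = len(alts)
        try:
            gts = rec.genotypes  # [[a1, a2, phased], ...]
        except Exception as exc:  # pragma: no cover - cyvcf2 parse failure
            raise FormatError(
                f"{path}: malformed genotype at {rec.CHROM}:{rec.POS}"
            ) from exc
        for ai, alt in enumerate(alts):
            genotypes: dict[str, int] = {}
            for s, gt in zip(samples, gts):
                alleles = [a for a in gt[:-1] if a is not None]
                if len(alleles) < 2 or any(a < 0 for a in alleles):
                    genotypes[s] = -1
                else:
                    genotypes[s] = sum(a == ai + 1 for a in alleles)
            info = rec.INFO
            pop_afs: dict[str, float] = {}
            for db, key in fmap.pop_afs.items():
                raw = _info_scalar(info.get(key), ai, n_alts)
                if raw is not None:
                    pop_afs[db] = float(raw)
            cds = _info_scalar(info.get(fmap.cds_pos), ai, n_alts)
            prot = _info_scalar(info.get(fmap.protein_pos), ai, n_alts)
            csq = _info_scalar(info.get(fmap.consequence), ai, n_alts)
            out.append(
                AnnotatedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=_info_scalar(info.get(fmap.gene), ai, n_alts),
                    consequence=str(csq).lower() if csq is not None else None,
                    cds_pos=int(cds) if cds is not None else None,
                    protein_pos=int(prot) if prot is not None else None,
                    pop_afs=pop_afs,
                    genotypes=genotypes,
                )
            )
    return out


_GT_OUT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(
    variants: Sequence[AnnotatedVariant],
    samples: Sequence[str],
    path: PathLike,
    info_field_map: Optional[InfoFieldMap] = None,
) -> None:
    """Write biallelic annotated variants as a minimal VCF v4.2 file."""
    fmap = info_field_map or InfoFieldMap()
    lines = ["##fileformat=VCFv4.2"]
    for chrom in sorted({v.chrom for v in variants}):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(f'##INFO=<ID={fmap.gene},Number=1,Type=String,Description="Gene symbol">')
    lines.append(f'##INFO=<ID={fmap.consequence},Number=1,Type=String,Description="Consequence">')
    lines.append(f'##INFO=<ID={fmap.cds_pos},Number=1,Type=Integer,Description="CDS position">')
    lines.append(f'##INFO=<ID={fmap.protein_pos},Number=1,Type=Integer,Description="Protein residue">')
    for db, key in fmap.pop_afs.items():
        lines.append(
            f'##INFO=<ID={key},Number=A,Type=Float,Description="Allele frequency in {db}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        info_parts = []
        if v.gene is not None:
            info_parts.append(f"{fmap.gene}={v.gene}")
        if v.consequence is not None:
            info_parts.append(f"{fmap.consequence}={v.consequence}")
        if v.cds_pos is not None:
            info_parts.append(f"{fmap.cds_pos}={v.cds_pos}")
        if v.protein_pos is not None:
            info_parts.append(f"{fmap.protein_pos}={v.protein_pos}")
        for db, key in fmap.pop_afs.items():
            if db in v.pop_afs:
                info_parts.append(f"{key}={v.pop_afs[db]:.6g}")
        gts = "\t".join(_GT_OUT[v.genotypes.get(s, -1)] for s in samples)
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
            f"{';'.join(info_parts) or '.'}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED

def write_bed(segments: SegmentSet, path: PathLike) -> None:
    """Write segments as BED (0-based half-open), sorted by (chrom, start).

    Column 4 carries the sample id and column 5 the supporting marker count
    when present, so a round-trip preserves both.
    """
    with open(path, "w") as fh:
        for seg in sorted(segments, key=Segment.sort_key):
            fields = [seg.chrom, str(seg.start), str(seg.end)]
            if seg.sample_id is not None or seg.n_markers is not None:
                fields.append(seg.sample_id if seg.sample_id is not None else ".")
            if seg.n_markers is not None:
                fields.append(str(seg.n_markers))
            fh.write("\t".join(fields) + "\n")


def read_bed(path: PathLike) -> SegmentSet:
    segs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            sample_id = None
            n_markers = None
            if len(fields) >= 4 and fields[3] != ".":
                sample_id = fields[3]
            if len(fields) >= 5 and fields[4] != ".":
                n_markers = int(fields[4])
            segs.append(Segment(chrom, start, end, sample_id, n_markers))
    return SegmentSet(segs)


# ---------------------------------------------------------------------------
# Genotype panel TSV

def write_panel_tsv(panel: GenotypePanel, path: PathLike) -> None:
    df = pd.DataFrame(
        panel.calls, columns=panel.samples
    )
    df.insert(0, "marker", [m for _, _, m in panel.markers])
    df.insert(1, "chrom", [c for c, _, _ in panel.markers])
    df.insert(2, "pos", [p for _, p, _ in panel.markers])
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: PathLike) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["marker", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"{path}: first columns must be {required}")
    samples = list(df.columns[3:])
    markers = list(zip(df["chrom"], df["pos"].astype(int), df["marker"]))
    return GenotypePanel(markers, samples, df[samples].to_numpy(dtype=np.int8))


# ---------------------------------------------------------------------------
# Config

def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return data


def segment_from_display(
    chrom: str, start_1based: int, end_1based: int, **kwargs
) -> Segment:
    """Build a Segment from 1-based inclusive (table/VCF-style) coordinates."""
    start, end = to_internal(start_1based, end_1based)
    return Segment(chrom, start, end, **kwargs)
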