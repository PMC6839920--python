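"""Per-residue variant-burden tracks along a protein, and HGVS-style
CDS-to-codon arithmetic.

The burden track aggregates population allele frequencies of coding variants
at each residue of a protein (a "lollipop"-style summary), with optional
domain annotations such as EF-hand intervals.  The codon arithmetic maps a
CDS nucleotide offset (c. coordinate) to its codon and translates a single
base substitution to the amino-acid change (p. coordinate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .errors import ValidationError
from .variants import AnnotatedVariant

_DNA = set("ACGT")


def cds_to_codon(cds_pos: int) -> tuple[int, int]:
    """Map a 1-based CDS nucleotide offset to (codon index, position in codon).

    Codon index is the 1-based residue number; position in codon is 1..3.
    c.230 falls in codon 77, position 2.
    """
    if not isinstance(cds_pos, (int, np.integer)) or cds_pos < 1:
        raise ValidationError(f"cds_pos must be a positive integer, got {cds_pos!r}")
    codon_index = math.ceil(cds_pos / 3)
    position_in_codon = (cds_pos - 1) % 3 + 1
    return codon_index, position_in_codon


def apply_codon_change(
    ref_codon: str, position_in_codon: int, alt_base: str
) -> tuple[str, str]:
    """Translate a single-base substitution within one codon.

    Returns three-letter amino-acid names (HGVS style, stop = ``Ter``), e.g.
    ``("CGC", 2, "A") -> ("Arg", "His")``.
    """
    if len(ref_codon) != 3 or any(b not in _DNA for b in ref_codon):
        raise ValidationError(f"ref_codon must be 3 uppercase DNA bases, got {ref_codon!r}")
    if position_in_codon not in (1, 2, 3):
        raise ValidationError("position_in_codon must be 1, 2 or 3")
    if alt_base not in _DNA:
        raise ValidationError(f"invalid alt base {alt_base!r}")
    if ref_codon[position_in_codon - 1] == alt_base:
        raise ValidationError("alt base equals the reference base at that position")
    alt_codon = (
        ref_codon[: position_in_codon - 1] + alt_base + ref_codon[position_in_codon:]
    )
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return seq3(ref_aa), seq3(alt_aa)


@dataclass(frozen=True)
class DomainAnnotation:
    """A named protein domain, 1-based inclusive residue interval."""

    name: str
    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_residue <= self.end_residue):
            raise ValidationError(
                f"domain {self.name!r}: need 1 <= start <= end, got "
                f"[{self.start_residue}, {self.end_residue}]"
            )

    def contains(self, residue: int) -> bool:
        return self.start_residue <= residue <= self.end_residue


@dataclass
class BurdenTrack:
    protein_length: int
    per_residue_af: np.ndarray  # length protein_length, residue i at index i-1
    contributing_variants: dict[int, list[tuple[str, int, str, str]]] = field(
        default_factory=dict
    )

    @property
    def total_mass(self) -> float:
        return float(self.per_residue_af.sum())


def build_burden_track(
    variants: Sequence[AnnotatedVariant],
    protein_length: int,
    database: str = "ExAC",
    aggregation: str = "sum",
) -> BurdenTrack:
    """Aggregate allele frequencies per residue.

    ``sum`` (default) adds the AFs of all variants at a residue, conserving
    total mass; ``max`` keeps the largest.  Variants lacking a protein
    position or an AF in ``database`` contribute nothing.
    """
    if protein_length < 1:
        raise ValidationError("protein_length must be >= 1")
    if aggregation not in ("sum", "max"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    track = np.zeros(protein_length)
    contributing: dict[int, list[tuple[str, int, str, str]]] = {}
    for v in variants:
        if v.protein_pos is None or database not in v.pop_afs:
            continue
        if not (1 <= v.protein_pos <= protein_length):
            raise ValidationError(
                f"variant {v.key} protein_pos {v.protein_pos} outside protein "
                f"of length {protein_length}"
            )
        i = v.protein_pos - 1
        af = v.pop_afs[database]
        if aggregation == "sum":
            track[i] += af
        else:
            track[i] = max(track[i], af)
        contributing.setdefault(v.protein_pos, []).append(v.key)
    return BurdenTrack(protein_length, track, contributing)


def annotate_and_plot(
    track: BurdenTrack,
    domains: Sequence[DomainAnnotation] = (),
    highlight_residue: Optional[int] = None,
    tsv_path: Optional[str] = None,
    figure_path: Optional[str] = None,
) -> pd.DataFrame:
    """Tabulate (and optionally plot) a burden track with domain membership.

    Returns a DataFrame with one row per residue: residue (1-based), burden
    value, comma-joined names of every overlapping domain, and a highlight
    flag.  The TSV is the tested surface; the figure is a convenience.
    """
    for d in domains:
        if d.end_residue > track.protein_length:
            raise ValidationError(
                f"domain {d.name!r} extends past protein length {track.protein_length}"
            )
    if highlight_residue is not None and not (
        1 <= highlight_residue <= track.protein_length
    ):
        raise ValidationError(
            f"highlight residue {highlight_residue} outside protein"
        )
    residues = np.arange(1, track.protein_length + 1)
    membership = [
        ",".join(d.name for d in domains if d.contains(int(r))) for r in residues
    ]
    df = pd.DataFrame(
        {
            "residue": residues,
            "burden": track.per_residue_af,
            "domains": membership,
            "highlight": [
                bool(highlight_residue is not None and r == highlight_residue)
                for r in residues
            ],
        }
    )
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3))
        ax.vlines(residues, 0, track.per_residue_af, color="0.2", lw=1.5)
        for d in domains:
            ax.axvspan(
                d.start_residue - 0.5, d.end_residue + 0.5, alpha=0.2, color="tab:blue"
            )
        if highlight_residue is not None:
            top = track.per_residue_af.max() if track.per_residue_af.any() else 1.0
            ax.annotate(
                f"residue {highlight_residue}",
                xy=(highlight_residue, track.per_residue_af[highlight_residue - 1]),
                xytext=(highlight_residue, top * 1.1),
                arrowprops={"arrowstyle": "->"},
                ha="center",
            )
        ax.set_xlabel("protein residue")
        ax.set_ylabel("summed allele frequency")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return df
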