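"""Bench-side quantifications as pure functions.

Relative qPCR expression by the delta-delta-Ct method, membrane/total
fluorescence ratio, hormone-secretion normalization to total protein, the
DSS-colitis disease activity index (sum of clinical subscores) and a
composite histology score (sum of component scores times an involvement
score).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import ValidationError


@dataclass(frozen=True)
class CtQuartet:
    """Cycle-threshold values for target and reference genes in test and
    control conditions."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_ctrl: float
    ct_ref_ctrl: float

    def __post_init__(self) -> None:
        vals = (
            self.ct_target_test,
            self.ct_ref_test,
            self.ct_target_ctrl,
            self.ct_ref_ctrl,
        )
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError("all Ct values must be finite")
        if any(not (5.0 <= v <= 40.0) for v in vals):
            warnings.warn(
                "Ct value outside the typical 5-40 cycle range", stacklevel=3
            )


def ddct_fold_change(quartet: CtQuartet) -> float:
    """Fold change 2^-(ddCt), assuming perfect doubling per cycle.

    ddCt = (Ct_target - Ct_ref)_test - (Ct_target - Ct_ref)_control.
    Always positive; 1.0 means no change.
    """
    dct_test = quartet.ct_target_test - quartet.ct_ref_test
    dct_ctrl = quartet.ct_target_ctrl - quartet.ct_ref_ctrl
    return 2.0 ** (-(dct_test - dct_ctrl))


def membrane_total_ratio(
    membrane_intensity: float, total_intensity: float, clamp: bool = False
) -> float:
    """Membranous over total cellular fluorescence intensity, in [0, 1].

    A membrane signal exceeding the total signal indicates a segmentation
    problem; it warns, and optionally clamps the ratio to 1.
    """
    if total_intensity <= 0:
        raise ValidationError("total_intensity must be > 0")
    if membrane_intensity < 0:
        raise ValidationError("membrane_intensity must be >= 0")
    ratio = membrane_intensity / total_intensity
    if ratio > 1.0:
        warnings.warn(
            "membrane intensity exceeds total intensity", stacklevel=2
        )
        if clamp:
            return 1.0
    return ratio


def normalize_secretion(hormone_conc: float, total_protein: float) -> float:
    """Hormone concentration per unit total protein (e.g. pM per ug)."""
    if total_protein <= 0:
        raise ValidationError("total_protein must be > 0")
    return hormone_conc / total_protein


@dataclass(frozen=True)
class Subscale:
    name: str
    min: float = 0.0
    max: float = 4.0

    def check(self, value: float) -> float:
        if not (self.min <= value <= self.max):
            raise ValidationError(
                f"{self.name} score {value} outside [{self.min}, {self.max}]"
            )
        return value


@dataclass(frozen=True)
class ScoreConfig:
    """Subscale ranges for the clinical and histology scores.

    Defaults follow the common 0-4 DSS-colitis convention; the exact scales
    are study-configurable.
    """

    dai_subscales: tuple[Subscale, ...] = (
        Subscale("stool_consistency"),
        Subscale("blood_in_stool"),
        Subscale("weight_change"),
    )
    histology_subscales: tuple[Subscale, ...] = (
        Subscale("epithelial_damage"),
        Subscale("inflammatory_infiltrate"),
    )
    involvement: Subscale = Subscale("involvement")


def dai_score(subscores, config: ScoreConfig | None = None) -> float:
    """Disease activity index: sum of the clinical subscores."""
    config = config or ScoreConfig()
    subscores = list(subscores)
    if len(subscores) != len(config.dai_subscales):
        raise ValidationError(
            f"expected {len(config.dai_subscales)} subscores, got {len(subscores)}"
        )
    return float(
        sum(sub.check(v) for sub, v in zip(config.dai_subscales, subscores))
    )


def histology_score(
    components, involvement: float, config: ScoreConfig | None = None
) -> float:
    """Composite histology score: (sum of component scores) x involvement."""
    config = config or ScoreConfig()
    components = list(components)
    if len(components) != len(config.histology_subscales):
        raise ValidationError(
            f"expected {len(config.histology_subscales)} components, "
            f"got {len(components)}"
        )
    total = sum(
        sub.check(v) for sub, v in zip(config.histology_subscales, components)
    )
    return float(total * config.involvement.check(involvement))
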