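"""GC content and the structural reward.

The reward of a candidate sequence with predicted structure at Hamming
distance ``d`` from the target is::

    r = R_GC + (N - d) / N    if |alpha - alpha*| <= delta
    r = (N - d) / N           otherwise (or when no GC target is given)

where ``alpha`` is the realized GC fraction, ``alpha*`` the target GC
content, ``delta`` the allowed deviation and ``R_GC > 0`` the bonus weight.
A perfect structural match inside the GC window therefore scores
``1 + R_GC``; the worst case scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .structure_model import TargetStructure, structure_distance

__all__ = ["RewardParams", "RewardValue", "gc_content", "reward"]

_RNA_ALPHABET = frozenset("ACGU")

# alpha is rounded before the window comparison so that floating-point
# representation noise cannot flip the bonus branch
_GC_DECIMALS = 12


@dataclass(frozen=True)
class RewardParams:
    """Reward configuration: GC target alpha*, tolerance delta, bonus R_GC."""

    alpha_star: Optional[float] = None
    delta: float = 0.01
    r_gc: float = 1.0

    def __post_init__(self) -> None:
        if self.r_gc <= 0:
            raise ValueError(f"r_gc must be > 0, got {self.r_gc}")
        if not (0 <= self.delta < 1):
            raise ValueError(f"delta must be in [0, 1), got {self.delta}")
        if self.alpha_star is not None and not (0 <= self.alpha_star <= 1):
            raise ValueError(
                f"alpha_star must be in [0, 1], got {self.alpha_star}"
            )


@dataclass(frozen=True)
class RewardValue:
    """A computed reward with its components for diagnostics."""

    r: float
    alpha: float
    d: int
    gc_bonus_applied: bool


def gc_content(sequence: str) -> float:
    """Fraction of G and C bases in an RNA sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    if not set(sequence) <= _RNA_ALPHABET:
        bad = sorted(set(sequence) - _RNA_ALPHABET)
        raise ValueError(f"non-ACGU characters in sequence: {bad}")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def reward(
    sequence: str,
    target: TargetStructure,
    predicted: str,
    params: RewardParams,
) -> RewardValue:
    """Score a sequence against the target structure.

    ``d`` is the canonical Hamming distance between target and predicted
    structures.  The GC bonus fires iff a GC target is set and the realized
    GC content lies within the closed interval ``alpha* +- delta``.
    """
    if len(sequence) != target.n or len(predicted) != target.n:
        raise ValueError(
            f"length mismatch: sequence {len(sequence)}, "
            f"predicted {len(predicted)}, target N={target.n}"
        )
    alpha = gc_content(sequence)
    d = structure_distance(target.dotbracket, predicted)
    base = (target.n - d) / target.n
    bonus = False
    if params.alpha_star is not None:
        bonus = abs(round(alpha - params.alpha_star, _GC_DECIMALS)) <= params.delta
    r = params.r_gc + base if bonus else base
    return RewardValue(r=r, alpha=alpha, d=d, gc_bonus_applied=bonus)
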