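"""The problem-dependent playout: assignment events, GC-targeted initial
sequences, and the two local rewriting rules.

A *site* is either one unpaired position (``int``) or one target base pair
(``(i, j)`` tuple); an *event* assigns a base to a single site or one of the
six admissible base pairs to a paired site.  Positions fixed by the search
tree's root-to-leaf path are *essential* and are never altered by the
playout.

The playout generates an initial sequence whose GC count approximates
``N * alpha*``, then improves it by up to ``k - 1`` local updates.  Each
update folds the current sequence and applies, in one pass:

rule (i)
    a target pair absent from the prediction (both positions non-essential)
    is rewritten to a random element of [AU, UA, CG, GC], encouraging the
    pair to form;
rule (ii)
    a predicted pair that is not a target pair (both positions
    non-essential) is broken: AU/UA -> AA or UU, GC/CG -> CC or GG, GU/UG ->
    one of [AC, CA, AG, GA, CU, UC].  All three maps conserve the sequence's
    GC count.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

from .folding import FoldBackend
from .scoring import RewardParams, RewardValue, reward
from .structure_model import TargetStructure

__all__ = [
    "Site",
    "SINGLE_BASES",
    "PAIR_VALUES",
    "RULE_I_PAIRS",
    "RULE_II_MAP",
    "AssignmentEvent",
    "EssentialAssignment",
    "CandidateSequence",
    "random_assignment",
    "generate_initial",
    "local_update",
    "simulate_playout",
]

Site = Union[int, Tuple[int, int]]

SINGLE_BASES: Tuple[str, ...] = ("A", "C", "G", "U")
PAIR_VALUES: Tuple[str, ...] = ("AU", "UA", "GU", "UG", "CG", "GC")

#: Replacement pool of rewriting rule (i) — GU/UG are deliberately absent.
RULE_I_PAIRS: Tuple[str, ...] = ("AU", "UA", "CG", "GC")

#: Replacement pools of rewriting rule (ii); every option conserves GC count.
RULE_II_MAP = {
    "AU": ("AA", "UU"),
    "UA": ("AA", "UU"),
    "GC": ("CC", "GG"),
    "CG": ("CC", "GG"),
    "GU": ("AC", "CA", "AG", "GA", "CU", "UC"),
    "UG": ("AC", "CA", "AG", "GA", "CU", "UC"),
}


@dataclass(frozen=True)
class AssignmentEvent:
    """One base (single site) or base pair (paired site) assignment."""

    site: Site
    value: str

    def __post_init__(self) -> None:
        if isinstance(self.site, int):
            if self.value not in SINGLE_BASES:
                raise ValueError(f"single site takes one base, got {self.value!r}")
        else:
            if self.value not in PAIR_VALUES:
                raise ValueError(
                    f"paired site takes one of {PAIR_VALUES}, got {self.value!r}"
                )

    @property
    def positions(self) -> Tuple[int, ...]:
        return (self.site,) if isinstance(self.site, int) else tuple(self.site)

    def __str__(self) -> str:
        if isinstance(self.site, int):
            return f"{{{self.value}_{self.site}}}"
        return f"{{{self.value}_{self.site[0]},{self.site[1]}}}"


@dataclass(frozen=True)
class EssentialAssignment:
    """The events fixed by the search path; sites are pairwise disjoint."""

    events: Tuple[AssignmentEvent, ...] = ()

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for ev in self.events:
            for p in ev.positions:
                if p in seen:
                    raise ValueError(f"position {p} assigned by two events")
                seen.add(p)

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(p for ev in self.events for p in ev.positions)

    def bases(self) -> dict[int, str]:
        """Position -> base map implied by the events (1-based)."""
        out: dict[int, str] = {}
        for ev in self.events:
            for p, b in zip(ev.positions, ev.value):
                out[p] = b
        return out


@dataclass
class CandidateSequence:
    """A full-length candidate with its fold and reward once scored."""

    bases: str
    predicted: Optional[str] = None
    score: Optional[RewardValue] = None


def random_assignment(site: Site, rng: random.Random) -> AssignmentEvent:
    """Uniform draw: one of 4 bases for a single site, 6 pairs for a pair."""
    if isinstance(site, int):
        return AssignmentEvent(site=site, value=rng.choice(SINGLE_BASES))
    return AssignmentEvent(site=site, value=rng.choice(PAIR_VALUES))


def generate_initial(
    target: TargetStructure,
    essential: EssentialAssignment,
    alpha_star: Optional[float],
    rng: random.Random,
) -> CandidateSequence:
    """Generate a full sequence honoring essential positions.

    With a GC target, non-essential positions are filled G/C (singles) or
    GC/CG (pairs) at randomly picked positions until the running GC count
    (essential positions included) reaches ``N * alpha*``; remaining
    positions get A/U (AU/UA for pairs).  A paired placement may overshoot
    the target count by one base; no correction is applied.  Without a GC
    target every non-essential site is assigned uniformly at random.
    """
    n = target.n
    bases: list[Optional[str]] = [None] * (n + 1)  # 1-based
    for pos, b in essential.bases().items():
        bases[pos] = b
    partner = {i: j for i, j in target.pairs}
    partner.update({j: i for i, j in target.pairs})

    if alpha_star is None:
        for site in target.sites:
            first = site if isinstance(site, int) else site[0]
            if bases[first] is not None:
                continue
            ev = random_assignment(site, rng)
            for p, b in zip(ev.positions, ev.value):
                bases[p] = b
        return CandidateSequence(bases="".join(bases[1:]))

    gc_count = sum(1 for b in bases[1:] if b in ("G", "C"))
    unassigned = [i for i in range(1, n + 1) if bases[i] is None]
    # GC-placement loop: skipped entirely if essentials already meet the target
    while gc_count < n * alpha_star and unassigned:
        pos = unassigned[rng.randrange(len(unassigned))]
        mate = partner.get(pos)
        if mate is not None:
            value = rng.choice(("GC", "CG"))
            bases[pos], bases[mate] = value[0], value[1]
            unassigned.remove(pos)
            unassigned.remove(mate)
            gc_count += 2
        else:
            bases[pos] = rng.choice(("G", "C"))
            unassigned.remove(pos)
            gc_count += 1
    # remaining positions take A/U in the same randomly-picked manner
    while unassigned:
        pos = unassigned[rng.randrange(len(unassigned))]
        mate = partner.get(pos)
        if mate is not None:
            value = rng.choice(("AU", "UA"))
            bases[pos], bases[mate] = value[0], value[1]
            unassigned.remove(pos)
            unassigned.remove(mate)
        else:
            bases[pos] = rng.choice(("A", "U"))
            unassigned.remove(pos)
    return CandidateSequence(bases="".join(bases[1:]))


def local_update(
    seq: CandidateSequence,
    target: TargetStructure,
    predicted: str,
    essential: EssentialAssignment,
    rng: random.Random,
) -> CandidateSequence:
    """One exhaustive rewriting pass against a fixed predicted structure.

    Rule (i) sites are processed in ascending opening position, then rule
    (ii) sites likewise; positions touched by one rule in this pass are not
    re-touched by the other, and essential positions never change.  Pairs
    with exactly one essential position are skipped by both rules.  The
    caller re-folds the returned sequence before the next pass.
    """
    from .structure_model import dotbracket_pairs

    bases = list(seq.bases)
    ess = essential.positions
    predicted_pairs = dotbracket_pairs(predicted) if predicted else frozenset()
    touched: set[int] = set()

    for i, j in sorted(target.pairs):
        if i in ess or j in ess:
            continue
        if (i, j) not in predicted_pairs:
            value = rng.choice(RULE_I_PAIRS)
            bases[i - 1], bases[j - 1] = value[0], value[1]
            touched.update((i, j))

    for i, j in sorted(predicted_pairs):
        if (i, j) in target.pairs:
            continue
        if i in ess or j in ess or i in touched or j in touched:
            continue
        current = bases[i - 1] + bases[j - 1]
        options = RULE_II_MAP.get(current)
        if options is None:
            continue  # engine paired non-complementary bases; leave alone
        value = rng.choice(options)
        bases[i - 1], bases[j - 1] = value[0], value[1]
        touched.update((i, j))

    return CandidateSequence(bases="".join(bases))


def simulate_playout(
    essential: EssentialAssignment,
    target: TargetStructure,
    reward_params: RewardParams,
    k: int,
    backend: FoldBackend,
    rng: random.Random,
    gc_targeted_init: bool = True,
) -> List[CandidateSequence]:
    """Generate, fold and score up to ``k`` candidates.

    Candidate 1 is the GC-targeted initial sequence (uniform random when
    ``gc_targeted_init`` is False — the randomly-designed baseline);
    candidates 2..k are successive local updates.  Exactly one fold call
    is spent per candidate.  The playout short-circuits as soon as a
    prediction matches the target's canonical structure.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    out: List[CandidateSequence] = []
    alpha_init = reward_params.alpha_star if gc_targeted_init else None
    cand = generate_initial(target, essential, alpha_init, rng)
    for step in range(k):
        if step > 0:
            cand = local_update(cand, target, out[-1].predicted, essential, rng)
        cand.predicted = backend.fold(cand.bases).structure
        cand.score = reward(cand.bases, target, cand.predicted, reward_params)
        out.append(cand)
        if cand.predicted == target.dotbracket:
            break
    return out
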