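"""Monte Carlo tree search over base-assignment events.

The search tree's root carries no assignment; each other node carries one
event (a base at a single site or a base pair at a paired site), so a
root-to-leaf path is a partial sequence and the tree depth is bounded by
the number of sites.  Each round runs Selection (descend by largest UCB
score, ties broken at random), optional Expansion (gated by the visit
threshold ``beta``), Simulation (a playout of ``k`` folded-and-scored
candidates with the path's positions held essential), and Backpropagation
(the playout's best reward is added to every node on the path).

The UCB score of node i is ``w_i / v_i + C * sqrt(2 ln v_parent / v_i)``,
infinite while the node is unvisited.  The run terminates the moment a
candidate's predicted structure equals the target (optionally also
requiring the GC window), or when the iteration / fold-call / wall-clock
budget is exhausted, in which case the best-reward candidate seen is
returned with ``success=False``.
"""

from __future__ import annotations

import logging
import math
import random
import time
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .folding import FoldBackend
from .scoring import RewardParams, RewardValue
from .sequence_design import (
    AssignmentEvent,
    CandidateSequence,
    EssentialAssignment,
    PAIR_VALUES,
    SINGLE_BASES,
    Site,
    simulate_playout,
)
from .structure_model import TargetStructure

__all__ = [
    "SearchNode",
    "SearchParams",
    "DesignResult",
    "ConfigurationError",
    "ucb_score",
    "select",
    "expand",
    "backpropagate",
    "run",
    "random_restart_design",
]

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Raised before the search loop for invalid target/backend pairings."""


@dataclass
class SearchNode:
    """One tree node: its event and the visit/value statistics v, w, z.

    Nodes are born with ``v = w = z = 0`` and are treated as having an
    infinite UCB score until first visited.  All children of a node are
    created together and assign events to the same site.
    """

    event: Optional[AssignmentEvent] = None  # None marks the root
    v: int = 0
    w: float = 0.0
    z: float = 0.0
    children: List["SearchNode"] = field(default_factory=list)
    expansion_site: Optional[Site] = None

    @property
    def is_root(self) -> bool:
        return self.event is None


@dataclass(frozen=True)
class SearchParams:
    """Search configuration.

    C : exploration constant of the UCB score (default 0.5)
    beta : expansion threshold — a leaf is expanded once its visit count
        reaches beta (default 1)
    k : playout length, one initial sequence plus k - 1 local updates
        (default 50)
    time_limit : wall-clock budget in seconds, or None
    max_iterations : round budget, or None
    max_fold_calls : prediction budget, or None
    require_gc : if True, a design only terminates the run when it also
        satisfies the GC window |alpha - alpha*| <= delta
    """

    C: float = 0.5
    beta: int = 1
    k: int = 50
    time_limit: Optional[float] = None
    max_iterations: Optional[int] = None
    max_fold_calls: Optional[int] = None
    seed: int = 0
    require_gc: bool = False

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError(f"C must be >= 0, got {self.C}")
        if self.beta < 1:
            raise ValueError(f"beta must be >= 1, got {self.beta}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.time_limit is None and self.max_iterations is None and self.max_fold_calls is None:
            raise ValueError(
                "at least one of time_limit, max_iterations, max_fold_calls is required"
            )


@dataclass
class DesignResult:
    """Outcome of one design run, with diagnostics for replay and audits."""

    success: bool
    sequence: Optional[str]
    predicted: Optional[str]
    score: Optional[RewardValue]
    gc: Optional[float]
    iterations: int
    fold_calls: int
    solution_depth: Optional[int]
    max_tree_depth: int
    elapsed: float
    backend: str
    seed: int

    def as_dict(self) -> dict:
        d = {
            "success": self.success,
            "sequence": self.sequence,
            "predicted": self.predicted,
            "reward": self.score.r if self.score else None,
            "distance": self.score.d if self.score else None,
            "gc": self.gc,
            "gc_bonus_applied": self.score.gc_bonus_applied if self.score else None,
            "iterations": self.iterations,
            "fold_calls": self.fold_calls,
            "solution_depth": self.solution_depth,
            "max_tree_depth": self.max_tree_depth,
            "elapsed_seconds": round(self.elapsed, 4),
            "backend": self.backend,
            "seed": self.seed,
        }
        return d


def ucb_score(node: SearchNode, v_parent: int, C: float) -> float:
    """Upper-confidence-bound score; infinite for an unvisited node."""
    if node.v == 0:
        return math.inf
    if v_parent < node.v:
        raise RuntimeError(
            f"inconsistent tree: v_parent={v_parent} < v_child={node.v}"
        )
    return node.w / node.v + C * math.sqrt(2.0 * math.log(v_parent) / node.v)


def select(root: SearchNode, C: float, rng: random.Random) -> List[SearchNode]:
    """Descend from the root to a leaf, taking the argmax-UCB child.

    Ties (including several unvisited children) are broken uniformly at
    random from the seeded stream.  Returns the full node path.
    """
    path = [root]
    node = root
    while node.children:
        scores = [ucb_score(c, node.v, C) for c in node.children]
        best = max(scores)
        winners = [c for c, s in zip(node.children, scores) if s == best]
        node = winners[0] if len(winners) == 1 else rng.choice(winners)
        path.append(node)
    return path


def expand(
    leaf: SearchNode,
    remaining_sites: Sequence[Site],
    beta: int,
    rng: random.Random,
) -> SearchNode:
    """Expand a leaf if it has been visited at least ``beta`` times.

    A site is drawn uniformly from the remaining sites; all of its events
    become children at once (4 for a single site, 6 for a paired site) and
    one child is returned, chosen uniformly.  A rarely visited leaf
    (``v < beta``) or a leaf at full depth is returned unchanged.
    """
    if leaf.children:
        raise ValueError("expand called on an internal node")
    if leaf.v < beta or not remaining_sites:
        return leaf
    site = rng.choice(list(remaining_sites))
    values = SINGLE_BASES if isinstance(site, int) else PAIR_VALUES
    leaf.expansion_site = site
    leaf.children = [
        SearchNode(event=AssignmentEvent(site=site, value=v)) for v in values
    ]
    return rng.choice(leaf.children)


def backpropagate(path: Sequence[SearchNode], z: float) -> None:
    """Credit a playout's best reward to the whole path.

    Every node on the path — the simulated node itself included — gets
    ``v += 1`` and ``w += z``; the simulated node additionally records ``z``
    as its immediate value.
    """
    for node in path:
        node.v += 1
        node.w += z
    path[-1].z = z


def _path_essentials(path: Sequence[SearchNode]) -> EssentialAssignment:
    return EssentialAssignment(
        events=tuple(n.event for n in path if n.event is not None)
    )


def _design_from(cand: CandidateSequence, **kw) -> DesignResult:
    return DesignResult(
        sequence=cand.bases,
        predicted=cand.predicted,
        score=cand.score,
        gc=cand.score.alpha if cand.score else None,
        **kw,
    )


def run(
    target: TargetStructure,
    reward_params: RewardParams,
    search_params: SearchParams,
    backend: FoldBackend,
) -> DesignResult:
    """Design a sequence folding into ``target`` by tree search.

    Fully reproducible for a given (target, parameters, seed) triple with a
    deterministic backend.  Raises :class:`ConfigurationError` if the
    target is pseudoknotted but the backend only predicts nested
    structures.
    """
    if target.is_pseudoknotted and not backend.supports_pseudoknots:
        raise ConfigurationError(
            f"target contains crossing pairs but backend {backend.name!r} "
            "predicts nested structures only"
        )
    rng = random.Random(search_params.seed)
    start = time.monotonic()
    folds_at_start = backend.call_count
    root = SearchNode()
    best: Optional[CandidateSequence] = None
    best_r = -math.inf
    iterations = 0
    max_depth = 0
    solution_depth: Optional[int] = None

    def budget_left() -> bool:
        if search_params.max_iterations is not None and iterations >= search_params.max_iterations:
            return False
        if search_params.max_fold_calls is not None and (
            backend.call_count - folds_at_start >= search_params.max_fold_calls
        ):
            return False
        if search_params.time_limit is not None and (
            time.monotonic() - start >= search_params.time_limit
        ):
            return False
        return True

    def is_solution(c: CandidateSequence) -> bool:
        if c.predicted != target.dotbracket:
            return False
        if search_params.require_gc and reward_params.alpha_star is not None:
            return c.score is not None and c.score.gc_bonus_applied
        return True

    while budget_left():
        iterations += 1
        path = select(root, search_params.C, rng)
        leaf = path[-1]
        used = {p for n in path if n.event for p in n.event.positions}
        remaining = [
            s
            for s in target.sites
            if (s if isinstance(s, int) else s[0]) not in used
        ]
        # the root is expanded unconditionally in round 1; afterwards the
        # beta-gate applies to the leaf's pre-increment visit count
        if leaf.is_root and iterations == 1 and remaining:
            child = expand(leaf, remaining, beta=0 if leaf.v == 0 else search_params.beta, rng=rng)
        else:
            child = expand(leaf, remaining, search_params.beta, rng=rng)
        if child is not leaf:
            path.append(child)
        depth = len(path) - 1
        max_depth = max(max_depth, depth)
        essential = _path_essentials(path)
        k_eff = search_params.k
        if len(essential.positions) == target.n:
            # full-depth leaf: the sequence is fixed, nothing is updatable
            logger.debug("round=%d path at full depth; single-fold playout", iterations)
            k_eff = 1
        playout = simulate_playout(
            essential, target, reward_params, k_eff, backend, rng
        )
        z = max(c.score.r for c in playout)
        backpropagate(path, z)
        for cand in playout:
            if cand.score.r > best_r:
                best, best_r = cand, cand.score.r
        logger.debug(
            "round=%d depth=%d z=%.4f best=%.4f folds=%d",
            iterations, depth, z, best_r, backend.call_count - folds_at_start,
        )
        hit = next((c for c in playout if is_solution(c)), None)
        if hit is not None:
            solution_depth = depth
            # termination soundness: the stored prediction is the fold of
            # the returned sequence under this backend
            assert hit.predicted == target.dotbracket
            return _design_from(
                hit,
                success=True,
                iterations=iterations,
                fold_calls=backend.call_count - folds_at_start,
                solution_depth=solution_depth,
                max_tree_depth=max_depth,
                elapsed=time.monotonic() - start,
                backend=backend.name,
                seed=search_params.seed,
            )

    if best is None:
        best = CandidateSequence(bases="", predicted=None, score=None)
        best.bases = None  # type: ignore[assignment]
    return _design_from(
        best,
        success=False,
        iterations=iterations,
        fold_calls=backend.call_count - folds_at_start,
        solution_depth=None,
        max_tree_depth=max_depth,
        elapsed=time.monotonic() - start,
        backend=backend.name,
        seed=search_params.seed,
    )


def random_restart_design(
    target: TargetStructure,
    reward_params: RewardParams,
    search_params: SearchParams,
    backend: FoldBackend,
    gc_targeted_init: bool = False,
) -> DesignResult:
    """Local search from randomly designed initial sequences, no tree.

    Each restart draws a fresh initial sequence and improves it with the
    same ``k - 1`` local-update chain the tree search uses, with no
    essential positions.  By default the initial sequences are uniform
    random assignments of every site (the randomly-designed baseline the
    tree search is classically compared against); with
    ``gc_targeted_init=True`` the restarts instead use the same
    GC-budgeted initial generation as the tree's playouts, isolating the
    contribution of the tree alone.
    """
    if target.is_pseudoknotted and not backend.supports_pseudoknots:
        raise ConfigurationError(
            f"target contains crossing pairs but backend {backend.name!r} "
            "predicts nested structures only"
        )
    rng = random.Random(search_params.seed)
    start = time.monotonic()
    folds_at_start = backend.call_count
    empty = EssentialAssignment()
    best: Optional[CandidateSequence] = None
    best_r = -math.inf
    iterations = 0

    while True:
        if search_params.max_iterations is not None and iterations >= search_params.max_iterations:
            break
        if search_params.max_fold_calls is not None and (
            backend.call_count - folds_at_start >= search_params.max_fold_calls
        ):
            break
        if search_params.time_limit is not None and (
            time.monotonic() - start >= search_params.time_limit
        ):
            break
        iterations += 1
        playout = simulate_playout(
            empty, target, reward_params, search_params.k, backend, rng,
            gc_targeted_init=gc_targeted_init,
        )
        for cand in playout:
            if cand.score.r > best_r:
                best, best_r = cand, cand.score.r
        hit = next(
            (
                c
                for c in playout
                if c.predicted == target.dotbracket
                and (
                    not (search_params.require_gc and reward_params.alpha_star is not None)
                    or c.score.gc_bonus_applied
                )
            ),
            None,
        )
        if hit is not None:
            return _design_from(
                hit,
                success=True,
                iterations=iterations,
                fold_calls=backend.call_count - folds_at_start,
                solution_depth=0,
                max_tree_depth=0,
                elapsed=time.monotonic() - start,
                backend=backend.name,
                seed=search_params.seed,
            )

    if best is None:
        best = CandidateSequence(bases=None, predicted=None, score=None)  # type: ignore[arg-type]
    return _design_from(
        best,
        success=False,
        iterations=iterations,
        fold_calls=backend.call_count - folds_at_start,
        solution_depth=None,
        max_tree_depth=0,
        elapsed=time.monotonic() - start,
        backend=backend.name,
        seed=search_params.seed,
    )
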