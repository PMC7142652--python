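"""Dempster-Shafer combination of expert mass functions.

Expert judgments arrive as basic probability assignments m(.) over a shared
frame of discernment Theta.  Dempster's rule combines N assignments by
intersection-product and renormalizes by 1 - K, where the conflict degree K
is the total product mass landing on empty intersections.  K = 1 means the
experts are irreconcilable and combination is undefined.

The package uses the rule in two places mirroring the elicitation workflow:
deciding whether a causal edge exists (frame {strong, weak}, threshold on
the combined "strong" mass) and fusing one CPT row per parent-state
combination (frame = the child's states).  Both use singleton-supported
masses; a closed-form normalized-product fast path covers that case, while
the general arbitrary-focal-subset implementation serves as its oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import reduce

import numpy as np

from .errors import ModelError, TotalConflictError

__all__ = [
    "MassFunction",
    "CombinationResult",
    "combine_pair",
    "combine_all",
    "conflict",
    "decide_edge",
    "fuse_cpt_row",
]

_TOL = 1e-9


class MassFunction:
    """A basic probability assignment over subsets of a finite frame.

    ``masses`` maps non-empty frozensets of frame labels to values in [0, 1]
    summing to 1; the empty set always carries mass 0.
    """

    def __init__(
        self,
        frame: "tuple[str, ...] | list[str]",
        masses: dict[frozenset, float],
    ) -> None:
        self.frame = tuple(frame)
        frame_set = frozenset(self.frame)
        clean: dict[frozenset, float] = {}
        for subset, m in masses.items():
            subset = frozenset(subset)
            if not subset:
                if abs(m) > _TOL:
                    raise ModelError("mass on the empty set must be 0")
                continue
            if not subset <= frame_set:
                raise ModelError(
                    f"focal set {sorted(subset)} not within frame {self.frame}"
                )
            if m < -_TOL or m > 1 + _TOL:
                raise ModelError(f"mass {m} outside [0, 1]")
            if m > 0.0:
                clean[subset] = clean.get(subset, 0.0) + float(m)
        total = sum(clean.values())
        if abs(total - 1.0) > _TOL:
            raise ModelError(f"masses sum to {total}, not 1")
        self.masses = clean

    @classmethod
    def from_vector(
        cls, frame: "tuple[str, ...] | list[str]", vector
    ) -> "MassFunction":
        """Singleton-supported mass function from a probability vector."""
        frame = tuple(frame)
        vector = list(map(float, vector))
        if len(vector) != len(frame):
            raise ModelError("vector length does not match frame size")
        return cls(
            frame,
            {frozenset({s}): v for s, v in zip(frame, vector) if v > 0.0},
        )

    def is_singleton_supported(self) -> bool:
        return all(len(a) == 1 for a in self.masses)

    def as_vector(self) -> np.ndarray:
        """Singleton masses in frame order (requires singleton support)."""
        if not self.is_singleton_supported():
            raise ModelError("mass function has non-singleton focal sets")
        return np.array(
            [self.masses.get(frozenset({s}), 0.0) for s in self.frame]
        )

    def __getitem__(self, subset) -> float:
        if isinstance(subset, str):
            subset = {subset}
        return self.masses.get(frozenset(subset), 0.0)


@dataclass
class CombinationResult:
    """Combined mass function plus the conflict degree K of the inputs."""

    combined: MassFunction
    conflict: float


def _check_shared_frame(panel: "list[MassFunction]") -> tuple[str, ...]:
    if not panel:
        raise ModelError("panel must contain at least one mass function")
    frame = panel[0].frame
    for m in panel[1:]:
        if m.frame != frame:
            raise ModelError("all mass functions must share one frame")
    return frame


def _combine_general(panel: list[MassFunction]) -> CombinationResult:
    """Simultaneous N-way Dempster combination over arbitrary focal sets."""
    frame = _check_shared_frame(panel)
    agree: dict[frozenset, float] = {}
    conflict_mass = 0.0
    for focal_combo in itertools.product(*(m.masses.items() for m in panel)):
        subsets, weights = zip(*focal_combo)
        inter = reduce(frozenset.intersection, subsets)
        w = float(np.prod(weights))
        if inter:
            agree[inter] = agree.get(inter, 0.0) + w
        else:
            conflict_mass += w
    k = conflict_mass / (conflict_mass + sum(agree.values()))
    if not agree:
        raise TotalConflictError("total conflict: K = 1, combination undefined")
    z = sum(agree.values())
    combined = MassFunction(frame, {a: w / z for a, w in agree.items()})
    return CombinationResult(combined, k)


def _combine_singleton(panel: list[MassFunction]) -> CombinationResult:
    """Closed form for singleton-supported panels: normalized product."""
    frame = _check_shared_frame(panel)
    prod = np.ones(len(frame))
    for m in panel:
        prod *= m.as_vector()
    z = float(prod.sum())
    if z <= 0.0:
        raise TotalConflictError("total conflict: K = 1, combination undefined")
    return CombinationResult(MassFunction.from_vector(frame, prod / z), 1.0 - z)


def combine_pair(m1: MassFunction, m2: MassFunction) -> CombinationResult:
    """Dempster's rule for two mass functions on a shared frame."""
    return combine_all([m1, m2])


def combine_all(panel: "list[MassFunction]") -> CombinationResult:
    """Simultaneous N-way Dempster combination of an expert panel.

    Equals sequential pairwise combination (the rule is associative); a
    single-member panel is returned unchanged with zero conflict.
    """
    _check_shared_frame(panel)
    if len(panel) == 1:
        return CombinationResult(panel[0], 0.0)
    if all(m.is_singleton_supported() for m in panel):
        return _combine_singleton(panel)
    return _combine_general(panel)


def conflict(panel: "list[MassFunction]") -> float:
    """Conflict degree K: total product mass on empty intersections."""
    _check_shared_frame(panel)
    if len(panel) == 1:
        return 0.0
    try:
        return combine_all(panel).conflict
    except TotalConflictError:
        return 1.0


def decide_edge(
    panel: "list[MassFunction]", threshold: float = 0.85
) -> tuple[bool, float]:
    """Edge-existence decision from a panel over the frame (strong, weak).

    Returns ``(exists, weight)`` where ``weight`` is the combined mass of
    the first frame element ("strong") and ``exists`` requires the weight to
    strictly exceed the threshold.
    """
    frame = _check_shared_frame(panel)
    if len(frame) != 2:
        raise ModelError("edge decision requires a 2-state (strong, weak) frame")
    combined = combine_all(panel).combined
    weight = combined[frame[0]]
    return weight > threshold, weight


def fuse_cpt_row(panel: "list[MassFunction]") -> np.ndarray:
    """Fuse one elicited CPT row: combined singleton masses as a vector.

    All panel members must be singleton-supported (each expert hands in a
    probability vector over the child's states).
    """
    frame = _check_shared_frame(panel)
    for m in panel:
        if not m.is_singleton_supported():
            raise ModelError("CPT-row fusion requires singleton-supported masses")
    combined = combine_all(panel).combined
    return np.array([combined[s] for s in frame])
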