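"""Penalty configuration and result containers.

Scores are exact rationals (:class:`fractions.Fraction`); infeasibility is
represented by ``math.inf``, which absorbs addition and compares correctly
against any rational, and is rendered as ``"NO"`` at the tool surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Union

__all__ = ["PenaltyConfig", "DivergenceResult", "INFEASIBLE", "Score", "as_score"]

INFEASIBLE = math.inf

Score = Union[Fraction, float]


def as_score(value) -> Fraction:
    """Coerce a penalty parameter to an exact rational."""
    if isinstance(value, Fraction):
        return value
    if isinstance(value, float):
        return Fraction(str(value))
    return Fraction(value)


@dataclass(frozen=True)
class PenaltyConfig:
    """Event penalties of the divergence model.

    delta_q_ord
        Penalty multiplier for each signed break-point created while
        reordering the children of a Q-node (a reversal-unfriendly event).
    delta_q_flip
        Penalty for flipping a leaf or a whole Q-node.
    rho_t_del
        Penalty per leaf deleted from the tree.
    rho_s_del
        Penalty per character deleted from the target string.
    jump_enabled
        Whether P-node reorderings pay the jump violation (the minimum
        weight vertex cover of the changed-signed-order graph, with weight
        (span-1)/2 per moved unit).
    """

    delta_q_ord: Fraction = Fraction(3, 2)
    delta_q_flip: Fraction = Fraction(1, 2)
    rho_t_del: Fraction = Fraction(1)
    rho_s_del: Fraction = Fraction(1)
    jump_enabled: bool = True

    def __post_init__(self):
        for name in ("delta_q_ord", "delta_q_flip", "rho_t_del", "rho_s_del"):
            v = as_score(getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
            object.__setattr__(self, name, v)


@dataclass
class DivergenceResult:
    """Outcome of a divergence computation.

    ``score`` is a Fraction, or ``INFEASIBLE`` when the target cannot be
    derived from the tree under the given budgets.  Optional fields carry
    traceback detail where the engine provides it.
    """

    score: Score
    feasible: bool = True
    del_t: int = 0
    del_s: int = 0
    start: Optional[int] = None
    end: Optional[int] = None
    strand: str = "given"
    node_trace: dict = field(default_factory=dict)

    @classmethod
    def no(cls) -> "DivergenceResult":
        return cls(score=INFEASIBLE, feasible=False)

    def __bool__(self) -> bool:
        return self.feasible

    def render_score(self) -> str:
        """Exact decimal when terminating, else a fraction string, else NO."""
        if not self.feasible or self.score == INFEASIBLE:
            return "NO"
        f = Fraction(self.score)
        if f.denominator == 1:
            return str(f.numerator)
        # terminating decimal iff the denominator is 2^a * 5^b
        d, a, b = f.denominator, 0, 0
        while d % 2 == 0:
            d //= 2
            a += 1
        while d % 5 == 0:
            d //= 5
            b += 1
        if d == 1:
            k = max(a, b)
            scaled = abs(f.numerator) * 10**k // f.denominator
            text = f"{scaled:0{k + 1}d}"
            sign = "-" if f.numerator < 0 else ""
            return f"{sign}{text[:-k]}.{text[-k:]}"
        return f"{f.numerator}/{f.denominator}"
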