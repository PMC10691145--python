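"""File loading, strand handling and run reports."""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Callable, Union

from .config import DivergenceResult
from .pqtree import PQTree, SignedString, parse_signed_string, parse_tree

__all__ = [
    "load_tree",
    "load_signed_string",
    "reverse_and_negate",
    "min_over_strands",
    "result_report",
]


def load_tree(path: Union[str, Path]) -> PQTree:
    return parse_tree(Path(path).read_text())


def load_signed_string(path: Union[str, Path]) -> SignedString:
    return parse_signed_string(Path(path).read_text())


def reverse_and_negate(s: SignedString) -> SignedString:
    """The target read from the opposite strand: order reversed, every
    sign negated.  An involution."""
    return s.reverse_and_negate()


def min_over_strands(
    tree: PQTree,
    s2: SignedString,
    engine: Callable[[PQTree, SignedString], DivergenceResult],
) -> DivergenceResult:
    """Run the engine on the target and on its opposite strand, keep the
    smaller divergence (infeasible only if both runs are)."""
    given = engine(tree, s2)
    given.strand = "given"
    other = engine(tree, reverse_and_negate(s2))
    other.strand = "reversed"
    if not given.feasible:
        return other
    if not other.feasible:
        return given
    return given if given.score <= other.score else other


def _render(value):
    if isinstance(value, Fraction):
        return DivergenceResult(score=value).render_score()
    if isinstance(value, dict):
        return {k: _render(v) for k, v in value.items()}
    return value


def result_report(result: DivergenceResult, trace: bool = False) -> dict:
    """JSON-ready report of a divergence run."""
    report = {
        "score": result.render_score(),
        "feasible": result.feasible,
        "del_T": result.del_t,
        "del_S": result.del_s,
        "start": result.start,
        "end": result.end,
        "strand": result.strand,
    }
    if trace:
        report["trace"] = {
            str(color): {k: _render(v) for k, v in entry.items()}
            for color, entry in result.node_trace.items()
        }
    return report


def report_tsv(report: dict) -> str:
    cols = ["score", "feasible", "del_T", "del_S", "start", "end", "strand"]
    head = "\t".join(cols)
    row = "\t".join(str(report.get(c)) for c in cols)
    return head + "\n" + row + "\n"


def dump_report(report: dict, fmt: str = "json") -> str:
    if fmt == "tsv":
        return report_tsv(report)
    return json.dumps(report, indent=2, sort_keys=True) + "\n"
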