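"""Post-calling quality filters and per-callset descriptive statistics.

A call survives filtering iff

* its t-test ``p_value`` is strictly below ``p_max`` (default 0.01),
* its zero-mapping-quality fraction ``q0`` is at most ``q0_max``
  (default 0.5; a value of exactly 0.5 passes),
* its size lies in ``[min_size, max_size]`` inclusive (defaults 1 kb and
  5 Mb; calls of exactly 1 kb or 5 Mb pass, only strictly smaller/larger
  ones are removed).

Boundary semantics are deliberately isolated in :func:`passes` so each
comparison is unit-testable on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .caller import DELETION, DUPLICATION, CNVCall


@dataclass(frozen=True)
class FilterPolicy:
    p_max: float = 0.01
    q0_max: float = 0.5
    min_size: int = 1_000
    max_size: int = 5_000_000

    def __post_init__(self) -> None:
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")
        if not 0 <= self.q0_max <= 1:
            raise ValueError("q0_max must lie in [0, 1]")
        if not 0 < self.min_size < self.max_size:
            raise ValueError("require 0 < min_size < max_size")


@dataclass(frozen=True)
class CallsetSummary:
    n_total: int
    n_deletion: int
    n_duplication: int
    loss_gain_ratio: float
    min_size: int
    max_size: int
    mean_size: float


def passes(call: CNVCall, policy: FilterPolicy) -> bool:
    return (
        call.p_value < policy.p_max
        and call.q0 <= policy.q0_max
        and policy.min_size <= call.size <= policy.max_size
    )


def apply_filters(
    calls: Sequence[CNVCall], policy: FilterPolicy = FilterPolicy()
) -> list[CNVCall]:
    """Retain calls passing every filter; order preserved, input untouched."""
    return [c for c in calls if passes(c, policy)]


def summarize(calls: Sequence[CNVCall]) -> CallsetSummary:
    """Counts by type, loss/gain ratio and size statistics of a callset."""
    n_del = sum(1 for c in calls if c.type == DELETION)
    n_dup = sum(1 for c in calls if c.type == DUPLICATION)
    sizes = [c.size for c in calls]
    return CallsetSummary(
        n_total=len(calls),
        n_deletion=n_del,
        n_duplication=n_dup,
        loss_gain_ratio=n_del / n_dup if n_dup > 0 else math.nan,
        min_size=min(sizes) if sizes else 0,
        max_size=max(sizes) if sizes else 0,
        mean_size=sum(sizes) / len(sizes) if sizes else 0.0,
    )
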