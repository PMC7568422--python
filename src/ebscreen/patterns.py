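"""Multi-condition expression patterns.

A pattern is a partition of the experimental conditions into equality
blocks: conditions in the same block share a mean expression level, and
conditions in different blocks differ.  With five conditions there are 52
possible partitions (the Bell number B5); a screen typically restricts
attention to a named subset, e.g. the six-pattern set used for a
five-cell-line screen (all-unequal plus each single adjacent merge plus
the 3+2 split).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "PatternSpec",
    "all_equal_pattern",
    "all_unequal_pattern",
    "enumerate_patterns",
    "parse_pattern",
]


@dataclass(frozen=True)
class PatternSpec:
    """A partition of condition labels into ordered equality blocks.

    Parameters
    ----------
    blocks
        Tuple of tuples of condition labels.  Blocks are disjoint and
        jointly cover every condition.  Block order is meaningful for
        display and for the simulator's ``ordering`` tag.
    name
        Display name; autogenerated from the blocks if empty.
    ordering
        Optional tag consumed by the simulator when assigning block
        means: ``"increasing"`` / ``"decreasing"`` force monotone block
        levels in block order; ``None`` permutes levels at random.
    """

    blocks: tuple[tuple[str, ...], ...]
    name: str = ""
    ordering: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        labels = [c for b in self.blocks for c in b]
        if not self.blocks or any(len(b) == 0 for b in self.blocks):
            raise ValueError("pattern must have at least one non-empty block")
        if len(set(labels)) != len(labels):
            raise ValueError("pattern blocks must be disjoint")
        if not self.name:
            object.__setattr__(self, "name", self.format_blocks())

    def format_blocks(self) -> str:
        return "".join("{" + ",".join(str(c) for c in b) + "}" for b in self.blocks)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(c for b in self.blocks for c in b)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, condition: str) -> int:
        for i, b in enumerate(self.blocks):
            if condition in b:
                return i
        raise KeyError(condition)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def all_equal_pattern(conditions: Sequence[str], name: str = "EE") -> PatternSpec:
    """Single-block pattern: every condition shares one mean."""
    return PatternSpec(blocks=(tuple(conditions),), name=name)


def all_unequal_pattern(
    conditions: Sequence[str], name: str = "DE", ordering: str | None = None
) -> PatternSpec:
    """Fully split pattern: every condition mean distinct."""
    return PatternSpec(
        blocks=tuple((c,) for c in conditions), name=name, ordering=ordering
    )


def parse_pattern(
    text: str, name: str = "", ordering: str | None = None
) -> PatternSpec:
    """Parse a block string like ``"{A,B}{C}{D}"`` into a PatternSpec."""
    body = text.strip()
    if not (body.startswith("{") and body.endswith("}")):
        raise ValueError(f"malformed pattern text: {text!r}")
    blocks = tuple(
        tuple(lab.strip() for lab in chunk.split(","))
        for chunk in body[1:-1].split("}{")
    )
    return PatternSpec(blocks=blocks, name=name, ordering=ordering)


def _partitions(items: list) -> Iterable[list[list]]:
    """Yield all set partitions of ``items`` (first element anchors)."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for sub in _partitions(rest):
        # head joins an existing block, or starts its own
        for i in range(len(sub)):
            yield sub[:i] + [[head] + sub[i]] + sub[i + 1 :]
        yield [[head]] + sub


def _six_pattern_set(conditions: Sequence[str]) -> list[PatternSpec]:
    # For K = 5: all-unequal; merge of each adjacent pair; {1,2,3}{4,5}.
    c = tuple(conditions)
    if len(c) != 5:
        raise ValueError("the 'p1_p6' restriction is defined for exactly 5 conditions")
    return [
        PatternSpec(tuple((x,) for x in c), name="P1"),
        PatternSpec(((c[0], c[1]), (c[2],), (c[3],), (c[4],)), name="P2"),
        PatternSpec(((c[0],), (c[1], c[2]), (c[3],), (c[4],)), name="P3"),
        PatternSpec(((c[0],), (c[1],), (c[2], c[3]), (c[4],)), name="P4"),
        PatternSpec(((c[0],), (c[1],), (c[2],), (c[3], c[4])), name="P5"),
        PatternSpec(((c[0], c[1], c[2]), (c[3], c[4])), name="P6"),
    ]


RESTRICTIONS = {"p1_p6": _six_pattern_set}


def enumerate_patterns(
    conditions: Sequence[str] | int, restriction: str | None = None
) -> list[PatternSpec]:
    """Enumerate equality patterns over the given conditions.

    Without a restriction, returns every set partition of the conditions
    (Bell-number many).  With ``restriction="p1_p6"`` returns the six
    named patterns of the five-condition screen.

    Parameters
    ----------
    conditions
        Condition labels, or an integer K (labels become ``"C1".."CK"``).
    restriction
        Optional named subset.
    """
    if isinstance(conditions, int):
        if conditions < 1:
            raise ValueError("need at least one condition")
        conditions = [f"C{i}" for i in range(1, conditions + 1)]
    conditions = list(conditions)
    if restriction is not None:
        try:
            builder = RESTRICTIONS[restriction]
        except KeyError:
            raise ValueError(
                f"unknown restriction {restriction!r}; known: {sorted(RESTRICTIONS)}"
            ) from None
        return builder(conditions)
    out = [
        PatternSpec(tuple(tuple(b) for b in part))
        for part in _partitions(conditions)
    ]
    out.sort(key=lambda p: (p.n_blocks, p.name))
    return out
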