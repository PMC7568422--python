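"""Directionality gate: ordering constraints on condition means.

After pattern selection picks genes whose condition means differ, a
deterministic gate keeps only those whose normalized condition means
follow the ordering observed in the phenotype (e.g. a cell line panel's
ranked ability to generate CD68+ macrophages).  Constraints are chains
like ``"OV90<=OVCAR4<=OVCAR3<=OVCAR5<=OVCA432"`` over the condition
labels with relations drawn from {<=, >=, =}, an optional relative
tolerance, and a strict flag turning <=/>= into strict inequalities.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrderingConstraint",
    "parse_constraint",
    "constraint_preset",
    "check_ordering",
    "apply_gate",
    "derive_condition_order",
    "univariate_r2",
    "R2Result",
    "PRESETS",
]

_RELATIONS = ("<=", ">=", "=")


@dataclass(frozen=True)
class OrderingConstraint:
    """A chain of {<=, >=, =} relations over condition labels.

    ``rel_tol`` loosens comparisons relatively (a <= b passes iff
    a <= b*(1+rel_tol) + abs_floor; equality iff |a-b| <=
    rel_tol*max(a,b) + abs_floor).  ``strict=True`` makes <= and >=
    exclude equality beyond the tolerance.
    """

    labels: tuple[str, ...]
    relations: tuple[str, ...]
    rel_tol: float = 0.0
    abs_floor: float = 0.0
    strict: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.relations) != len(self.labels) - 1:
            raise ValueError("need exactly one relation between adjacent labels")
        if any(r not in _RELATIONS for r in self.relations):
            raise ValueError(f"relations must be among {_RELATIONS}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("condition labels must be distinct")
        if self.rel_tol < 0 or self.abs_floor < 0:
            raise ValueError("tolerances must be non-negative")
        if not self.name:
            object.__setattr__(self, "name", self.to_text())

    def to_text(self) -> str:
        parts = [self.labels[0]]
        for rel, lab in zip(self.relations, self.labels[1:]):
            parts += [rel, lab]
        return "".join(parts)

    def reversed(self) -> "OrderingConstraint":
        """Mirror image: reversed labels with <= and >= swapped."""
        flip = {"<=": ">=", ">=": "<=", "=": "="}
        return replace(
            self,
            labels=self.labels[::-1],
            relations=tuple(flip[r] for r in self.relations[::-1]),
            name="",
        )


_CHAIN = re.compile(r"(<=|>=|=)")


def parse_constraint(
    spec: str,
    rel_tol: float = 0.0,
    abs_floor: float = 0.0,
    strict: bool = False,
    known_labels: Sequence[str] | None = None,
) -> OrderingConstraint:
    """Parse a chain like ``"A<=B>=C=D"`` into an OrderingConstraint."""
    tokens = [t.strip() for t in _CHAIN.split(spec)]
    labels = tokens[0::2]
    relations = tokens[1::2]
    if len(labels) < 2 or any(not lab for lab in labels):
        raise ValueError(f"malformed constraint chain: {spec!r}")
    if known_labels is not None:
        unknown = [lab for lab in labels if lab not in known_labels]
        if unknown:
            raise ValueError(f"unknown condition labels: {unknown}")
    return OrderingConstraint(
        labels=tuple(labels),
        relations=tuple(relations),
        rel_tol=rel_tol,
        abs_floor=abs_floor,
        strict=strict,
    )


# Named presets for the five-line screen.  The main-text criteria are
# monotone chains of <=; the supplemental variants tie the first three
# conditions and use strict inequalities.
_LINES = ("OV90", "OVCAR4", "OVCAR3", "OVCAR5", "OVCA432")
PRESETS: dict[str, dict] = {
    "c1_main": {"relations": ("<=", "<=", "<=", "<="), "strict": False},
    "c2_main": {"relations": ("<=", "<=", "<=", ">="), "strict": False},
    "c1_supp": {"relations": ("=", "=", "<=", "<="), "strict": True},
    "c2_supp": {"relations": ("=", "=", "<=", ">="), "strict": True},
}


def constraint_preset(
    name: str,
    labels: Sequence[str] = _LINES,
    rel_tol: float = 0.0,
    abs_floor: float = 0.0,
) -> OrderingConstraint:
    """Build a named constraint preset over the given 5 condition labels."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    cfg = PRESETS[name]
    if len(labels) != len(cfg["relations"]) + 1:
        raise ValueError(f"preset {name} needs {len(cfg['relations']) + 1} labels")
    return OrderingConstraint(
        labels=tuple(labels),
        relations=cfg["relations"],
        rel_tol=rel_tol,
        abs_floor=abs_floor,
        strict=cfg["strict"],
        name=name,
    )


class GateRecord(NamedTuple):
    """Per-gene verdict for one constraint."""

    passed: bool
    first_violation: int | None  # index of the first violated relation
    margin: float  # size of the worst violation (0 when passed)


def _relation_holds(
    a: float, b: float, rel: str, rel_tol: float, abs_floor: float, strict: bool
) -> tuple[bool, float]:
    """Evaluate one relation; returns (holds, violation margin)."""
    slack = rel_tol * max(abs(a), abs(b)) + abs_floor
    if rel == "=":
        margin = abs(a - b) - slack
        return margin <= 0, max(margin, 0.0)
    if rel == ">=":
        a, b = b, a
    # now testing a <= b
    if strict:
        margin = a - b + slack  # need a < b - slack
        return a < b - slack, max(margin, 0.0)
    margin = a - b - slack
    return margin <= 0, max(margin, 0.0)


def check_ordering(
    mu: Mapping[str, float] | pd.Series, constraint: OrderingConstraint
) -> tuple[bool, GateRecord]:
    """Check one gene's condition means against a constraint chain."""
    missing = [lab for lab in constraint.labels if lab not in mu]
    if missing:
        raise KeyError(f"missing condition values: {missing}")
    first: int | None = None
    worst = 0.0
    for i, rel in enumerate(constraint.relations):
        a, b = float(mu[constraint.labels[i]]), float(mu[constraint.labels[i + 1]])
        ok, margin = _relation_holds(
            a, b, rel, constraint.rel_tol, constraint.abs_floor, constraint.strict
        )
        if not ok:
            if first is None:
                first = i
            worst = max(worst, margin)
    passed = first is None
    return passed, GateRecord(passed, first, worst)


def apply_gate(
    selected_genes: Sequence,
    means: pd.DataFrame,
    constraints: Sequence[OrderingConstraint],
    mode: str = "any",
) -> tuple[list, pd.DataFrame]:
    """Filter genes by ordering constraints on their condition means.

    ``mode="any"`` keeps genes passing at least one constraint (the
    disjunctive C1-or-C2 usage); ``mode="all"`` requires every
    constraint.  Returns the retained genes plus a per-gene report with
    one pass/violation column pair per constraint.
    """
    if len(constraints) == 0:
        raise ValueError("need at least one constraint")
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    missing = [g for g in selected_genes if g not in means.index]
    if missing:
        raise KeyError(f"genes without condition means: {missing}")
    rows = []
    kept = []
    combine = any if mode == "any" else all
    for g in selected_genes:
        row: dict = {"gene": g}
        verdicts = []
        for c in constraints:
            ok, rec = check_ordering(means.loc[g], c)
            verdicts.append(ok)
            row[f"pass_{c.name}"] = ok
            row[f"violation_{c.name}"] = (
                "" if rec.first_violation is None else str(rec.first_violation)
            )
            row[f"margin_{c.name}"] = rec.margin
        row["passed"] = combine(verdicts)
        if row["passed"]:
            kept.append(g)
        rows.append(row)
    report = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()
    return kept, report


def derive_condition_order(
    phenotype: pd.DataFrame, marker: str
) -> list[str]:
    """Order conditions by donor-averaged phenotype counts, ascending.

    ``phenotype`` must have columns ``donor``, ``condition`` and one
    column per marker (e.g. CD68, CD163).  Ties break lexicographically
    and are flagged with a warning.
    """
    if marker not in phenotype.columns:
        raise KeyError(f"marker {marker!r} not in phenotype table")
    means = phenotype.groupby("condition")[marker].mean()
    if means.isna().any():
        raise ValueError("every condition needs at least one measurement")
    order = sorted(means.index, key=lambda c: (means[c], str(c)))
    if means.duplicated().any():
        warnings.warn("tied condition means; ties broken lexicographically")
    return list(order)


class R2Result(NamedTuple):
    r2: float  # squared Pearson correlation; NaN when undefined
    direction: int  # sign of the regression slope

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r2)


def univariate_r2(feature: Sequence[float], response: Sequence[float]) -> R2Result:
    """Simple-regression R-squared of response on feature, with sign.

    Equals the squared Pearson correlation.  A constant feature leaves
    the statistic undefined and returns NaN (never 0).
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("feature and response must share length >= 3")
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    if np.ptp(x) == 0:
        return R2Result(float("nan"), 0)
    xc, yc = x - x.mean(), y - y.mean()
    sxy = float(xc @ yc)
    r2 = sxy**2 / float((xc @ xc) * (yc @ yc))
    return R2Result(r2, int(np.sign(sxy)))
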