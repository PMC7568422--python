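"""End-to-end candidate screen: counts -> normalize -> pattern posterior
-> FDR selection -> ordering gate -> annotation filter.

Each stage writes a plain-text artifact into the output directory and
the run ends with a manifest recording the funnel (gene counts at every
stage) plus all parameters, so a run is reproducible and auditable from
its outputs alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as _io
from .annotate import annotate_and_filter
from .model import NBBetaPatternModel
from .normalize import condition_means, median_ratio_size_factors
from .ordering import (
    OrderingConstraint,
    PRESETS,
    apply_gate,
    constraint_preset,
    derive_condition_order,
    parse_constraint,
)
from .patterns import all_equal_pattern, all_unequal_pattern, enumerate_patterns

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure with stage-named diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Configuration for one full screen run."""

    counts: str
    condition_map: str
    output_dir: str
    phenotype: str | None = None
    annotations: str | None = None
    pattern_restriction: str | None = "p1_p6"
    target_pattern: str | None = None  # defaults to the fully split pattern
    fdr_level: float = 0.05
    de_threshold: float = 0.05
    constraints: list[str] = field(default_factory=list)
    gate_mode: str = "any"
    rel_tol: float = 0.0
    require_flags: list[str] = field(default_factory=lambda: ["relevance", "secreted"])
    max_iter: int = 100
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")


def _build_constraints(
    config: PipelineConfig, conditions: Sequence[str], phenotype: pd.DataFrame | None
) -> list[OrderingConstraint]:
    out: list[OrderingConstraint] = []
    for text in config.constraints:
        if text in PRESETS:
            out.append(constraint_preset(text, rel_tol=config.rel_tol))
        else:
            out.append(
                parse_constraint(text, rel_tol=config.rel_tol, known_labels=conditions)
            )
    if not out and phenotype is not None:
        # derive one monotone chain per phenotype marker and union them
        markers = [c for c in phenotype.columns if c not in ("donor", "condition")]
        for m in markers:
            order = derive_condition_order(phenotype, m)
            chain = "<=".join(order)
            out.append(parse_constraint(chain, rel_tol=config.rel_tol))
    if not out:
        raise PipelineError("gate", "no ordering constraints configured or derivable")
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns (and writes) the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        counts = _io.read_counts(config.counts)
        condition_map = _io.read_condition_map(config.condition_map)
        phenotype = _io.read_phenotype(config.phenotype) if config.phenotype else None
        annotations = (
            _io.read_annotations(config.annotations) if config.annotations else None
        )
    except (OSError, ValueError) as e:
        raise PipelineError("load", str(e)) from e

    conditions: list[str] = []
    for s in counts.columns:
        if s not in condition_map:
            raise PipelineError("load", f"sample {s} missing from condition map")
        if condition_map[s] not in conditions:
            conditions.append(condition_map[s])

    try:
        factors = median_ratio_size_factors(counts)
    except ValueError:
        factors = median_ratio_size_factors(counts, allow_pseudo_reference=True)
    means = condition_means(counts, factors, condition_map, conditions)
    _io.write_matrix(factors.to_frame(), outdir / "size_factors.tsv", "sample")
    _io.write_matrix(means, outdir / "condition_means.tsv")

    try:
        patterns = (
            enumerate_patterns(conditions, config.pattern_restriction)
            if config.pattern_restriction
            else enumerate_patterns(conditions)
        )
    except ValueError as e:
        raise PipelineError("fit", str(e)) from e
    if not any(p.n_blocks == 1 for p in patterns):
        patterns = [all_equal_pattern(conditions)] + patterns
    target = config.target_pattern or all_unequal_pattern(conditions).format_blocks()
    target_names = {p.name: p for p in patterns}
    full = [p for p in patterns if p.n_blocks == len(conditions)]
    if config.target_pattern is None and full:
        target = full[0].name
    if target not in target_names:
        raise PipelineError("fit", f"target pattern {target!r} not among candidates")

    model = NBBetaPatternModel(counts, condition_map, patterns, size_factors=factors)
    results = model.fit(max_iter=config.max_iter, tol=config.tol)
    post_out = results.posteriors.copy()
    post_out["map_pattern"] = results.map_pattern
    _io.write_matrix(post_out, outdir / "posteriors.tsv")
    (outdir / "fit_report.txt").write_text(results.summary() + "\n")

    universe = set(results.de_universe(config.de_threshold))
    selection = results.fdr_select(target, config.fdr_level)
    selected = [g for g in selection.genes if g in universe]
    pd.Series(selected, name="gene").to_csv(
        outdir / "selected_genes.tsv", sep="\t", index=False
    )

    constraints = _build_constraints(config, conditions, phenotype)
    try:
        gated, report = apply_gate(selected, means, constraints, mode=config.gate_mode)
    except (KeyError, ValueError) as e:
        raise PipelineError("gate", str(e)) from e
    if len(report):
        _io.write_matrix(report, outdir / "gate_report.tsv")

    if annotations is not None:
        try:
            candidates = annotate_and_filter(gated, annotations, config.require_flags)
        except ValueError as e:
            raise PipelineError("filter", str(e)) from e
        table = means.reindex([str(s) for s in candidates["symbol"]]).join(
            candidates.set_index("symbol"), how="left"
        )
        _io.write_matrix(table.round(2), outdir / "candidates.tsv", "symbol")
        n_candidates = len(candidates)
    else:
        n_candidates = None

    manifest = {
        "funnel": {
            "genes_in": int(counts.shape[0]),
            "genes_fit": int(results.posteriors.shape[0]),
            "de_universe": len(universe),
            "pattern_selected": len(selected),
            "gate_passed": len(gated),
            "annotation_passed": n_candidates,
        },
        "fit": {
            "alpha": results.params.alpha,
            "beta": results.params.beta,
            "mixture": {k: float(v) for k, v in results.params.mixture.items()},
            "converged": bool(results.converged),
            "n_iter": results.n_iter,
            "estimated_fdr": selection.estimated_fdr,
            "target_pattern": target,
        },
        "constraints": [c.name for c in constraints],
        "config": asdict(config),
    }
    _io.write_manifest(manifest, outdir / "manifest.json")
    return manifest
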