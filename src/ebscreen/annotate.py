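"""Annotation join: narrow gated genes to candidates with required flags.

The curation steps of a factor screen (pathway relevance, secreted /
soluble-factor status) enter as a user-supplied annotation table rather
than live database queries, so the funnel is deterministic and
reproducible given the curation encoded as data.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

__all__ = ["annotate_and_filter"]

log = logging.getLogger(__name__)


def _canon(symbol: str) -> str:
    return str(symbol).strip().upper()


def annotate_and_filter(
    genes: Sequence[str],
    annotations: pd.DataFrame,
    require: Sequence[str] = ("secreted",),
) -> pd.DataFrame:
    """Keep genes whose annotation has every required flag set.

    Parameters
    ----------
    genes
        Gene symbols that passed the upstream gate.
    annotations
        Table with a ``symbol`` column (or symbol index) and boolean
        flag columns (e.g. ``relevance``, ``secreted``); symbols are
        matched case-insensitively.
    require
        Non-empty set of flag column names that must all be true.

    Genes absent from the annotation table are excluded and logged; an
    empty annotation table is an error (distinct from "none pass").
    """
    if len(require) == 0:
        raise ValueError("require must name at least one flag")
    if annotations is None or len(annotations) == 0:
        raise ValueError("annotation table is empty; supply curation data")
    ann = annotations.reset_index() if "symbol" not in annotations.columns else annotations.copy()
    if "symbol" not in ann.columns:
        ann = ann.rename(columns={ann.columns[0]: "symbol"})
    ann["_key"] = ann["symbol"].map(_canon)
    if ann["_key"].duplicated().any():
        dupes = ann.loc[ann["_key"].duplicated(), "symbol"].tolist()
        raise ValueError(f"duplicate annotation symbols: {dupes}")
    missing_flags = [f for f in require if f not in ann.columns]
    if missing_flags:
        raise ValueError(f"annotation table lacks flag columns: {missing_flags}")
    ann = ann.set_index("_key")

    kept_rows = []
    for g in genes:
        key = _canon(g)
        if key not in ann.index:
            log.warning("gene %s absent from annotation table; excluded", g)
            continue
        row = ann.loc[key]
        if all(bool(row[f]) for f in require):
            out = {"symbol": g}
            out.update(
                {
                    c: row[c]
                    for c in ann.columns
                    if c not in ("symbol",)
                }
            )
            kept_rows.append(out)
    if not kept_rows:
        return pd.DataFrame(columns=["symbol", *[c for c in ann.columns if c != "symbol"]])
    return pd.DataFrame(kept_rows)
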