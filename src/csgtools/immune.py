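"""Tumor-infiltrating leukocyte (TIL) scoring from bulk expression.

Marker-set scoring in the Danaher style: each immune cell type is
represented by a small marker gene list; the cell-type score is the mean
log2(TPM+1) of its present markers, and the TIL score summarises a
sample's overall infiltration as the unweighted mean over cell-type
scores (or, behind a flag, a pooled mean over all markers).  The shipped
catalog is a deliberately small, editable stand-in — marker lists are
data, not code, and should be replaced with a curated catalog for real
analyses.
"""

from __future__ import annotations

import logging
from importlib import resources as _ir

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


def load_marker_catalog(path=None) -> dict[str, list[str]]:
    """Read a ``cell_type<TAB>gene`` TSV into a catalog; default is packaged."""
    if path is None:
        with _ir.as_file(_ir.files("csgtools.resources").joinpath("til_markers.tsv")) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    for col in ("cell_type", "gene"):
        if col not in df.columns:
            raise ValidationError(f"marker catalog missing column {col!r}")
    catalog: dict[str, list[str]] = {}
    for ct, grp in df.groupby("cell_type", sort=False):
        genes = list(grp["gene"])
        if len(set(genes)) != len(genes):
            raise ValidationError(f"duplicate markers within cell type {ct!r}")
        catalog[ct] = genes
    if not catalog:
        raise ValidationError("marker catalog is empty")
    return catalog


def cell_type_scores(
    expr: ExpressionMatrix, catalog: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Samples × cell-types score table (mean log2 expression of present markers).

    Cell types with no marker present in the matrix yield an NA column
    (with a warning); individually missing markers are logged and skipped.
    """
    if catalog is None:
        catalog = load_marker_catalog()
    log2 = expr.to_log2()
    out = {}
    any_present = False
    for ct, markers in catalog.items():
        present = [g for g in markers if g in log2.values.columns]
        missing = sorted(set(markers) - set(present))
        if missing:
            logger.warning("cell type %s: markers absent from matrix: %s", ct, missing)
        if not present:
            logger.warning("cell type %s has no present markers; scores set to NA", ct)
            out[ct] = pd.Series(np.nan, index=log2.values.index)
            continue
        any_present = True
        out[ct] = log2.values[present].mean(axis=1)
    if not any_present:
        raise ValidationError("no marker of any cell type present in the matrix")
    return pd.DataFrame(out)


def til_score(cell_scores: pd.DataFrame, pool: bool = False, catalog=None, expr=None) -> pd.Series:
    """Per-sample TIL score: mean of available cell-type scores (NA excluded).

    With ``pool=True``, the score is instead the mean over all individual
    markers (requires ``expr`` and ``catalog``), weighting cell types by
    their marker counts.
    """
    if pool:
        if expr is None or catalog is None:
            raise ValidationError("pooled TIL scoring needs expr and catalog")
        log2 = expr.to_log2()
        markers = sorted({g for genes in catalog.values() for g in genes})
        present = [g for g in markers if g in log2.values.columns]
        if not present:
            raise ValidationError("no marker present for pooled TIL scoring")
        score = log2.values[present].mean(axis=1)
    else:
        score = cell_scores.mean(axis=1, skipna=True)
    score.name = "til_score"
    return score
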