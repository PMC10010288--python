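"""Signature gene selection and activator/response set scoring.

Starting from a candidate list of cGAS-STING pathway genes, the signature
is the subset showing both high inter-sample variation (SD > 1 on the
log2 scale) and robust expression (per-gene mean above a cohort-level
reference).  The selected signature is then split into an *activator* set
(pathway initiation: STING1, CGAS, IFI16, ATM) and a *response* set
(downstream chemokine output: CCL5, CXCL9, CXCL10, CXCL11).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as _ir

import numpy as np
import pandas as pd

from .types import LOG2_TPM_PLUS1, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

ACTIVATOR_SET = ("STING1", "CGAS", "IFI16", "ATM")
RESPONSE_SET = ("CCL5", "CXCL9", "CXCL10", "CXCL11")
SIGNATURE_GENES = ACTIVATOR_SET + RESPONSE_SET


def default_candidates() -> list[str]:
    """Load the packaged 20-gene candidate list (comment lines ignored)."""
    text = _ir.files("csgtools.resources").joinpath("candidate_genes.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def load_candidates(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


@dataclass
class GenePanel:
    """Candidate list, selected signature genes, and the two functional sets."""

    candidates: list[str]
    selected: list[str]
    activator_set: list[str] = field(default_factory=lambda: list(ACTIVATOR_SET))
    response_set: list[str] = field(default_factory=lambda: list(RESPONSE_SET))

    def __post_init__(self) -> None:
        unknown = set(self.selected) - set(self.candidates)
        if unknown:
            raise ValidationError(f"selected genes not in candidate list: {sorted(unknown)}")
        if set(self.activator_set) & set(self.response_set):
            raise ValidationError("activator and response sets must be disjoint")

    @classmethod
    def default(cls) -> "GenePanel":
        """Panel with the eight signature genes pre-selected (no filtering)."""
        return cls(candidates=default_candidates(), selected=list(SIGNATURE_GENES))


def select_signature_genes(
    expr: ExpressionMatrix,
    candidates: list[str] | None = None,
    sd_threshold: float = 1.0,
    cohort_median_of: str = "gene_means",
) -> GenePanel:
    """Filter candidates to those with SD > 1 and mean above the cohort median.

    Parameters
    ----------
    expr
        Expression on the log2(TPM+1) scale.  The SD filter is
        scale-sensitive, so a linear-scale matrix is rejected.
    candidates
        Gene symbols to consider; defaults to the packaged 20-gene list.
        Candidates absent from the matrix are skipped with a warning.
    sd_threshold
        Minimum per-gene standard deviation (ddof=1).
    cohort_median_of
        What "cohort median" refers to: ``"gene_means"`` (default) compares
        each candidate's mean against the median of per-gene mean expression
        over every gene in the matrix; ``"all_values"`` compares against the
        median of all matrix entries.

    Returns
    -------
    GenePanel
        ``selected`` holds the passing candidates in input candidate order;
        the activator/response sets are the intersection of the defaults
        with the selection.
    """
    if expr.scale != LOG2_TPM_PLUS1:
        raise ValidationError(
            "signature selection requires log2(TPM+1) expression; call .to_log2() first"
        )
    if expr.n_samples < 2:
        raise ValidationError("signature selection needs at least 2 samples")
    if candidates is None:
        candidates = default_candidates()

    present = [g for g in candidates if g in expr.values.columns]
    missing = [g for g in candidates if g not in expr.values.columns]
    if missing:
        logger.warning("candidates absent from matrix, skipped: %s", missing)
    if not present:
        raise ValidationError("no candidate gene present in the expression matrix")

    gene_means = expr.values.mean(axis=0)
    if cohort_median_of == "gene_means":
        reference = float(gene_means.median())
    elif cohort_median_of == "all_values":
        reference = float(np.median(expr.values.to_numpy()))
    else:
        raise ValueError(f"unknown cohort_median_of mode {cohort_median_of!r}")

    sds = expr.values[present].std(axis=0, ddof=1)
    means = gene_means[present]
    selected = [g for g in present if sds[g] > sd_threshold and means[g] > reference]
    logger.info(
        "signature selection: %d/%d candidates pass (SD>%g, mean>%.3f)",
        len(selected), len(present), sd_threshold, reference,
    )
    return GenePanel(
        candidates=list(candidates),
        selected=selected,
        activator_set=[g for g in ACTIVATOR_SET if g in selected] or list(ACTIVATOR_SET),
        response_set=[g for g in RESPONSE_SET if g in selected] or list(RESPONSE_SET),
    )


def gene_set_score(values: pd.DataFrame | ExpressionMatrix, gene_set: list[str]) -> pd.Series:
    """Per-sample unweighted mean over a gene set, on the matrix's current scale.

    Accepts either an :class:`ExpressionMatrix` or a plain samples × genes
    frame (e.g. a z-scored matrix).
    """
    frame = values.values if isinstance(values, ExpressionMatrix) else values
    if not gene_set:
        raise ValidationError("gene_set is empty")
    present = [g for g in gene_set if g in frame.columns]
    if not present:
        raise ValidationError(f"no gene of {list(gene_set)} present in the matrix")
    if len(present) < len(gene_set):
        logger.warning("gene_set_score: missing genes %s", sorted(set(gene_set) - set(present)))
    return frame[present].mean(axis=1)
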