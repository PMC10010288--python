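"""Readers and writers for the pipeline's tabular formats.

All on-disk formats are plain TSV:

* expression — genes × samples or samples × genes numeric matrix with an
  index column; orientation is declared by the caller and values are
  auto-converted to the internal log2(TPM+1) scale;
* segments — SEG-like long table (``sample_id chrom start end cn_major
  cn_minor purity ploidy``), 1-based closed coordinates;
* mutations — MAF-like long table (``sample_id gene effect lof_flag``);
* clinical — one row per sample;
* truth — the simulator's ground-truth labels.

Readers validate headers and values up front and never silently drop
rows; every exclusion or conversion is logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import EffectCoefs, SimConfig, SimulatedCohort
from .types import (
    LINEAR_TPM,
    LOG2_TPM_PLUS1,
    CohortTable,
    CopyNumberProfile,
    ExpressionMatrix,
    MutationTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

SEGMENT_FILE_COLUMNS = ["sample_id", "chrom", "start", "end", "cn_major", "cn_minor", "purity", "ploidy"]
TRUTH_COLUMNS = ["sample_id", "true_csg", "true_wgii_regime", "true_neo_regime"]

VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}


def _require_columns(df: pd.DataFrame, required: list[str], what: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} file {path}: missing required columns {missing}")


def read_expression(
    path,
    scale_hint: str = LINEAR_TPM,
    orientation: str = "samples_by_genes",
) -> ExpressionMatrix:
    """Read a TSV expression matrix and convert to log2(TPM+1).

    ``orientation`` declares the file layout (``samples_by_genes`` or
    ``genes_by_samples``); the first column is the index either way.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "genes_by_samples":
        df = df.T
    elif orientation != "samples_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    arr = df.apply(pd.to_numeric, errors="coerce")
    bad = arr.isna() & df.notna()
    if bad.to_numpy().any():
        rows = df.index[bad.any(axis=1)].tolist()[:5]
        raise ValidationError(f"expression file {path}: non-numeric values in rows {rows}")
    if arr.isna().to_numpy().any():
        rows = arr.index[arr.isna().any(axis=1)].tolist()[:5]
        raise ValidationError(f"expression file {path}: missing values in rows {rows}")
    arr.index.name = None
    arr.columns.name = None
    em = ExpressionMatrix(arr, scale=scale_hint)
    if em.scale != LOG2_TPM_PLUS1:
        logger.info("expression %s read on %s scale; converting to log2(TPM+1)", path, em.scale)
        em = em.to_log2()
    return em


def write_expression(em: ExpressionMatrix, path) -> None:
    em.values.to_csv(path, sep="\t", index_label="sample_id")


def _parse_chrom(value, path, row_idx):
    c = str(value).removeprefix("chr")
    if c not in VALID_CHROMS:
        raise ValidationError(f"segment file {path}: unknown chromosome {value!r} at row {row_idx}")
    return int(c) if c not in ("X", "Y") else c


def read_segments(path) -> list[CopyNumberProfile]:
    """Read a SEG-like TSV into per-sample copy-number profiles."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SEGMENT_FILE_COLUMNS, "segment", path)
    for col in ("start", "end", "cn_major", "cn_minor", "purity", "ploidy"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            idx = int(df.index[coerced.isna()][0])
            raise ValidationError(f"segment file {path}: non-numeric {col!r} at row {idx}")
        df[col] = coerced
    df["chrom"] = [_parse_chrom(v, path, i) for i, v in enumerate(df["chrom"])]
    profiles = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        purity = grp["purity"].iloc[0]
        ploidy = grp["ploidy"].iloc[0]
        if grp["purity"].nunique() > 1 or grp["ploidy"].nunique() > 1:
            raise ValidationError(
                f"segment file {path}: inconsistent purity/ploidy for sample {sample_id}"
            )
        seg = grp[["chrom", "start", "end", "cn_major", "cn_minor"]].reset_index(drop=True)
        seg[["start", "end", "cn_major", "cn_minor"]] = seg[
            ["start", "end", "cn_major", "cn_minor"]
        ].astype(int)
        profiles.append(
            CopyNumberProfile(
                sample_id=str(sample_id), segments=seg, purity=float(purity), ploidy=float(ploidy)
            )
        )
    return profiles


def write_segments(profiles: list[CopyNumberProfile], path) -> None:
    frames = []
    for p in profiles:
        seg = p.segments.copy()
        seg.insert(0, "sample_id", p.sample_id)
        seg["purity"] = p.purity
        seg["ploidy"] = p.ploidy
        frames.append(seg)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_mutations(path) -> MutationTable:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, list(MutationTable.REQUIRED), "mutation", path)
    if df["lof_flag"].dtype != bool:
        df["lof_flag"] = df["lof_flag"].map(
            {"True": True, "False": False, True: True, False: False, 1: True, 0: False}
        )
        if df["lof_flag"].isna().any():
            idx = int(df.index[df["lof_flag"].isna()][0])
            raise ValidationError(f"mutation file {path}: unparseable lof_flag at row {idx}")
        df["lof_flag"] = df["lof_flag"].astype(bool)
    return MutationTable(df)


def write_mutations(muts: MutationTable, path) -> None:
    muts.records.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> CohortTable:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "os_months", "os_event"], "clinical", path)
    coerced = pd.to_numeric(df["os_months"], errors="coerce")
    if coerced.isna().any():
        idx = int(df.index[coerced.isna()][0])
        raise ValidationError(f"clinical file {path}: non-numeric os_months at row {idx}")
    df["os_months"] = coerced
    df["os_event"] = df["os_event"].astype(bool)
    return CohortTable(df)


def write_clinical(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, TRUTH_COLUMNS, "truth", path)
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write all cohort tables to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "segments": outdir / "segments.seg",
        "mutations": outdir / "mutations.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression(cohort.expr, paths["expression"])
    write_segments(cohort.profiles, paths["segments"])
    write_mutations(cohort.mutations, paths["mutations"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_truth(cohort.truth, paths["truth"])
    return paths


def load_sim_config(path) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML mapping (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("response_logit_coefs", "survival_loghr_coefs"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = EffectCoefs(**raw[key])
    for key in (
        "cin_high_fraction_range",
        "cin_low_fraction_range",
        "til_shifts",
        "tp53_lof_prob",
        "til_marker_genes",
        "background_mean_range",
    ):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)
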