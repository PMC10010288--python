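"""Core in-memory containers shared across the pipeline.

All containers are thin, validated wrappers around pandas objects so that
the synthetic and real-data paths share one representation:

* :class:`ExpressionMatrix` — samples × genes abundances with an explicit
  scale tag (``linear_tpm`` or ``log2_tpm_plus1``).  Everything downstream
  of IO operates on the log2(TPM+1) scale.
* :class:`CopyNumberProfile` — per-sample allele-specific segments
  (1-based, closed intervals) with purity and ploidy, as an ASCAT-style
  caller would emit.
* :class:`MutationTable` — long-format per-mutation records with an effect
  class and a loss-of-function flag.
* :class:`CohortTable` — per-sample clinical table (overall survival,
  RECIST-like response, stage, cancer type, neoantigen burden, optional
  IHC immune phenotype).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LINEAR_TPM = "linear_tpm"
LOG2_TPM_PLUS1 = "log2_tpm_plus1"

EXPRESSION_SCALES = (LINEAR_TPM, LOG2_TPM_PLUS1)

#: Four cGAS-STING groups, ordered; CSG1 is the reference level everywhere.
CSG_LABELS = ("CSG1", "CSG2", "CSG3", "CSG4")

MUTATION_EFFECTS = ("nonsynonymous", "synonymous", "other")
RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NA")
IMMUNE_PHENOTYPES = ("inflamed", "excluded", "desert", "NA")

#: RECIST-like categories counted as objective response.
RESPONDER_CATEGORIES = frozenset({"CR", "PR"})


class ValidationError(ValueError):
    """Raised when an input container violates its documented contract."""


@dataclass
class ExpressionMatrix:
    """Samples × genes abundance matrix with an explicit scale tag."""

    values: pd.DataFrame
    scale: str = LOG2_TPM_PLUS1

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("expression values must be a DataFrame")
        if self.scale not in EXPRESSION_SCALES:
            raise ValidationError(
                f"unknown expression scale {self.scale!r}; expected one of {EXPRESSION_SCALES}"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_log2(self) -> "ExpressionMatrix":
        """Return the matrix on the internal log2(TPM+1) scale (no-op if already)."""
        if self.scale == LOG2_TPM_PLUS1:
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), scale=LOG2_TPM_PLUS1)

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == LINEAR_TPM:
            return self
        return ExpressionMatrix(2.0 ** self.values - 1.0, scale=LINEAR_TPM)

    def require_genes(self, genes: list[str], context: str = "operation") -> None:
        missing = [g for g in genes if g not in self.values.columns]
        if missing:
            raise ValidationError(f"{context}: missing required genes {missing}")

    def gene(self, gene: str) -> pd.Series:
        self.require_genes([gene])
        return self.values[gene]


SEGMENT_COLUMNS = ["chrom", "start", "end", "cn_major", "cn_minor"]


@dataclass
class CopyNumberProfile:
    """Allele-specific copy-number segments for one sample.

    Coordinates are 1-based closed intervals; segment length is
    ``end - start + 1``.  Copy numbers are assumed purity-corrected, as
    ASCAT outputs are.
    """

    sample_id: str
    segments: pd.DataFrame
    purity: float = 1.0
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        seg = self.segments
        missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
        if missing:
            raise ValidationError(
                f"sample {self.sample_id}: segment table missing columns {missing}"
            )
        if not 0 < self.purity <= 1:
            raise ValidationError(f"sample {self.sample_id}: purity must be in (0, 1]")
        if len(seg) == 0:
            return
        if (seg["start"] > seg["end"]).any():
            raise ValidationError(f"sample {self.sample_id}: segment with start > end")
        if (seg["cn_major"] < 0).any() or (seg["cn_minor"] < 0).any():
            raise ValidationError(f"sample {self.sample_id}: negative copy number")
        if (seg["cn_minor"] > seg["cn_major"]).any():
            raise ValidationError(
                f"sample {self.sample_id}: cn_minor exceeds cn_major"
            )
        for chrom, grp in seg.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
                raise ValidationError(
                    f"sample {self.sample_id}: overlapping segments on chromosome {chrom}"
                )

    @property
    def total_cn(self) -> pd.Series:
        return self.segments["cn_major"] + self.segments["cn_minor"]


@dataclass
class MutationTable:
    """Long-format mutation records: one row per mutation call."""

    records: pd.DataFrame

    REQUIRED = ("sample_id", "gene", "effect", "lof_flag")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValidationError(f"mutation table missing columns {missing}")
        bad = set(self.records["effect"].unique()) - set(MUTATION_EFFECTS)
        if bad:
            raise ValidationError(
                f"unknown mutation effect classes {sorted(bad)}; expected {MUTATION_EFFECTS}"
            )

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.records[self.records["sample_id"] == sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.records["sample_id"]))


CLINICAL_REQUIRED = ("sample_id", "os_months", "os_event")


@dataclass
class CohortTable:
    """Per-sample clinical table; downstream modules append derived columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns {missing}")
        if self.data["sample_id"].duplicated().any():
            raise ValidationError("clinical table has duplicate sample ids")
        if (self.data["os_months"] < 0).any():
            raise ValidationError("os_months must be >= 0")
        if "response" in self.data.columns:
            bad = set(self.data["response"].fillna("NA")) - set(RESPONSE_CATEGORIES)
            if bad:
                raise ValidationError(f"unknown response categories {sorted(bad)}")
        if "immune_phenotype" in self.data.columns:
            bad = set(self.data["immune_phenotype"].fillna("NA")) - set(IMMUNE_PHENOTYPES)
            if bad:
                raise ValidationError(f"unknown immune phenotypes {sorted(bad)}")

    def copy(self) -> "CohortTable":
        return dataclasses.replace(self, data=self.data.copy())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])
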