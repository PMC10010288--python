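"""Per-sample genomic and pathway summary statistics.

* wGII — weighted genome integrity index: for each autosome, the fraction
  of covered bases whose total copy number differs from the sample's
  rounded ploidy, averaged over the 22 autosomes with equal weight
  (chromosome size does not enter).  Range [0, 1]; a perfectly diploid —
  or balanced tetraploid — genome scores 0.
* TMB — nonsynonymous mutations per megabase of capture territory
  (default 38 Mb exome).
* NFκB subunit log-ratio — log2((NFKB1+1)/(NFKB2+1)) on the linear scale,
  i.e. the difference of the shifted log2 values; low values flag
  non-canonical (NFκB2-dominant) signalling.
* Per-group CGAS–STING1 Pearson correlation and per-group TP53
  loss-of-function fractions.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._genome import GRCH38_AUTOSOME_LENGTHS
from .types import (
    CopyNumberProfile,
    ExpressionMatrix,
    MutationTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_CAPTURE_MB = 38.0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def wgii(
    profile: CopyNumberProfile,
    chrom_lengths: dict[int, int] | None = None,
    coverage_warn_fraction: float = 0.9,
) -> float:
    """Weighted genome integrity index of one copy-number profile.

    Parameters
    ----------
    profile
        Allele-specific segments with ploidy; sex chromosomes are ignored.
    chrom_lengths
        Autosome→length map defining the autosome set and expected
        coverage; defaults to the built-in GRCh38 table.  Aberrant
        fractions are computed over covered bases; chromosomes covered
        below ``coverage_warn_fraction`` of their length trigger a
        warning, and chromosomes with no segments are excluded from the
        average (also warned).
    """
    if profile.ploidy <= 0:
        raise ValidationError(f"sample {profile.sample_id}: ploidy must be > 0")
    if chrom_lengths is None:
        chrom_lengths = GRCH38_AUTOSOME_LENGTHS
    seg = profile.segments
    seg = seg[seg["chrom"].isin(chrom_lengths)]
    if seg.empty:
        raise ValidationError(f"sample {profile.sample_id}: no autosomal segments")
    baseline = _round_half_up(profile.ploidy)
    total_cn = (seg["cn_major"] + seg["cn_minor"]).to_numpy()
    lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
    aberrant = total_cn != baseline

    fracs = []
    for chrom, expected in chrom_lengths.items():
        mask = (seg["chrom"] == chrom).to_numpy()
        covered = lengths[mask].sum()
        if covered == 0:
            warnings.warn(
                f"sample {profile.sample_id}: chromosome {chrom} has no segments; "
                "excluded from wGII",
                stacklevel=2,
            )
            continue
        if covered < coverage_warn_fraction * expected:
            warnings.warn(
                f"sample {profile.sample_id}: chromosome {chrom} covered "
                f"{covered / expected:.1%} (<{coverage_warn_fraction:.0%}); "
                "fraction computed over covered bases",
                stacklevel=2,
            )
        fracs.append(lengths[mask][aberrant[mask]].sum() / covered)
    return float(np.mean(fracs))


def tmb(
    muts: MutationTable, sample_id: str, capture_mb: float = DEFAULT_CAPTURE_MB
) -> float:
    """Nonsynonymous mutations per megabase for one sample."""
    if capture_mb <= 0:
        raise ValidationError("capture_mb must be > 0")
    if sample_id not in set(muts.records["sample_id"]):
        logger.warning("sample %s absent from mutation table; TMB reported as 0", sample_id)
        return 0.0
    recs = muts.for_sample(sample_id)
    return float((recs["effect"] == "nonsynonymous").sum() / capture_mb)


def nfkb_ratio(expr: ExpressionMatrix) -> pd.Series:
    """Per-sample log2((NFKB1+1)/(NFKB2+1)) computed on the linear scale.

    The +1 pseudocount tolerates zeros; on log2(TPM+1) input the result is
    exactly the difference of the stored values.
    """
    expr.require_genes(["NFKB1", "NFKB2"], "nfkb_ratio")
    log2 = expr.to_log2()
    out = log2.values["NFKB1"] - log2.values["NFKB2"]
    out.name = "nfkb_log_ratio"
    return out


def group_correlation(
    expr: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    groups: pd.Series,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Per-group Pearson r (with p-value) between two genes.

    ``groups`` maps sample id → group label; groups with fewer than
    ``min_samples`` samples are reported as NA.
    """
    expr.require_genes([gene_a, gene_b], "group_correlation")
    frame = expr.values
    rows = []
    for grp, idx in groups.groupby(groups).groups.items():
        samples = [s for s in idx if s in frame.index]
        if len(samples) < min_samples:
            rows.append((grp, len(samples), np.nan, np.nan))
            continue
        r, p = stats.pearsonr(frame.loc[samples, gene_a], frame.loc[samples, gene_b])
        rows.append((grp, len(samples), float(r), float(p)))
    return pd.DataFrame(rows, columns=["group", "n", "r", "p_value"]).set_index("group")


def lof_fraction(
    muts: MutationTable, gene: str, groups: pd.Series
) -> pd.Series:
    """Per-group fraction of samples carrying ≥1 loss-of-function record in ``gene``.

    Duplicate LOF records within a sample count once.  ``groups`` maps
    sample id → group label and defines the samples in scope; empty groups
    yield NA.
    """
    recs = muts.records
    lof_samples = set(
        recs.loc[(recs["gene"] == gene) & recs["lof_flag"], "sample_id"]
    )
    out = {}
    for grp, idx in groups.groupby(groups).groups.items():
        members = list(idx)
        out[grp] = (
            np.nan if not members else sum(s in lof_samples for s in members) / len(members)
        )
    return pd.Series(out, name=f"{gene}_lof_fraction")


def sample_metrics(
    profiles: list[CopyNumberProfile],
    muts: MutationTable,
    expr: ExpressionMatrix,
    csg: pd.Series | None = None,
    capture_mb: float = DEFAULT_CAPTURE_MB,
    chrom_lengths: dict[int, int] | None = None,
) -> pd.DataFrame:
    """One row per sample: wGII, TMB, NFκB log-ratio (and CSG if given)."""
    ratio = nfkb_ratio(expr)
    rows = []
    for p in profiles:
        rows.append(
            {
                "sample_id": p.sample_id,
                "wgii": wgii(p, chrom_lengths=chrom_lengths),
                "tmb": tmb(muts, p.sample_id, capture_mb=capture_mb),
                "nfkb_log_ratio": ratio.get(p.sample_id, np.nan),
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    if csg is not None:
        out["csg"] = csg
    return out
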