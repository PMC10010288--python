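"""Synthetic linked multi-omic cohorts with known CSG structure.

The generator produces expression, copy-number, mutation and clinical
tables that share sample ids and a ground-truth table, with the
statistical structure the downstream analysis assumes:

* four expression archetypes over the 8-gene signature — two low-expression
  groups (CSG1: activators relatively up; CSG2: responders relatively up),
  one fully active group (CSG3: everything high) and one aberrant group
  (CSG4: activators high, responders low);
* within-group CGAS–STING1 correlation (positive in CSG3, negative in
  CSG4, none in CSG1/CSG2);
* NFκB1/NFκB2 log-ratio lowest in CSG2 (non-canonical signalling);
* TIL marker elevation highest in CSG3, second in CSG4;
* copy-number profiles whose aberrant genome fraction is drawn from a
  high or a low regime, providing a wGII substrate;
* response and survival outcomes in which the CSG3 × high-wGII ×
  high-neoantigen combination carries the configured benefit.

Archetype means are design parameters chosen to reproduce the qualitative
orderings above; they are not estimates of any real cohort and are all
overridable.  A fixed ``seed`` fully determines every output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._genome import AUTOSOMES, GRCH38_AUTOSOME_LENGTHS
from .panel import ACTIVATOR_SET, RESPONSE_SET, SIGNATURE_GENES
from .types import (
    LOG2_TPM_PLUS1,
    CSG_LABELS,
    CohortTable,
    CopyNumberProfile,
    ExpressionMatrix,
    MutationTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Default TIL marker genes placed in synthetic matrices (matches the
#: packaged marker catalog so scoring round-trips).
DEFAULT_TIL_MARKERS = (
    "CD8A", "CD8B", "CD3D", "CD3E", "CD3G", "CD6", "MS4A1", "CD19",
    "NKG7", "GNLY", "CD68", "CD163", "PRF1", "GZMA",
)

CANCER_TYPES = ("BLCA", "LUAD", "LUSC", "SKCM", "OV")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Latent expression archetype for one CSG (z-units on the 8-gene panel)."""

    csg_id: str
    activator_mean: float
    response_mean: float
    cgas_sting_corr: float = 0.0
    nfkb_log_ratio_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.csg_id not in CSG_LABELS:
            raise ValidationError(f"unknown CSG id {self.csg_id!r}")
        if not -1.0 <= self.cgas_sting_corr <= 1.0:
            raise ValidationError("cgas_sting_corr must lie in [-1, 1]")


def default_archetypes() -> tuple[ArchetypeSpec, ...]:
    """The four default archetypes (one per CSG)."""
    return (
        ArchetypeSpec("CSG1", -0.5, -1.0, cgas_sting_corr=0.0, nfkb_log_ratio_mean=0.5),
        ArchetypeSpec("CSG2", -1.0, -0.3, cgas_sting_corr=0.0, nfkb_log_ratio_mean=-1.0),
        ArchetypeSpec("CSG3", 1.0, 1.0, cgas_sting_corr=0.8, nfkb_log_ratio_mean=1.0),
        ArchetypeSpec("CSG4", 0.8, -0.5, cgas_sting_corr=-0.6, nfkb_log_ratio_mean=1.0),
    )


@dataclass(frozen=True)
class EffectCoefs:
    """Coefficients on (CSG3, high-wGII, high-neoantigen) indicators."""

    intercept: float = 0.0
    csg3: float = 0.0
    high_wgii: float = 0.0
    high_neo: float = 0.0
    interaction: float = 0.0

    def linear_predictor(self, csg3, high_wgii, high_neo) -> np.ndarray:
        csg3 = np.asarray(csg3, dtype=float)
        hw = np.asarray(high_wgii, dtype=float)
        hn = np.asarray(high_neo, dtype=float)
        lp = (
            self.intercept
            + self.csg3 * csg3
            + self.high_wgii * hw
            + self.high_neo * hn
            + self.interaction * csg3 * hw * hn
        )
        if not np.isfinite(lp).all():
            raise ValidationError("non-finite linear predictor from effect coefficients")
        return lp


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level generator settings; ``seed`` fully determines outputs."""

    n_samples_per_group: int = 200
    n_background_genes: int = 1000
    noise_sd: float = 0.5
    cin_high_fraction_range: tuple[float, float] = (0.4, 0.7)
    cin_low_fraction_range: tuple[float, float] = (0.0, 0.2)
    neoantigen_rate_high: float = 2.8
    neoantigen_rate_low: float = 1.2
    response_logit_coefs: EffectCoefs = EffectCoefs(
        intercept=-2.0, csg3=0.4, high_wgii=0.2, high_neo=0.6, interaction=0.6
    )
    survival_loghr_coefs: EffectCoefs = EffectCoefs(
        intercept=0.0, csg3=-0.3, high_wgii=-0.2, high_neo=-0.3, interaction=-1.5
    )
    baseline_hazard: float = 1.0 / 12.0  # events per month; median ~8.3 months untreated
    censor_rate: float = 0.25
    seed: int = 0
    # expression placement on the log2(TPM+1) scale
    signature_base: float = 6.0
    signature_scale: float = 1.5
    background_mean_range: tuple[float, float] = (0.5, 5.0)
    background_sd: float = 0.5
    til_marker_genes: tuple[str, ...] = DEFAULT_TIL_MARKERS
    til_shifts: tuple[float, float, float, float] = (-1.0, -0.6, 1.0, 0.5)
    til_base: float = 4.0
    til_sd: float = 0.5
    # mutation burden (per exome capture) by neoantigen regime
    mutation_mean_high: float = 60.0
    mutation_mean_low: float = 15.0
    capture_mb: float = 38.0
    tp53_lof_prob: tuple[float, float, float, float] = (0.25, 0.3, 0.2, 0.6)

    def __post_init__(self) -> None:
        if self.n_samples_per_group <= 0 or self.n_background_genes < 0:
            raise ValidationError("sample and gene counts must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for rng_ in (self.cin_high_fraction_range, self.cin_low_fraction_range):
            lo, hi = rng_
            if not (0 <= lo <= hi <= 1):
                raise ValidationError(f"CIN fraction range {rng_} not within [0, 1]")
        if not 0 <= self.censor_rate <= 1:
            raise ValidationError("censor_rate must be a probability")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be > 0")


@dataclass
class SimulatedExpression:
    """Expression matrix plus ground truth and the latent z-values it encodes."""

    expr: ExpressionMatrix
    truth: pd.DataFrame  # sample_id, true_csg, true_wgii_regime, true_neo_regime
    latent_z: pd.DataFrame  # samples × 8 signature genes, archetype z-units


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive streams per operation
    return np.random.default_rng([config.seed, stream])


def simulate_expression(
    config: SimConfig,
    archetypes: tuple[ArchetypeSpec, ...] | None = None,
) -> SimulatedExpression:
    """Draw the samples × genes matrix and the ground-truth table.

    The matrix contains the 8 signature genes, NFKB1/NFKB2, TP53, the TIL
    marker genes and ``n_background_genes`` noise genes, on the
    log2(TPM+1) scale.  Signature-gene values are an affine placement of
    latent archetype z-values (``signature_base + signature_scale * z``),
    so per-group means approach the archetype means as ``noise_sd`` → 0.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if not archetypes:
        raise ValidationError("archetype set is empty")
    by_csg = {a.csg_id: a for a in archetypes}
    if sorted(by_csg) != sorted(CSG_LABELS):
        raise ValidationError(
            f"archetype set must contain exactly one spec per CSG; got {sorted(by_csg)}"
        )

    rng = _rng(config, 1)
    n = config.n_samples_per_group
    sample_ids, groups = [], []
    for csg in CSG_LABELS:
        sample_ids += [f"{csg}_{i:04d}" for i in range(n)]
        groups += [csg] * n
    total = len(sample_ids)

    z = pd.DataFrame(index=sample_ids, columns=list(SIGNATURE_GENES), dtype=float)
    nfkb_ratio = np.empty(total)
    for csg in CSG_LABELS:
        a = by_csg[csg]
        mask = np.array(groups) == csg
        m = int(mask.sum())
        # CGAS and STING1 jointly, with the archetype's correlation;
        # degenerate cases (zero noise, |rho| = 1) handled exactly
        rho = a.cgas_sting_corr
        if config.noise_sd == 0:
            pair = np.full((m, 2), a.activator_mean)
        elif abs(rho) == 1.0:
            x = rng.normal(a.activator_mean, config.noise_sd, size=m)
            pair = np.column_stack([x, a.activator_mean + np.sign(rho) * (x - a.activator_mean)])
        else:
            cov = (config.noise_sd**2) * np.array([[1.0, rho], [rho, 1.0]])
            pair = rng.multivariate_normal(
                [a.activator_mean] * 2, cov, size=m, method="cholesky"
            )
        z.loc[mask, "CGAS"] = pair[:, 0]
        z.loc[mask, "STING1"] = pair[:, 1]
        for g in ("IFI16", "ATM"):
            z.loc[mask, g] = rng.normal(a.activator_mean, config.noise_sd, size=m)
        for g in RESPONSE_SET:
            z.loc[mask, g] = rng.normal(a.response_mean, config.noise_sd, size=m)
        nfkb_ratio[mask] = a.nfkb_log_ratio_mean + rng.normal(0, 0.2, size=m)

    values = {}
    for g in SIGNATURE_GENES:
        values[g] = np.clip(config.signature_base + config.signature_scale * z[g].to_numpy(), 0, None)
    nfkb2 = np.clip(5.0 + rng.normal(0, 0.4, size=total), 0, None)
    values["NFKB2"] = nfkb2
    values["NFKB1"] = np.clip(nfkb2 + nfkb_ratio, 0, None)
    values["TP53"] = np.clip(5.5 + rng.normal(0, 0.4, size=total), 0, None)

    group_idx = np.array([CSG_LABELS.index(g) for g in groups])
    til_shift = np.asarray(config.til_shifts)[group_idx]
    for g in config.til_marker_genes:
        values[g] = np.clip(
            config.til_base + til_shift + rng.normal(0, config.til_sd, size=total), 0, None
        )

    bg_lo, bg_hi = config.background_mean_range
    bg_means = rng.uniform(bg_lo, bg_hi, size=config.n_background_genes)
    for i in range(config.n_background_genes):
        values[f"BG{i:05d}"] = np.clip(
            bg_means[i] + rng.normal(0, config.background_sd, size=total), 0, None
        )

    expr = ExpressionMatrix(pd.DataFrame(values, index=sample_ids), scale=LOG2_TPM_PLUS1)
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "true_csg": groups,
            "true_wgii_regime": np.where(rng.random(total) < 0.5, "high", "low"),
            "true_neo_regime": np.where(rng.random(total) < 0.5, "high", "low"),
        }
    )
    return SimulatedExpression(expr=expr, truth=truth, latent_z=z)


def simulate_copy_number(
    config: SimConfig,
    truth: pd.DataFrame,
    chrom_lengths: dict[int, int] | None = None,
) -> list[CopyNumberProfile]:
    """Per-sample 22-autosome segment sets with regime-controlled aberrant fraction.

    Each chromosome is tiled without gaps or overlaps: an aberrant prefix
    (total copy number 3 against a diploid baseline) covering the sample's
    drawn genome fraction, then a normal 1+1 remainder.  The resulting
    wGII equals the drawn fraction up to base-level rounding.
    """
    if truth.empty:
        raise ValidationError("truth table is empty")
    if chrom_lengths is None:
        chrom_lengths = GRCH38_AUTOSOME_LENGTHS
    lo_hi = config.cin_high_fraction_range
    lo_lo = config.cin_low_fraction_range
    if lo_lo[1] > lo_hi[0]:
        warnings.warn(
            "CIN fraction ranges overlap; high/low wGII regimes may be indistinguishable",
            stacklevel=2,
        )
    rng = _rng(config, 2)
    profiles = []
    for _, row in truth.iterrows():
        lo, hi = lo_hi if row["true_wgii_regime"] == "high" else lo_lo
        frac = rng.uniform(lo, hi) if hi > lo else lo
        purity = rng.uniform(0.4, 0.95)
        rows = []
        for chrom, length in chrom_lengths.items():
            aberrant = int(round(frac * length))
            if aberrant >= length:
                rows.append((chrom, 1, length, 2, 1))
            elif aberrant == 0:
                rows.append((chrom, 1, length, 1, 1))
            else:
                rows.append((chrom, 1, aberrant, 2, 1))
                rows.append((chrom, aberrant + 1, length, 1, 1))
        seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn_major", "cn_minor"])
        profiles.append(
            CopyNumberProfile(
                sample_id=row["sample_id"], segments=seg, purity=float(purity), ploidy=2.0
            )
        )
    return profiles


def simulate_mutations(config: SimConfig, truth: pd.DataFrame) -> MutationTable:
    """Per-sample mutation records; burden tracks the neoantigen regime and
    TP53 loss-of-function probability is CSG-dependent (highest in CSG4)."""
    if truth.empty:
        raise ValidationError("truth table is empty")
    rng = _rng(config, 3)
    recs = []
    lof_prob = dict(zip(CSG_LABELS, config.tp53_lof_prob))
    for _, row in truth.iterrows():
        mean = (
            config.mutation_mean_high
            if row["true_neo_regime"] == "high"
            else config.mutation_mean_low
        )
        n_mut = rng.poisson(mean)
        effects = rng.choice(
            ["nonsynonymous", "synonymous", "other"], size=n_mut, p=[0.75, 0.2, 0.05]
        )
        for eff in effects:
            recs.append((row["sample_id"], f"GENE{rng.integers(0, 5000):05d}", eff, False))
        if rng.random() < lof_prob[row["true_csg"]]:
            recs.append((row["sample_id"], "TP53", "nonsynonymous", True))
    return MutationTable(
        pd.DataFrame(recs, columns=["sample_id", "gene", "effect", "lof_flag"])
    )


def simulate_clinical(config: SimConfig, truth: pd.DataFrame) -> CohortTable:
    """Draw response and survival outcomes from the configured effect models.

    Response is Bernoulli with a logit linear in the (CSG3, high-wGII,
    high-neoantigen, three-way interaction) indicators; survival is
    exponential with log-hazard linear in the same indicators; censoring
    replaces the event time with a uniform draw below it at rate
    ``censor_rate``.
    """
    if truth.empty:
        raise ValidationError("truth table is empty")
    rng = _rng(config, 4)
    csg3 = (truth["true_csg"] == "CSG3").to_numpy()
    hw = (truth["true_wgii_regime"] == "high").to_numpy()
    hn = (truth["true_neo_regime"] == "high").to_numpy()
    n = len(truth)

    logit = config.response_logit_coefs.linear_predictor(csg3, hw, hn)
    p_resp = 1.0 / (1.0 + np.exp(-logit))
    responder = rng.random(n) < p_resp
    cat_r = np.where(rng.random(n) < 0.3, "CR", "PR")
    cat_n = np.where(rng.random(n) < 0.3, "SD", "PD")
    response = np.where(responder, cat_r, cat_n)

    log_hr = config.survival_loghr_coefs.linear_predictor(csg3, hw, hn)
    hazard = config.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < config.censor_rate
    os_months = np.where(censored, rng.random(n) * t_event, t_event)
    os_event = ~censored

    neo_rate = np.where(hn, config.neoantigen_rate_high, config.neoantigen_rate_low)
    neoantigens = rng.gamma(shape=2.0, scale=neo_rate / 2.0)

    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.1, 0.3, 0.4, 0.2])
    cancer_type = rng.choice(CANCER_TYPES, size=n, p=[0.25, 0.2, 0.2, 0.2, 0.15])

    pheno = np.empty(n, dtype=object)
    for i, csg in enumerate(truth["true_csg"]):
        if csg == "CSG3":
            probs = [0.7, 0.2, 0.1]
        elif csg == "CSG4":
            probs = [0.1, 0.55, 0.35]
        else:
            probs = [0.15, 0.35, 0.5]
        pheno[i] = rng.choice(["inflamed", "excluded", "desert"], p=probs)

    return CohortTable(
        pd.DataFrame(
            {
                "sample_id": truth["sample_id"].to_numpy(),
                "os_months": os_months,
                "os_event": os_event,
                "response": response,
                "stage": stage,
                "cancer_type": cancer_type,
                "neoantigen_burden": neoantigens,
                "immune_phenotype": pheno,
            }
        )
    )


@dataclass
class SimulatedCohort:
    """All linked tables for one synthetic cohort."""

    expr: ExpressionMatrix
    truth: pd.DataFrame
    latent_z: pd.DataFrame
    profiles: list[CopyNumberProfile]
    mutations: MutationTable
    clinical: CohortTable
    config: SimConfig


def simulate_cohort(
    config: SimConfig | None = None,
    archetypes: tuple[ArchetypeSpec, ...] | None = None,
    chrom_lengths: dict[int, int] | None = None,
) -> SimulatedCohort:
    """Generate the full linked cohort (expression, CN, mutations, clinical)."""
    if config is None:
        config = SimConfig()
    sim = simulate_expression(config, archetypes)
    profiles = simulate_copy_number(config, sim.truth, chrom_lengths=chrom_lengths)
    mutations = simulate_mutations(config, sim.truth)
    clinical = simulate_clinical(config, sim.truth)
    return SimulatedCohort(
        expr=sim.expr,
        truth=sim.truth,
        latent_z=sim.latent_z,
        profiles=profiles,
        mutations=mutations,
        clinical=clinical,
        config=config,
    )
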