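"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from csgtools.simulate import SimConfig, simulate_cohort

#: Small chromosome-length table used for brute-force wGII oracle tests
#: (unit-bin expansion of real chromosome lengths would be infeasible).
TOY_CHROMS = {1: 600, 2: 450, 3: 300}


def wgii_bruteforce(profile, chrom_lengths) -> float:
    """Unit-bin oracle for wGII: expand every segment to single bases.

    Independent of the production implementation: counts, base by base,
    covered bases whose total copy number differs from the rounded
    ploidy, averaging the per-chromosome fractions over chromosomes with
    at least one covered base.
    """
    baseline = int(np.floor(profile.ploidy + 0.5))
    fracs = []
    for chrom in chrom_lengths:
        seg = profile.segments[profile.segments["chrom"] == chrom]
        covered = []
        for _, row in seg.iterrows():
            total = int(row["cn_major"] + row["cn_minor"])
            covered.extend([total] * int(row["end"] - row["start"] + 1))
        if not covered:
            continue
        covered = np.array(covered)
        fracs.append(float((covered != baseline).mean()))
    return float(np.mean(fracs))


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums, over all tables with the observed margins, the probabilities of
    tables no more likely than the observed one (with a small relative
    tolerance for float ties, matching the conventional definition).
    """
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p_k = hypergeom.pmf(k, n, col1, row1)
        if p_k <= p_obs * (1 + 1e-9):
            total += p_k
    return min(total, 1.0)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return dataclasses.replace(
        SimConfig(), n_samples_per_group=40, n_background_genes=30, seed=3
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A small but fully linked synthetic cohort shared by read-only tests."""
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def blob_z8():
    """Four well-separated Gaussian blobs over the 8 signature genes,
    bypassing UMAP for fast unit tests of clustering-adjacent code."""
    from csgtools.panel import SIGNATURE_GENES

    rng = np.random.default_rng(0)
    centers = {
        "CSG1": (-0.5, -1.0),
        "CSG2": (-1.0, -0.3),
        "CSG3": (1.0, 1.0),
        "CSG4": (0.8, -0.5),
    }
    frames, labels = [], []
    for csg, (a, r) in centers.items():
        mean = [a] * 4 + [r] * 4
        frames.append(rng.normal(mean, 0.15, size=(50, 8)))
        labels += [csg] * 50
    z = pd.DataFrame(
        np.vstack(frames),
        columns=list(SIGNATURE_GENES),
        index=[f"s{i}" for i in range(200)],
    )
    return z, pd.Series(labels, index=z.index)
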