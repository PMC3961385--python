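"""Shared fixtures: a small synthetic study and pileup helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from haploscan.region import default_region
from haploscan.simulate import (
    Cohort,
    default_tag_spec,
    sample_cohort,
    simulate_haplotype_pool,
)


@pytest.fixture(scope="session")
def region():
    return default_region("test")


@pytest.fixture(scope="session")
def pool(region):
    return simulate_haplotype_pool(
        region, n_founders=30, theta_sim=5.42e-4, tag_spec=default_tag_spec(region), seed=11
    )


@pytest.fixture(scope="session")
def cohort(pool):
    return sample_cohort(pool, n_cases=48, n_controls=0, n_reference=174, seed=12)


def pileups_from_truth(
    cohort: Cohort,
    depth: int = 30,
    epsilon: float = 0.0,
    seed: int = 0,
    statuses: tuple[str, ...] = ("case",),
) -> pd.DataFrame:
    """Fixed-depth pileups at the pool's polymorphic sites only.

    A fast alternative to the full per-base simulator for caller-focused
    tests: every sequenced sample gets exactly ``depth`` reads per site,
    with a symmetric error rate ``epsilon`` and no allelic bias.
    """
    rng = np.random.default_rng(seed)
    pool = cohort.pool
    idx = np.sort(np.concatenate([cohort.indices(s) for s in statuses]))
    samples = [cohort.sample_ids[i] for i in idx]
    geno = cohort.genotype_matrix()[:, idx]  # (S, n)
    q_alt = geno / 2.0
    p_alt = q_alt * (1 - epsilon) + (1 - q_alt) * epsilon / 3.0
    alt = rng.binomial(depth, p_alt)
    p_other = 2 * epsilon / 3.0
    other = rng.binomial(depth - alt, p_other / (1 - p_alt + 1e-12))
    ref = depth - alt - other
    S, n = geno.shape
    pi, si = np.meshgrid(np.arange(S), np.arange(n), indexing="ij")
    return pd.DataFrame(
        {
            "sample_id": np.array(samples, dtype=object)[si.ravel()],
            "pos": pool.positions[pi.ravel()],
            "ref_count": ref.ravel(),
            "alt_count": alt.ravel(),
            "other_count": other.ravel(),
        }
    )
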