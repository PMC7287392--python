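"""Shared fixtures.

The null p-value matrix is expensive (500 simulated null studies, 999
permutations each) and is shared between the permutation-uniformity
property test and the type-I calibration check, so it is built once per
session.
"""

from __future__ import annotations

import numpy as np
import pytest

from ectoscope.permstats import ModelSpec, permutation_test
from ectoscope.synthetic import (
    DesignSpec,
    EffectModel,
    generate_design,
    simulate_traits,
)

N_NULL_DATASETS = 500
NULL_B = 999
NULL_N_PER_GROUP = 16


@pytest.fixture(scope="session")
def design16():
    return generate_design(DesignSpec(n_per_group=NULL_N_PER_GROUP))


@pytest.fixture(scope="session")
def null_pvalues(design16):
    """(500, 14) permutation p-values from all-null simulated studies.

    Traits have fish-level and residual variance but no treatment effects,
    so every term's p-value should be (approximately) uniform.
    """
    model = EffectModel(baseline=1.0, noise_sd=1.0, within_fish_sd=0.5)
    rng = np.random.default_rng(20260901)
    pvals = np.empty((N_NULL_DATASETS, 14))
    terms = None
    for i in range(N_NULL_DATASETS):
        d = design16.copy()
        d["y"] = simulate_traits(d, model, rng)
        res = permutation_test(
            d,
            ModelSpec(
                response="y",
                n_permutations=NULL_B,
                seed=int(rng.integers(2**31)),
            ),
        )
        if terms is None:
            terms = res.table["term"].tolist()
        pvals[i] = res.table["p_perm"].to_numpy()
    return terms, pvals
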