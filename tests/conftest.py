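"""Shared fixtures: small phantom specs and cached volume loaders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neuroage.phantom import PhantomSpec, generate_phantom
from neuroage.preprocess import crop_pad, zscore_nonzero


@pytest.fixture(scope="session")
def spec32() -> PhantomSpec:
    """Default-condition phantom spec on a 32^3 grid."""
    return PhantomSpec(grid_dims=(32, 32, 32))


@pytest.fixture(scope="session")
def spec32_clean() -> PhantomSpec:
    """Noise-free phantom spec on a 32^3 grid."""
    return PhantomSpec(grid_dims=(32, 32, 32), noise_sd=0.0)


def make_cohort_frame(n: int, seed: int, sites=("siteA",) * 9 + ("siteB",),
                      age_range=(5.0, 95.0)) -> pd.DataFrame:
    """Metadata-only cohort with per-row generation seeds."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, size=n)
    return pd.DataFrame(
        {
            "subject_id": [f"s{seed}-{i:03d}" for i in range(n)],
            "age": ages,
            "site": [sites[i % len(sites)] for i in range(n)],
            "gen_seed": [seed * 100000 + i for i in range(n)],
        }
    )


class PhantomLoader:
    """Row -> (preprocessed volume, age), memoized across a test."""

    def __init__(self, spec: PhantomSpec, target_dims):
        self.spec = spec
        self.target_dims = tuple(target_dims)
        self._cache: dict = {}

    def __call__(self, row):
        key = (row.age, row.gen_seed)
        if key not in self._cache:
            vol = generate_phantom(
                row.age, site=row.site, seed=row.gen_seed, spec=self.spec
            ).data
            self._cache[key] = crop_pad(
                zscore_nonzero(vol), self.target_dims
            ).astype(np.float32)
        return self._cache[key], row.age
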