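import numpy as np
import pytest

from craniomorph import (Dataset, SpecimenRecord, default_scheme,
                         make_template)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def template(scheme):
    return make_template(scheme=scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def build_dataset(scheme, coords_list, groups=None, sexes=None, ids=None):
    """Assemble a Dataset from raw (k, 3) arrays with defaulted metadata."""
    n = len(coords_list)
    groups = groups or ["EUP"] * n
    sexes = sexes or ["M"] * n
    ids = ids or [f"s{i}" for i in range(n)]
    recs = [SpecimenRecord(i, g, s, c)
            for i, g, s, c in zip(ids, groups, sexes, coords_list)]
    return Dataset(scheme, recs)


@pytest.fixture(scope="session")
def two_group_dataset(scheme, template):
    """Small two-group dataset with distinct mean shapes, complete."""
    rng = np.random.default_rng(7)
    coords = []
    groups = []
    for g, off_seed in (("EUP", 1), ("LUPswf", 2)):
        off = np.random.default_rng(off_seed).normal(size=template.shape)
        off -= off.mean(axis=0)
        off *= 0.02 / np.linalg.norm(off)
        for _ in range(5):
            noise = rng.normal(scale=0.003, size=template.shape)
            coords.append(1000 * (template + off + noise))
            groups.append(g)
    return build_dataset(scheme, coords, groups=groups,
                         ids=[f"{g}_{i}" for i, g in enumerate(groups)])
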