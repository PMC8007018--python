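import numpy as np
import pytest

from tracheamorph.cohort import STUDY_GROUPS, CohortConfig, generate_cohort
from tracheamorph.geometry import BranchPolar, DiameterSet, PolarParameters


def params_from_means(group: str) -> tuple[PolarParameters, DiameterSet]:
    """Build exact spherical parameters from a group's configured means."""
    m = STUDY_GROUPS[group].mean
    params = PolarParameters(
        trachea=BranchPolar(m["r1"], m["theta1"], m["phi1"]),
        right_bronchus=BranchPolar(m["r2"], m["theta2"], m["phi2"]),
        left_bronchus=BranchPolar(m["r3"], m["theta3"], m["phi3"]),
    )
    return params, DiameterSet(m["d1"], m["d2"], m["d3"])


@pytest.fixture(scope="session")
def children_means():
    return params_from_means("children")


@pytest.fixture(scope="session")
def zero_noise_cohorts():
    """One single-group degenerate cohort per age group: parameter SDs and
    all measurement noise zero, so every patient carries the group means."""
    dists = {g: d.zero_sd() for g, d in STUDY_GROUPS.items()}
    out = {}
    for g in STUDY_GROUPS:
        cfg = CohortConfig(seed=0, group_sizes={g: STUDY_GROUPS[g].n}).noise_free()
        out[g] = generate_cohort(cfg, dists)
    return out


@pytest.fixture(scope="session")
def default_cohort():
    """The default noisy 7/6/7 cohort at a fixed seed."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
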