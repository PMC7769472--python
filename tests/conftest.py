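import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import iskappa as ik

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset_cohort():
    """One deterministic ten-rater cohort from the breast preset."""
    cfg = ik.breast_grading_preset(seed=7)
    return ik.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def preset_profiles(preset_cohort):
    """Eligible-rater profiles per axis for the preset cohort."""
    summary = ik.summarize_cohort(preset_cohort, min_cases=35)
    return {
        axis: ik.profile_raters(preset_cohort, axis, summary.eligible_rater_ids)
        for axis in ik.AXES
    }


@pytest.fixture
def tiny_cases():
    """Three raters, hand-countable scores."""
    rec = ik.CaseRecord
    cases = []
    # rater A: 4 cases, grades 1,1,2,3; B: 3 cases 2,2,3; C: 2 cases, one ungraded
    for i, g in enumerate([1, 1, 2, 3]):
        cases.append(rec(case_id=f"a{i}", rater_id="A", grade=g))
    for i, g in enumerate([2, 2, 3]):
        cases.append(rec(case_id=f"b{i}", rater_id="B", grade=g))
    cases.append(rec(case_id="c0", rater_id="C", grade=1))
    cases.append(rec(case_id="c1", rater_id="C", grade=None))
    return cases


def random_pir(rng: np.random.Generator) -> np.ndarray:
    """A random 3-level rate vector, bounded away from degenerate corners."""
    v = rng.dirichlet([1.0, 1.0, 1.0])
    v = np.clip(v, 1e-6, None)
    return v / v.sum()
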