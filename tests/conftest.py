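
import numpy as np
import pytest

from nihlselect.synthetic_cohort import (
    FREQ_GRID,
    Cohort,
    SimulationParams,
    Worker,
    compute_cne,
    generate_cohort,
)


def make_worker(wid, *, sex="male", age=40.0, exposure_time=10.0,
                leq_8h=85.0, cne=None, smoking="never", drinking="never",
                ht=None, left=None, right=None, pre=None, latent=None,
                flags=None):
    """Build a worker with flat or per-frequency thresholds.

    ``ht`` may be a scalar (applied at every frequency, both ears) or a
    frequency map; ``left``/``right`` override per ear.
    """
    def expand(spec, default=10.0):
        if spec is None:
            return {f: float(default) for f in FREQ_GRID}
        if isinstance(spec, (int, float)):
            return {f: float(spec) for f in FREQ_GRID}
        base = {f: float(default) for f in FREQ_GRID}
        base.update({float(k): float(v) for k, v in spec.items()})
        return base

    base = expand(ht)
    lht = dict(base) if left is None else expand(left)
    rht = dict(base) if right is None else expand(right)
    if cne is None:
        cne = compute_cne(leq_8h, max(exposure_time, 1e-9))
    pre_map = None
    if pre is not None:
        if isinstance(pre, (int, float)):
            pre_map = {f: float(pre) for f in (0.5, 1.0, 2.0, 3.0, 4.0, 6.0)}
        else:
            pre_map = {float(k): float(v) for k, v in pre.items()}
    return Worker(id=str(wid), sex=sex, age=float(age),
                  exposure_time=float(exposure_time), leq_8h=float(leq_8h),
                  cne=float(cne), smoking=smoking, drinking=drinking,
                  ht_left=lht, ht_right=rht, preemployment_ht=pre_map,
                  latent_susceptibility=latent, flags=flags or {})


def make_cohort(workers):
    return Cohort(list(workers))


@pytest.fixture
def worker_factory():
    return make_worker


@pytest.fixture
def cohort_factory():
    return make_cohort


@pytest.fixture(scope="session")
def default_cohort_6000():
    """Default simulation at full scale; shared across tests (read-only)."""
    return generate_cohort(SimulationParams(n_workers=6000, seed=1))


@pytest.fixture(scope="session")
def default_cohort_3000():
    return generate_cohort(SimulationParams(n_workers=3000, seed=5))
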