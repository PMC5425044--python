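import numpy as np
import pytest

from fdsee.smoothing import SmoothCurveSet, fit_curves, make_bspline_basis
from fdsee.synthetic import MeanShape, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structured synthetic cohort at reduced size (45 subjects, T=120)."""
    cfg = SimulationConfig(n_per_group=(20, 25), T=120)
    cohort, truth = simulate_cohort(cfg, seed=11)
    return cohort, truth


@pytest.fixture(scope="session")
def small_curves(small_cohort):
    """Smoothed weight-adjusted curves of the small cohort (K=20)."""
    from fdsee.allometric import weight_adjust

    cohort, truth = small_cohort
    adjusted = weight_adjust(cohort, truth.config.allometric_exponent)
    basis = make_bspline_basis((1, truth.config.T), K=20)
    return fit_curves(adjusted, basis), cohort.groups


def null_config(n_per_group=(10, 10), T=48):
    """Two groups drawn from the identical generator (global null)."""
    shape = MeanShape(baseline=0.128)
    return SimulationConfig(
        n_per_group=n_per_group,
        T=T,
        mean_shapes=(shape, shape),
    )


def random_curveset(seed, n=30, K=12, domain=(1.0, 101.0), scale=1.0):
    """A random smooth curve set: i.i.d. normal B-spline coefficients."""
    rng = np.random.default_rng(seed)
    basis = make_bspline_basis(domain, K)
    coef = scale * rng.standard_normal((n, K))
    return SmoothCurveSet(
        basis=basis, coef=coef, subject_ids=[f"s{i}" for i in range(n)]
    )
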