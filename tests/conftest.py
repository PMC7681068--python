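import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import plasmaclock as pc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec() -> pc.CohortSpec:
    """A quick cohort with plenty of signal for module-level tests."""
    return pc.CohortSpec(
        n_subjects=300, n_analytes=120, frac_informative=0.25, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return pc.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def noisefree_spec() -> pc.CohortSpec:
    return pc.CohortSpec(
        n_subjects=40, n_analytes=15, frac_informative=0.4,
        noise_sd=0.0, sex_effect_sd=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def noisefree_cohort(noisefree_spec):
    return pc.generate_cohort(noisefree_spec)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        candidates = [m * p[order[j]] / (j + 1) for j in range(i, m)]
        q_sorted[i] = min(1.0, min(candidates))
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enet_objective(Zc, yc, b, lam, alpha):
    n = Zc.shape[0]
    resid = yc - Zc @ b
    return (
        0.5 / n * float(resid @ resid)
        + lam * ((1 - alpha) / 2 * float(b @ b) + alpha * float(np.abs(b).sum()))
    )


def kkt_violation(Zc, yc, b, lam, alpha):
    """Max violation of the elastic-net stationarity conditions."""
    n = Zc.shape[0]
    g = Zc.T @ (yc - Zc @ b) / n
    worst = 0.0
    for j in range(len(b)):
        if b[j] != 0:
            worst = max(worst, abs(g[j] - lam * alpha * np.sign(b[j]) - lam * (1 - alpha) * b[j]))
        else:
            worst = max(worst, max(0.0, abs(g[j]) - lam * alpha))
    return worst


def lasso_grid_oracle(Zc, yc, lam, iters=8, half=None, g=11):
    """Exhaustive grid search for the 3-predictor LASSO, iteratively refined."""
    assert Zc.shape[1] == 3
    ols = np.linalg.lstsq(Zc, yc, rcond=None)[0]
    if half is None:
        half = 2 * float(np.abs(ols).max()) + 1.0
    center = np.zeros(3)
    for _ in range(iters):
        grids = [np.linspace(c - half, c + half, g) for c in center]
        best_b, best_v = None, np.inf
        for b0 in grids[0]:
            for b1 in grids[1]:
                for b2 in grids[2]:
                    b = np.array([b0, b1, b2])
                    v = enet_objective(Zc, yc, b, lam, 1.0)
                    if v < best_v:
                        best_v, best_b = v, b
        center = best_b
        half = 2.2 * half / (g - 1)
    return center
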