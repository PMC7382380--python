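import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import nuetrace as nt

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_ds() -> nt.Dataset:
    return nt.fixture_small()


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulation shared across tests."""
    cfg = nt.SyntheticConfig()
    return nt.simulate(cfg, seed=123)


@pytest.fixture(scope="session")
def zero_noise_sim():
    cfg = nt.SyntheticConfig.zero_noise()
    return nt.simulate(cfg, seed=5)


def make_plant_frame(
    dw=(230.0, 1590.0, 840.0),
    qty_n=(1.0, 5.0, 4.0),
    e_pct=(1.0, 1.0, 1.0),
    a15_control=0.3660,
    plant_id="p1",
) -> pd.DataFrame:
    """Three-organ frame with prescribed DW, N pools and enrichments."""
    rows = []
    for organ, d, q, e in zip(nt.datasets.ORGANS, dw, qty_n, e_pct):
        n_pct = 100.0 * q / d if d > 0 else 0.0
        rows.append(
            {
                "plant_id": plant_id,
                "genotype": "g1",
                "condition": "control",
                "experiment": "1",
                "organ": organ,
                "dw_mg": d,
                "n_pct": n_pct,
                "c_pct": 42.0,
                "a15_pct": a15_control + e,
            }
        )
    return pd.DataFrame(rows)


def grid_tls_slope(x, y, coarse=2000):
    """Independent TLS oracle: scan line angle, refine, return slope.

    For a direction angle theta the orthogonal SSE (with the optimal
    offset, the mean projection onto the normal) is computed directly;
    the coarse minimum is refined with a bounded scalar minimizer.
    """
    from scipy.optimize import minimize_scalar

    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def sse(theta):
        nx, ny = -np.sin(theta), np.cos(theta)
        proj = x * nx + y * ny
        return float(((proj - proj.mean()) ** 2).sum())

    thetas = np.linspace(0.0, np.pi, coarse, endpoint=False)
    vals = [sse(t) for t in thetas]
    i = int(np.argmin(vals))
    lo, hi = thetas[max(i - 1, 0)], thetas[min(i + 1, coarse - 1)]
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    theta = res.x
    return float(np.tan(theta))
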