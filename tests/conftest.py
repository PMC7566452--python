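import math

import numpy as np
import pytest

from tlstree.synthetic import (
    BranchWhorl,
    FluteHarmonic,
    SyntheticTreeSpec,
    generate_tree,
)

# ---------------------------------------------------------------------------
# independent oracles (never routed through the implementation under test)


def shoelace_area(poly: np.ndarray) -> float:
    """Polygon area by the shoelace formula; (N, 2) vertices, open ring."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def circle_loss(pts: np.ndarray, cx: float, cy: float, r: float) -> float:
    """Geometric circle objective sum((d_i - r)^2)."""
    d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    return float(np.sum((d - r) ** 2))


def circle_oracle(pts: np.ndarray) -> tuple[float, float, float]:
    """Independent geometric circle fit: Nelder-Mead from a grid of starts.

    Deliberately avoids the package's Taubin + Levenberg-Marquardt path.
    """
    from scipy.optimize import minimize

    cx0, cy0 = pts.mean(axis=0)
    r0 = float(np.mean(np.hypot(pts[:, 0] - cx0, pts[:, 1] - cy0)))
    best = None
    for dx in (-0.3, 0.0, 0.3):
        for dy in (-0.3, 0.0, 0.3):
            res = minimize(
                lambda p: circle_loss(pts, *p),
                x0=[cx0 + dx * r0, cy0 + dy * r0, r0],
                method="Nelder-Mead",
                options=dict(xatol=1e-12, fatol=1e-14, maxiter=20000),
            )
            if best is None or res.fun < best.fun:
                best = res
    return tuple(best.x)


def ols_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple-regression oracle via statsmodels."""
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1]), float(model.params[0]), float(model.rsquared)


# ---------------------------------------------------------------------------
# fixture trees (kept small; geometry chosen to exercise each feature)


@pytest.fixture(scope="session")
def cylinder_tree():
    """Noise-free constant-radius stem: closed-form volume pi r^2 H."""
    spec = SyntheticTreeSpec(
        height_m=10.0, base_radius_m=0.5, taper_exponent=0.0,
        point_spacing_m=0.04, seed=101,
    )
    return spec, *generate_tree(spec)


@pytest.fixture(scope="session")
def cone_tree():
    spec = SyntheticTreeSpec(
        height_m=10.0, base_radius_m=1.0, taper_exponent=1.0,
        point_spacing_m=0.04, seed=102,
    )
    return spec, *generate_tree(spec)


@pytest.fixture(scope="session")
def circular_tree():
    """Noise-free gently tapered circular stem for DBH/fDBH agreement."""
    spec = SyntheticTreeSpec(
        height_m=40.0, base_radius_m=1.75, taper_exponent=0.85,
        point_spacing_m=0.02, seed=103,
    )
    return spec, *generate_tree(spec)


@pytest.fixture(scope="session")
def fluted_tree():
    """Single k=5 harmonic at 8% amplitude (the canonical fluted fixture)."""
    spec = SyntheticTreeSpec(
        height_m=40.0, base_radius_m=1.0, taper_exponent=0.85,
        flutes=(FluteHarmonic(k=5, amplitude=0.08, phase=0.0),),
        point_spacing_m=0.02, noise_sigma_m=0.003, seed=104,
    )
    return spec, *generate_tree(spec)


@pytest.fixture(scope="session")
def whorled_tree():
    """Three whorls of four branches on a tapered trunk."""
    whorls = tuple(
        BranchWhorl(attachment_height_m=h, count=4, branch_radius_m=0.08,
                    branch_length_m=2.5, insertion_angle_deg=75.0)
        for h in (6.0, 10.0, 14.0)
    )
    spec = SyntheticTreeSpec(
        height_m=20.0, base_radius_m=0.5, taper_exponent=0.8,
        whorls=whorls, point_spacing_m=0.03, seed=105,
    )
    return spec, *generate_tree(spec)
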