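"""Two-state equilibrium binding and fluorescence-anisotropy titration fits.

A labeled species A at fixed total concentration c_A is titrated with B at
total concentration c_B.  Mass action with dissociation constant K_D gives
the complex concentration as the smaller root of

    c_AB = ((c_A + c_B + K_D) - sqrt((c_A + c_B + K_D)^2 - 4 c_A c_B)) / 2

and the observed anisotropy is the population-weighted mixture of the free
and bound anisotropies:

    r_obs = r_A (c_A - c_AB)/c_A + r_AB c_AB/c_A.

``fit_titration`` estimates (K_D, r_A, r_AB) by nonlinear least squares and
reports the SEM of each parameter from the covariance at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TitrationCurve",
    "BindingFit",
    "SaltSeriesSummary",
    "NonIdentifiableError",
    "complex_concentration",
    "predicted_anisotropy",
    "fit_titration",
    "salt_series_summary",
    "tetramer_concentration",
]


class NonIdentifiableError(ValueError):
    """Raised when a titration curve carries no usable anisotropy change."""


@dataclass(frozen=True)
class TitrationCurve:
    """Anisotropy titration data: r_obs versus total titrant concentration.

    Concentrations are molar.  ``metadata`` carries condition labels such as
    salt or competitor concentration.
    """

    c_a: float
    titrant_concentrations: np.ndarray
    observed_anisotropy: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c_b = np.asarray(self.titrant_concentrations, dtype=float)
        r = np.asarray(self.observed_anisotropy, dtype=float)
        if self.c_a <= 0:
            raise ValueError("c_a must be positive")
        if c_b.ndim != 1 or c_b.shape != r.shape or c_b.size < 4:
            raise ValueError("need matching 1-D arrays with at least 4 points")
        if (c_b < 0).any() or (np.diff(c_b) <= 0).any():
            raise ValueError("titrant concentrations must be non-negative and strictly increasing")
        if not np.isfinite(r).all():
            raise ValueError("anisotropy values must be finite")
        object.__setattr__(self, "titrant_concentrations", c_b)
        object.__setattr__(self, "observed_anisotropy", r)


@dataclass(frozen=True)
class BindingFit:
    """Fitted two-state binding parameters with SEMs from the fit covariance."""

    k_d: float
    k_d_sem: float
    r_a: float
    r_a_sem: float
    r_ab: float
    r_ab_sem: float
    residuals: np.ndarray
    rss: float
    converged: bool
    n_points: int

    def predicted(self, curve: TitrationCurve) -> np.ndarray:
        return predicted_anisotropy(
            curve.c_a, curve.titrant_concentrations, self.k_d, self.r_a, self.r_ab
        )


def complex_concentration(c_a, c_b, k_d):
    """Equilibrium complex concentration c_AB (molar) from total c_A, c_B, K_D.

    Smaller root of the mass-action quadratic, computed in the
    cancellation-free form 2 c_A c_B / (s + sqrt(s^2 - 4 c_A c_B)) with
    s = c_A + c_B + K_D, which stays accurate when 4 c_A c_B << s^2.
    Accepts scalars or arrays; K_D = 0 is handled as the stoichiometric
    limit min(c_A, c_B).
    """
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    k_d = np.asarray(k_d, dtype=float)
    if (c_a < 0).any() or (c_b < 0).any() or (k_d < 0).any():
        raise ValueError("concentrations and K_D must be non-negative")
    s = c_a + c_b + k_d
    disc = np.maximum(s * s - 4.0 * c_a * c_b, 0.0)
    denom = s + np.sqrt(disc)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_ab = np.where(denom > 0, 2.0 * c_a * c_b / np.where(denom > 0, denom, 1.0), 0.0)
    c_ab = np.minimum(c_ab, np.minimum(c_a, c_b))
    if c_ab.ndim == 0:
        return float(c_ab)
    return c_ab


def predicted_anisotropy(c_a, c_b, k_d, r_a, r_ab):
    """Observed anisotropy as the free/bound population mixture.

    r_obs = r_A (c_A - c_AB)/c_A + r_AB c_AB/c_A; bounded between r_A and
    r_AB and monotone in c_B.
    """
    if np.any(np.asarray(c_a, dtype=float) <= 0):
        raise ValueError("c_a must be positive")
    c_ab = complex_concentration(c_a, c_b, k_d)
    frac_bound = c_ab / c_a
    return r_a * (1.0 - frac_bound) + r_ab * frac_bound


def _default_initial_guesses(curve: TitrationCurve) -> tuple[float, float, float]:
    r = curve.observed_anisotropy
    c_b = curve.titrant_concentrations
    r_a0, r_ab0 = float(r[0]), float(r[-1])
    half = 0.5 * (r_a0 + r_ab0)
    # titrant concentration nearest the half-change point
    idx = int(np.argmin(np.abs(r - half)))
    k_d0 = float(c_b[idx]) if c_b[idx] > 0 else float(np.median(c_b[c_b > 0]))
    return k_d0, r_a0, r_ab0


def fit_titration(
    curve: TitrationCurve,
    initial_guesses: tuple[float, float, float] | None = None,
    weights: np.ndarray | None = None,
    min_anisotropy_range: float = 1e-3,
) -> BindingFit:
    """Nonlinear least-squares fit of (K_D, r_A, r_AB) to a titration curve.

    Unit weights by default; per-point standard deviations may be supplied
    (residuals are then divided by them).  Parameter SEMs come from the
    scaled covariance at the optimum.  A curve whose anisotropy range is
    below ``min_anisotropy_range`` is rejected as non-identifiable.
    """
    r = curve.observed_anisotropy
    c_b = curve.titrant_concentrations
    if float(np.ptp(r)) < min_anisotropy_range:
        raise NonIdentifiableError(
            f"anisotropy range {np.ptp(r):.2e} below floor {min_anisotropy_range:.2e}; "
            "no binding transition to fit"
        )
    if initial_guesses is None:
        initial_guesses = _default_initial_guesses(curve)
    k_d0, r_a0, r_ab0 = initial_guesses
    sigma = np.ones_like(r) if weights is None else np.asarray(weights, dtype=float)

    def residual(theta: np.ndarray) -> np.ndarray:
        k_d, r_a, r_ab = theta
        return (predicted_anisotropy(curve.c_a, c_b, k_d, r_a, r_ab) - r) / sigma

    tiny = 1e-30
    res = optimize.least_squares(
        residual,
        x0=[max(k_d0, tiny), r_a0, r_ab0],
        bounds=([tiny, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        x_scale=[max(k_d0, tiny), 1.0, 1.0],
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    k_d, r_a, r_ab = res.x
    resid = residual(res.x) * sigma
    rss = float(np.sum((residual(res.x)) ** 2))
    dof = max(r.size - 3, 1)
    # scaled covariance: (J^T J)^-1 * s^2, the standard NLS SEM
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * (rss / dof)
        sems = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sems = np.full(3, np.nan)
    return BindingFit(
        k_d=float(k_d),
        k_d_sem=float(sems[0]),
        r_a=float(r_a),
        r_a_sem=float(sems[1]),
        r_ab=float(r_ab),
        r_ab_sem=float(sems[2]),
        residuals=resid,
        rss=rss,
        converged=bool(res.success),
        n_points=int(r.size),
    )


def tetramer_concentration(monomer_concentration):
    """Convert a monomer concentration to the tetramer concentration (/4).

    Tetrameric p53 constructs are titrated on a per-tetramer basis.
    """
    return np.asarray(monomer_concentration, dtype=float) / 4.0


@dataclass(frozen=True)
class SaltSeriesSummary:
    """K_D versus salt with the log10-log10 slope of a simple linear fit."""

    salt_concentrations: np.ndarray
    k_d_values: np.ndarray
    slope: float
    slope_sem: float
    intercept: float

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"salt": self.salt_concentrations, "k_d": self.k_d_values}
        )


def salt_series_summary(fits) -> SaltSeriesSummary:
    """Descriptive summary of the salt dependence of K_D.

    ``fits`` is a sequence of (salt_concentration, BindingFit-or-K_D) pairs.
    Reports the slope of log10(K_D) against log10(salt) with its SEM from an
    ordinary linear regression; purely descriptive, no mechanistic model.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 salt points")
    salt = np.array([s for s, _ in fits], dtype=float)
    k_d = np.array(
        [f.k_d if isinstance(f, BindingFit) else float(f) for _, f in fits]
    )
    if (salt <= 0).any() or (k_d <= 0).any():
        raise ValueError("salt concentrations and K_D values must be positive")
    reg = stats.linregress(np.log10(salt), np.log10(k_d))
    return SaltSeriesSummary(
        salt_concentrations=salt,
        k_d_values=k_d,
        slope=float(reg.slope),
        slope_sem=float(reg.stderr) if np.isfinite(reg.stderr) else 0.0,
        intercept=float(reg.intercept),
    )
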