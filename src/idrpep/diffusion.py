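"""Single-molecule 1D sliding analysis along DNA.

Pipeline: position trajectories -> ensemble mean-square displacement (MSD)
and an average diffusion coefficient from its slope (msd = 2 D dt + b in
1D; the intercept b absorbs localization noise) -> pooled displacement
sample at a fixed lag (165 ms in the canonical analysis) -> two-component
Gaussian mixture fit

    P(dx) = sum_i A_i / sqrt(4 pi D_i dt) * exp(-(dx + v_i dt)^2 / (4 D_i dt))

resolving a slow and a fast sliding mode with per-mode drift, with per-bin
histogram uncertainties estimated by bootstrap resampling.

Because flow drift makes the raw MSD superlinear while the mixture model
carries drift explicitly, the MSD is computed on drift-corrected positions
by default (the pooled mean velocity is subtracted); pass
``drift_correction=False`` for the raw estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "Trajectory",
    "MsdCurve",
    "DisplacementSample",
    "DiffusionFit",
    "TwoModeFit",
    "compute_msd",
    "fit_diffusion_coefficient",
    "displacement_sample",
    "bootstrap_histogram_errors",
    "fit_two_mode",
    "two_mode_density",
    "freedman_diaconis_width",
]


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled 1D position time series of one molecule on DNA."""

    id: str
    frame_interval: float  # seconds
    positions: np.ndarray  # micrometers

    def __post_init__(self) -> None:
        x = np.asarray(self.positions, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise ValueError(f"trajectory {self.id!r}: need >= 2 frames")
        if not np.isfinite(x).all():
            raise ValueError(f"trajectory {self.id!r}: non-finite positions")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        object.__setattr__(self, "positions", x)

    @property
    def n_frames(self) -> int:
        return int(self.positions.size)

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


@dataclass(frozen=True)
class MsdCurve:
    """Ensemble-averaged MSD versus lag time (msd[0] = 0 by convention)."""

    lag_times: np.ndarray  # seconds, strictly increasing, starts at 0
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray  # displacement pairs contributing per lag
    sem: np.ndarray  # across-trajectory SEM per lag


@dataclass(frozen=True)
class DisplacementSample:
    """Pooled displacements x(t+dt) - x(t) at one fixed lag."""

    lag: float  # seconds
    displacements: np.ndarray  # um
    source_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return int(self.displacements.size)


@dataclass(frozen=True)
class DiffusionFit:
    """Average diffusion coefficient from the MSD slope (msd = 2 D dt + b)."""

    d: float  # um^2/s
    d_sem: float
    intercept: float  # um^2, retained localization-noise offset
    intercept_sem: float
    negative_slope: bool


@dataclass(frozen=True)
class TwoModeFit:
    """Two-Gaussian displacement-mixture fit; mode 0 is slow (D_1 <= D_2).

    ``amplitudes`` integrate to the total density (A_1 + A_2 ~ 1 for a
    density-normalized histogram); ``fraction_fast`` = A_2/(A_1+A_2).
    """

    amplitudes: np.ndarray
    drifts: np.ndarray  # um/s, sign per the model mean -v_i * dt
    diffusion_coefficients: np.ndarray  # um^2/s
    amplitude_sems: np.ndarray
    drift_sems: np.ndarray
    diffusion_sems: np.ndarray
    lag: float
    rss: float
    single_mode_rss: float
    converged: bool
    degenerate: bool
    bin_edges: np.ndarray = field(repr=False)
    bin_density: np.ndarray = field(repr=False)
    bin_sigma: np.ndarray = field(repr=False)

    @property
    def fraction_fast(self) -> float:
        a = self.amplitudes
        return float(a[1] / (a[0] + a[1]))

    def density(self, dx) -> np.ndarray:
        return two_mode_density(
            dx, self.lag, self.amplitudes, self.drifts, self.diffusion_coefficients
        )


def _check_uniform_interval(trajectories) -> float:
    dts = {t.frame_interval for t in trajectories}
    if len(dts) != 1:
        raise ValueError(f"trajectories have mixed frame intervals: {sorted(dts)}")
    return dts.pop()


def _pooled_velocity(trajectories) -> float:
    """Mean drift velocity pooled over all one-frame displacements."""
    total_disp = sum(float(t.positions[-1] - t.positions[0]) for t in trajectories)
    total_time = sum(t.duration for t in trajectories)
    return total_disp / total_time if total_time > 0 else 0.0


def compute_msd(
    trajectories,
    max_lag: float,
    drift_correction: bool = True,
) -> MsdCurve:
    """Time-averaged MSD per trajectory, then ensemble average across them.

    At each lag of m frames every overlapping pair (x[t+m] - x[t])^2 in a
    trajectory contributes; the ensemble mean weights trajectories by their
    pair counts, and the SEM is taken across trajectories.  With
    ``drift_correction`` (default) the pooled mean velocity is subtracted
    from the positions first.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("no trajectories supplied")
    dt = _check_uniform_interval(trajectories)
    if max_lag < dt:
        raise ValueError(f"max_lag {max_lag} shorter than one frame ({dt} s)")
    max_steps = int(np.floor(max_lag / dt + 1e-9))
    max_steps = min(max_steps, max(t.n_frames for t in trajectories) - 1)
    if max_steps < 1:
        raise ValueError("no trajectory long enough for the requested lag")

    v = _pooled_velocity(trajectories) if drift_correction else 0.0
    positions = []
    for t in trajectories:
        x = t.positions - v * dt * np.arange(t.n_frames)
        positions.append(x)

    lags = np.arange(max_steps + 1) * dt
    msd = np.zeros(max_steps + 1)
    n_pairs = np.zeros(max_steps + 1, dtype=int)
    sem = np.zeros(max_steps + 1)
    n_pairs[0] = sum(t.n_frames for t in trajectories)
    for m in range(1, max_steps + 1):
        per_traj = []
        weights = []
        for x in positions:
            if x.size > m:
                d2 = (x[m:] - x[:-m]) ** 2
                per_traj.append(float(d2.mean()))
                weights.append(d2.size)
        if not per_traj:
            lags = lags[:m]
            msd = msd[:m]
            n_pairs = n_pairs[:m]
            sem = sem[:m]
            break
        per_traj = np.asarray(per_traj)
        weights = np.asarray(weights, dtype=float)
        msd[m] = float(np.average(per_traj, weights=weights))
        n_pairs[m] = int(weights.sum())
        if per_traj.size > 1:
            sem[m] = float(per_traj.std(ddof=1) / np.sqrt(per_traj.size))
    return MsdCurve(lag_times=lags, msd=msd, n_pairs=n_pairs, sem=sem)


def fit_diffusion_coefficient(
    msd: MsdCurve,
    fit_lag_range: tuple[float, float] | None = None,
) -> DiffusionFit:
    """Weighted linear fit msd = 2 D dt + b; D = slope / 2 (1D convention).

    The intercept is retained (localization-noise offset), never forced
    through zero.  Lags are weighted by 1/SEM^2 where SEMs are available,
    otherwise the fit is unweighted.  A negative fitted slope sets the
    ``negative_slope`` flag and D is reported as-is.

    Errors of a time-averaged ensemble MSD are strongly correlated across
    lags (neighboring lags share the same displacement pairs), so the
    naive independent-error covariance badly understates the uncertainty
    of the slope.  When per-lag SEMs are available the SEM of D is instead
    propagated under a fully-correlated error model: the lag-dependent
    part of sem(dt) is what an ensemble-wide fluctuation contributes to
    the slope, so SEM_D = |d sem / d dt| / 2 from a linear fit of sem
    against lag.  Without SEMs (single trajectory) the residual-scaled
    ordinary covariance is used.
    """
    mask = msd.lag_times > 0
    if fit_lag_range is not None:
        lo, hi = fit_lag_range
        mask &= (msd.lag_times >= lo) & (msd.lag_times <= hi)
    t = msd.lag_times[mask]
    y = msd.msd[mask]
    s = msd.sem[mask]
    if t.size < 2:
        raise ValueError("need at least 2 lags in the fit range")
    have_sems = bool((s > 0).all())
    w = 1.0 / s**2 if have_sems else np.ones_like(t)
    X = np.column_stack([t, np.ones_like(t)])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ y)
    resid = y - X @ beta
    slope, intercept = beta
    if have_sems:
        # fully-correlated error model: a common ensemble fluctuation scales
        # the per-lag SEM profile, so its slope/intercept bound the fit error
        gamma = np.linalg.solve(xtwx, X.T @ W @ s)
        slope_sem, intercept_sem = np.abs(gamma)
    else:
        dof = max(t.size - 2, 1)
        scale = float(resid @ W @ resid) / dof
        cov = np.linalg.inv(xtwx) * scale
        slope_sem = float(np.sqrt(max(cov[0, 0], 0.0)))
        intercept_sem = float(np.sqrt(max(cov[1, 1], 0.0)))
    return DiffusionFit(
        d=float(slope / 2.0),
        d_sem=float(slope_sem) / 2.0,
        intercept=float(intercept),
        intercept_sem=float(intercept_sem),
        negative_slope=bool(slope < 0),
    )


def displacement_sample(trajectories, lag: float) -> DisplacementSample:
    """Pool all overlapping-window displacements at a fixed lag.

    The lag must be an integer multiple of the frame interval; otherwise
    the error message suggests the nearest commensurate lag.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("no trajectories supplied")
    dt = _check_uniform_interval(trajectories)
    steps = lag / dt
    m = int(round(steps))
    if m < 1 or abs(steps - m) > 1e-6:
        nearest = max(int(round(steps)), 1) * dt
        raise ValueError(
            f"lag {lag} s is not a multiple of the frame interval {dt} s; "
            f"nearest valid lag is {nearest:.6g} s"
        )
    chunks = []
    ids = []
    for t in trajectories:
        if t.n_frames > m:
            chunks.append(t.positions[m:] - t.positions[:-m])
            ids.append(t.id)
    if not chunks:
        raise ValueError("no trajectory long enough for the requested lag")
    return DisplacementSample(
        lag=m * dt, displacements=np.concatenate(chunks), source_ids=tuple(ids)
    )


def bootstrap_histogram_errors(
    sample: DisplacementSample,
    bins: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> np.ndarray:
    """Per-bin SEM of the density histogram by bootstrap resampling.

    Displacements are resampled with replacement ``n_boot`` times and the
    per-bin standard deviation of the density histogram across resamples is
    returned.  Deterministic given the seed.
    """
    if sample.n == 0:
        raise ValueError("empty displacement sample")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    dx = sample.displacements
    densities = np.empty((n_boot, len(bins) - 1))
    for b in range(n_boot):
        resampled = rng.choice(dx, size=dx.size, replace=True)
        densities[b], _ = np.histogram(resampled, bins=bins, density=True)
    return densities.std(axis=0, ddof=1)


def two_mode_density(dx, lag, amplitudes, drifts, diffusion_coefficients):
    """Mixture density sum_i A_i N(-v_i dt, 2 D_i dt) evaluated at dx."""
    dx = np.asarray(dx, dtype=float)
    out = np.zeros_like(dx)
    for a, v, d in zip(amplitudes, drifts, diffusion_coefficients):
        var = 4.0 * d * lag
        out = out + a / np.sqrt(np.pi * var) * np.exp(-((dx + v * lag) ** 2) / var)
    return out


def freedman_diaconis_width(data: np.ndarray) -> float:
    """Freedman-Diaconis histogram bin width, with a fallback for flat data."""
    data = np.asarray(data, dtype=float)
    iqr = float(np.subtract(*np.percentile(data, [75, 25])))
    if iqr <= 0:
        iqr = float(data.std()) or 1.0
    return 2.0 * iqr / data.size ** (1.0 / 3.0)


def _symmetric_bins(dx: np.ndarray, width: float) -> np.ndarray:
    half = int(np.ceil((np.abs(dx).max() + width) / width))
    return width * np.arange(-half, half + 1)


def _mixture_lsq(dx_centers, density, sigma, lag, n_components, x0, bounds):
    def residual(theta):
        a = theta[0::3]
        v = theta[1::3]
        d = theta[2::3]
        return (two_mode_density(dx_centers, lag, a, v, d) - density) / sigma

    return optimize.least_squares(residual, x0=x0, bounds=bounds, xtol=1e-12, ftol=1e-12)


def fit_two_mode(
    sample: DisplacementSample,
    bin_width: float | None = None,
    n_components: int = 2,
    n_boot: int = 1000,
    seed: int | None = 0,
    min_sample_size: int = 100,
) -> TwoModeFit:
    """Fit the displacement histogram with a two-Gaussian sliding-mode mixture.

    The density-normalized histogram (bin edges symmetric about zero;
    Freedman-Diaconis width unless overridden) is fitted by weighted least
    squares with per-bin bootstrap SEMs as weights.  Amplitudes are bounded
    at >= 0 and diffusion coefficients at > 0; modes are relabeled so
    D_1 <= D_2 (slow, fast).  A single-Gaussian fit is also computed and its
    residual sum stored for a degeneracy diagnostic; if the two fitted D
    agree within their combined SEM the ``degenerate`` flag is set.
    """
    if sample.n < min_sample_size:
        raise ValueError(
            f"only {sample.n} displacements; need >= {min_sample_size} for a "
            "stable mixture fit"
        )
    if n_components != 2:
        raise ValueError("only the two-component mixture is supported")
    dx = sample.displacements
    lag = sample.lag
    width = bin_width if bin_width is not None else freedman_diaconis_width(dx)
    edges = _symmetric_bins(dx, width)
    density, _ = np.histogram(dx, bins=edges, density=True)
    sigma = bootstrap_histogram_errors(sample, edges, n_boot=n_boot, seed=seed)
    positive = sigma[sigma > 0]
    floor = positive.min() if positive.size else 1.0
    sigma = np.where(sigma > 0, sigma, floor)
    centers = 0.5 * (edges[:-1] + edges[1:])

    var = float(dx.var())
    d_bar = max(var / (2.0 * lag), 1e-12)
    v0 = -float(dx.mean()) / lag
    tiny = 1e-12
    x0 = np.array([0.5, v0, d_bar / 5.0, 0.5, v0, 2.0 * d_bar])
    lb = [0.0, -np.inf, tiny] * 2
    ub = [np.inf, np.inf, np.inf] * 2
    res = _mixture_lsq(centers, density, sigma, lag, 2, x0, (lb, ub))

    theta = res.x
    rss = float(np.sum(res.fun**2))
    dof = max(centers.size - theta.size, 1)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * (rss / dof)
        sems = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sems = np.full(theta.size, np.nan)

    # single-component comparison fit for the degeneracy diagnostic
    res1 = _mixture_lsq(
        centers, density, sigma, lag, 1,
        np.array([1.0, v0, d_bar]),
        ([0.0, -np.inf, tiny], [np.inf, np.inf, np.inf]),
    )
    single_rss = float(np.sum(res1.fun**2))

    a = theta[0::3]
    v = theta[1::3]
    d = theta[2::3]
    a_sem, v_sem, d_sem = sems[0::3], sems[1::3], sems[2::3]
    order = np.argsort(d)  # slow mode first
    a, v, d = a[order], v[order], d[order]
    a_sem, v_sem, d_sem = a_sem[order], v_sem[order], d_sem[order]
    degenerate = bool(
        abs(d[1] - d[0]) <= np.sqrt(np.nansum([d_sem[0] ** 2, d_sem[1] ** 2]))
    )
    return TwoModeFit(
        amplitudes=a,
        drifts=v,
        diffusion_coefficients=d,
        amplitude_sems=a_sem,
        drift_sems=v_sem,
        diffusion_sems=d_sem,
        lag=lag,
        rss=rss,
        single_mode_rss=single_rss,
        converged=bool(res.success),
        degenerate=degenerate,
        bin_edges=edges,
        bin_density=density,
        bin_sigma=sigma,
    )
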