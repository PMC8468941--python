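"""Hybrid growth-curve fitting and pointwise confidence/prediction bands.

The mean model for a volumetric measure as a function of age is

    f(age; b) = b4 * (1 - exp(-age / b5)) + b0 + b1*age + b2*age**2 + b3*age**3

a saturating early-growth term plus a cubic polynomial. Fitting is bounded
nonlinear least squares with a multi-start over the saturation time-scale
``b5``; uncertainty is propagated either by the first-order delta method or by
parametric Monte Carlo over the parameter covariance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import (
    ConvergenceError,
    DomainError,
    InsufficientDataError,
    NonIdentifiabilityError,
    PropagationError,
    StateError,
)

#: Measures the pipeline models, in canonical order.
MEASURES = ("GMV", "WMV", "TIV", "GMV_over_TIV", "WMV_over_TIV")

N_PARAMS = 6

_SEXES = ("male", "female", "unknown")

#: Source-dataset labels of the default full-term reference pool.
DEFAULT_DATASETS = ("C-MIND", "NDAR-NIHPD", "ICBM", "IXI")


@dataclass(frozen=True)
class IndividualScan:
    """One full-term reference subject (scalar volumes only, no images)."""

    subject_id: str
    dataset: str
    age_years: float
    sex: str
    tiv_cm3: float
    gmv_cm3: float
    wmv_cm3: float

    def validate(self) -> None:
        if not 0 < self.age_years < 120:
            raise DomainError(f"age_years must be in (0, 120), got {self.age_years}")
        if self.sex not in _SEXES:
            raise DomainError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        for name in ("tiv_cm3", "gmv_cm3", "wmv_cm3"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.gmv_cm3 + self.wmv_cm3 < self.tiv_cm3:
            raise DomainError(
                f"gmv + wmv must be < tiv ({self.gmv_cm3} + {self.wmv_cm3} "
                f"vs {self.tiv_cm3}) for subject {self.subject_id}"
            )


@dataclass(frozen=True)
class FitSettings:
    """Multi-start and constraint configuration for :func:`fit_hybrid`.

    ``fixed`` maps parameter indices (0..5) to frozen values; frozen
    parameters are excluded from optimisation, covariance, and the residual
    degrees of freedom.
    """

    beta5_starts: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    beta5_bounds: tuple[float, float] = (1e-3, 50.0)
    beta4_init_scale: float = 0.25
    fixed: Optional[Mapping[int, float]] = None
    max_nfev: int = 2000
    cond_limit: float = 1e14

    def fixed_map(self) -> dict[int, float]:
        fixed = dict(self.fixed or {})
        for index in fixed:
            if index not in range(N_PARAMS):
                raise DomainError(f"fixed parameter index out of range: {index}")
        if 5 in fixed and not fixed[5] > 0:
            raise DomainError("fixed beta5 must be > 0")
        return fixed


@dataclass
class GrowthFit:
    """A fitted hybrid model for one measure."""

    measure: str
    beta: np.ndarray            # shape (6,)
    sigma: float                # residual SD, measure units
    n_obs: int
    param_cov: np.ndarray       # shape (6, 6); zero rows/cols for fixed params
    sse: float
    converged: bool
    n_starts_tried: int
    df: int                     # n_obs - number of free parameters

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "beta": [float(b) for b in self.beta],
            "sigma": float(self.sigma),
            "n_obs": int(self.n_obs),
            "param_cov": [[float(v) for v in row] for row in self.param_cov],
            "sse": float(self.sse),
            "converged": bool(self.converged),
            "n_starts_tried": int(self.n_starts_tried),
            "df": int(self.df),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GrowthFit":
        return cls(
            measure=str(payload["measure"]),
            beta=np.asarray(payload["beta"], dtype=float),
            sigma=float(payload["sigma"]),
            n_obs=int(payload["n_obs"]),
            param_cov=np.asarray(payload["param_cov"], dtype=float),
            sse=float(payload["sse"]),
            converged=bool(payload["converged"]),
            n_starts_tried=int(payload["n_starts_tried"]),
            df=int(payload["df"]),
        )


@dataclass
class IntervalBand:
    """Pointwise mean curve with confidence and prediction bounds on an age grid."""

    measure: str
    level: float
    ages: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    pi_lo: np.ndarray
    pi_hi: np.ndarray
    method: str = "delta"

    def validate(self) -> None:
        if not 0 < self.level < 1:
            raise DomainError(f"level must be in (0, 1), got {self.level}")
        if np.any(np.diff(self.ages) <= 0):
            raise DomainError("ages must be strictly increasing")
        stacked = np.vstack([self.pi_lo, self.ci_lo, self.mean, self.ci_hi, self.pi_hi])
        if np.any(np.diff(stacked, axis=0) < -1e-9 * (1 + np.abs(self.mean))):
            raise StateError("band ordering pi_lo <= ci_lo <= mean <= ci_hi <= pi_hi violated")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "measure": self.measure,
                "level": self.level,
                "method": self.method,
                "age": self.ages,
                "mean": self.mean,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "pi_lo": self.pi_lo,
                "pi_hi": self.pi_hi,
            }
        )

    @classmethod
    def from_frame(cls, frame) -> "IntervalBand":
        return cls(
            measure=str(frame["measure"].iloc[0]),
            level=float(frame["level"].iloc[0]),
            ages=frame["age"].to_numpy(dtype=float),
            mean=frame["mean"].to_numpy(dtype=float),
            ci_lo=frame["ci_lo"].to_numpy(dtype=float),
            ci_hi=frame["ci_hi"].to_numpy(dtype=float),
            pi_lo=frame["pi_lo"].to_numpy(dtype=float),
            pi_hi=frame["pi_hi"].to_numpy(dtype=float),
            method=str(frame["method"].iloc[0]),
        )


def default_age_grid(start: float = 0.7, stop: float = 30.0, step: float = 0.1) -> np.ndarray:
    """Inclusive age grid; default spans the reference pool's range."""
    n_steps = int(round((stop - start) / step))
    return start + step * np.arange(n_steps + 1)


# ---------------------------------------------------------------------------
# Mean curve and gradient
# ---------------------------------------------------------------------------

def evaluate_hybrid(beta: Sequence[float], age) -> np.ndarray | float:
    """Noise-free mean curve at ``age`` (scalar or array)."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (N_PARAMS,):
        raise DomainError(f"beta must have length {N_PARAMS}")
    if not beta[5] > 0:
        raise DomainError(f"beta5 must be > 0, got {beta[5]}")
    age_arr = np.asarray(age, dtype=float)
    value = (
        beta[4] * (1.0 - np.exp(-age_arr / beta[5]))
        + beta[0]
        + beta[1] * age_arr
        + beta[2] * age_arr**2
        + beta[3] * age_arr**3
    )
    return value if np.ndim(age) else float(value)


def hybrid_gradient(beta: Sequence[float], age) -> np.ndarray:
    """Partial derivatives of the mean curve w.r.t. the six parameters.

    Returns shape ``(6,)`` for scalar ``age`` and ``(len(age), 6)`` otherwise.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (N_PARAMS,):
        raise DomainError(f"beta must have length {N_PARAMS}")
    if not beta[5] > 0:
        raise DomainError(f"beta5 must be > 0, got {beta[5]}")
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    decay = np.exp(-age_arr / beta[5])
    grad = np.column_stack(
        [
            np.ones_like(age_arr),
            age_arr,
            age_arr**2,
            age_arr**3,
            1.0 - decay,
            -beta[4] * (age_arr / beta[5] ** 2) * decay,
        ]
    )
    return grad if np.ndim(age) else grad[0]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def measure_values(scans: Sequence[IndividualScan], measure: str) -> np.ndarray:
    """Per-subject observed values for ``measure`` (ratios computed per subject)."""
    if measure == "GMV":
        return np.array([s.gmv_cm3 for s in scans], dtype=float)
    if measure == "WMV":
        return np.array([s.wmv_cm3 for s in scans], dtype=float)
    if measure == "TIV":
        return np.array([s.tiv_cm3 for s in scans], dtype=float)
    if measure == "GMV_over_TIV":
        return np.array([s.gmv_cm3 / s.tiv_cm3 for s in scans], dtype=float)
    if measure == "WMV_over_TIV":
        return np.array([s.wmv_cm3 / s.tiv_cm3 for s in scans], dtype=float)
    raise DomainError(f"unknown measure {measure!r}; expected one of {MEASURES}")


def _initial_beta(ages: np.ndarray, values: np.ndarray, settings: FitSettings) -> np.ndarray:
    beta = np.zeros(N_PARAMS)
    try:
        # polyfit returns coefficients highest-degree first
        poly = np.polyfit(ages, values, 3)
        beta[0:4] = poly[::-1]
    except np.linalg.LinAlgError:
        beta[0] = float(np.mean(values))
    spread = float(np.max(values) - np.min(values))
    beta[4] = settings.beta4_init_scale * spread if spread > 0 else 1.0
    return beta


def fit_hybrid_xy(
    ages: Sequence[float],
    values: Sequence[float],
    measure: str = "GMV",
    settings: FitSettings = FitSettings(),
) -> GrowthFit:
    """Fit the hybrid model to paired (age, value) arrays.

    Minimizes the residual sum of squares by bounded trust-region least
    squares, multi-started over ``settings.beta5_starts``; the best SSE wins.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.shape != values.shape or ages.ndim != 1:
        raise DomainError("ages and values must be equal-length 1-D arrays")
    fixed = settings.fixed_map()
    free = [i for i in range(N_PARAMS) if i not in fixed]
    n_free = len(free)
    n = ages.size
    if n <= n_free:
        raise InsufficientDataError(
            f"need more than {n_free} observations for {n_free} free parameters, got {n}"
        )
    if np.ptp(ages) == 0:
        raise NonIdentifiabilityError("all ages identical; age effects unidentifiable")

    beta_init = _initial_beta(ages, values, settings)
    for index, value in fixed.items():
        beta_init[index] = value

    lo = np.full(N_PARAMS, -np.inf)
    hi = np.full(N_PARAMS, np.inf)
    lo[5], hi[5] = settings.beta5_bounds

    def full_beta(theta: np.ndarray) -> np.ndarray:
        beta = beta_init.copy()
        beta[free] = theta
        return beta

    def residuals(theta: np.ndarray) -> np.ndarray:
        return values - evaluate_hybrid(full_beta(theta), ages)

    def jacobian(theta: np.ndarray) -> np.ndarray:
        return -hybrid_gradient(full_beta(theta), ages)[:, free]

    def scaled_normal_matrix(beta_hat: np.ndarray):
        """Column-equilibrated J'J so unit scale (1 vs age^3) is not mistaken
        for collinearity. Returns (scaled J'J, column scales) or None when a
        column has exactly zero sensitivity."""
        jac_full = hybrid_gradient(beta_hat, ages)[:, free]
        jtj = jac_full.T @ jac_full
        col_norms = np.sqrt(np.diag(jtj))
        if not np.all(np.isfinite(jtj)) or np.any(col_norms == 0):
            return None
        scale = 1.0 / col_norms
        return jtj * np.outer(scale, scale), scale

    starts = settings.beta5_starts if 5 in free else (beta_init[5] or 1.0,)
    best = None           # best identifiable converged result
    best_normal = None    # its scaled J'J factors
    any_converged = False
    best_any = None       # best result regardless, for diagnostics
    n_tried = 0
    for b5_start in starts:
        theta0 = beta_init[free].copy()
        if 5 in free:
            theta0[free.index(5)] = np.clip(b5_start, *settings.beta5_bounds)
        n_tried += 1
        try:
            result = least_squares(
                residuals,
                theta0,
                jac=jacobian,
                bounds=(lo[free], hi[free]),
                method="trf",
                max_nfev=settings.max_nfev,
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best_any is None or result.cost < best_any.cost:
            best_any = result
        if not result.success:
            continue
        any_converged = True
        if best is not None and result.cost >= best.cost:
            continue
        normal = scaled_normal_matrix(full_beta(result.x))
        if normal is None or np.linalg.cond(normal[0]) > settings.cond_limit:
            continue  # converged but degenerate (e.g. beta5 -> 0 valley)
        best, best_normal = result, normal
    if best is None:
        if any_converged:
            raise NonIdentifiabilityError(
                "every converged start is singular or extremely ill-conditioned; "
                "inspect the age range and consider fixing weakly identified parameters"
            )
        raise ConvergenceError(
            f"no start converged for measure {measure}",
            best_sse=None if best_any is None else float(2 * best_any.cost),
        )

    beta_hat = full_beta(best.x)
    resid = values - evaluate_hybrid(beta_hat, ages)
    sse = float(resid @ resid)
    df = n - n_free
    sigma2 = sse / df
    jtj_scaled, scale = best_normal
    cov_free = sigma2 * (np.linalg.inv(jtj_scaled) * np.outer(scale, scale))
    cov_free = 0.5 * (cov_free + cov_free.T)
    param_cov = np.zeros((N_PARAMS, N_PARAMS))
    param_cov[np.ix_(free, free)] = cov_free
    return GrowthFit(
        measure=measure,
        beta=beta_hat,
        sigma=float(np.sqrt(sigma2)),
        n_obs=n,
        param_cov=param_cov,
        sse=sse,
        converged=True,
        n_starts_tried=n_tried,
        df=df,
    )


def fit_hybrid(
    scans: Sequence[IndividualScan],
    measure: str,
    settings: FitSettings = FitSettings(),
) -> GrowthFit:
    """Fit the hybrid model to individual scans for one measure."""
    ages = np.array([s.age_years for s in scans], dtype=float)
    return fit_hybrid_xy(ages, measure_values(scans, measure), measure, settings)


# ---------------------------------------------------------------------------
# Bands
# ---------------------------------------------------------------------------

def _check_fit(fit: GrowthFit, level: float) -> None:
    if not fit.converged:
        raise StateError("cannot build a band from an unconverged fit")
    if not 0 < level < 1:
        raise DomainError(f"level must be in (0, 1), got {level}")


def mean_curve_se(fit: GrowthFit, ages) -> np.ndarray:
    """Delta-method standard error of the fitted mean curve at ``ages``."""
    grads = hybrid_gradient(fit.beta, np.atleast_1d(ages))
    variances = np.einsum("ij,jk,ik->i", grads, fit.param_cov, grads)
    return np.sqrt(np.clip(variances, 0.0, None))


def _delta_band(fit: GrowthFit, ages, level: float, method: str = "delta") -> IntervalBand:
    ages = np.asarray(ages, dtype=float)
    mean = evaluate_hybrid(fit.beta, ages)
    se = mean_curve_se(fit, ages)
    tq = stats.t.ppf(1 - (1 - level) / 2, fit.df)
    ci_half = tq * se
    pi_half = tq * np.sqrt(se**2 + fit.sigma**2)
    band = IntervalBand(
        measure=fit.measure,
        level=level,
        ages=ages,
        mean=np.atleast_1d(mean),
        ci_lo=mean - ci_half,
        ci_hi=mean + ci_half,
        pi_lo=mean - pi_half,
        pi_hi=mean + pi_half,
        method=method,
    )
    band.validate()
    return band


def confidence_band(fit: GrowthFit, ages, level: float = 0.95) -> IntervalBand:
    """Pointwise delta-method band for the MEAN curve.

    The returned band also carries the matching prediction bounds so that the
    band-ordering invariant holds on every instance.
    """
    _check_fit(fit, level)
    return _delta_band(fit, ages, level)


def prediction_band(fit: GrowthFit, ages, level: float = 0.95) -> IntervalBand:
    """Pointwise delta-method band for a NEW individual observation."""
    _check_fit(fit, level)
    return _delta_band(fit, ages, level)


def _draw_beta(fit: GrowthFit, n_draws: int, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    # eigen-factor of the (possibly singular) covariance; deterministic given rng
    eigvals, eigvecs = np.linalg.eigh(fit.param_cov)
    factor = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    draws = np.empty((n_draws, N_PARAMS))
    filled = 0
    rejected = 0
    while filled < n_draws:
        want = n_draws - filled
        z = rng.standard_normal((want, N_PARAMS))
        candidate = fit.beta + z @ factor.T
        ok = candidate[:, 5] > 0
        n_ok = int(ok.sum())
        rejected += want - n_ok
        draws[filled : filled + n_ok] = candidate[ok]
        filled += n_ok
        if rejected > n_draws:
            raise PropagationError(
                "rejection rate above 50%: parameter covariance is inconsistent "
                "with the beta5 > 0 bound"
            )
    return draws, rejected


def mc_band(
    fit: GrowthFit,
    ages,
    level: float = 0.95,
    n_draws: int = 10_000,
    seed: int = 0,
) -> IntervalBand:
    """Parametric Monte-Carlo band: draw parameters from N(beta, cov), push
    through the mean curve (CI) and add residual noise (PI); empirical
    quantiles at the requested level. Deterministic given ``seed``."""
    _check_fit(fit, level)
    if n_draws < 1000:
        raise DomainError(f"n_draws must be >= 1000, got {n_draws}")
    ages = np.asarray(ages, dtype=float)
    rng = np.random.default_rng(seed)
    beta_draws, n_rejected = _draw_beta(fit, n_draws, rng)
    decay = np.exp(-np.outer(beta_draws[:, 5] ** -1, ages))
    curves = (
        beta_draws[:, [4]] * (1.0 - decay)
        + beta_draws[:, [0]]
        + beta_draws[:, [1]] * ages
        + beta_draws[:, [2]] * ages**2
        + beta_draws[:, [3]] * ages**3
    )
    noise = rng.normal(0.0, fit.sigma, size=curves.shape) if fit.sigma > 0 else 0.0
    predicted = curves + noise
    alpha = (1 - level) / 2
    mean = np.atleast_1d(evaluate_hybrid(fit.beta, ages))
    ci_lo = np.quantile(curves, alpha, axis=0)
    ci_hi = np.quantile(curves, 1 - alpha, axis=0)
    pi_lo = np.quantile(predicted, alpha, axis=0)
    pi_hi = np.quantile(predicted, 1 - alpha, axis=0)
    # numerical guard: empirical quantiles can cross by MC error at tiny widths
    ci_lo = np.minimum(ci_lo, mean)
    ci_hi = np.maximum(ci_hi, mean)
    pi_lo = np.minimum(pi_lo, ci_lo)
    pi_hi = np.maximum(pi_hi, ci_hi)
    band = IntervalBand(
        measure=fit.measure,
        level=level,
        ages=ages,
        mean=mean,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        pi_lo=pi_lo,
        pi_hi=pi_hi,
        method="monte_carlo",
    )
    band.n_rejected = n_rejected  # type: ignore[attr-defined]
    band.validate()
    return band


# ---------------------------------------------------------------------------
# Scan I/O
# ---------------------------------------------------------------------------

SCAN_COLUMNS = ("subject_id", "dataset", "age_years", "sex", "tiv_cm3", "gmv_cm3", "wmv_cm3")


def read_scans(path) -> list[IndividualScan]:
    """Read an individual-scan CSV and validate every row."""
    import pandas as pd

    frame = pd.read_csv(path)
    missing = [c for c in SCAN_COLUMNS if c not in frame.columns]
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"scan CSV missing columns: {missing}")
    scans = []
    for row in frame.itertuples(index=False):
        scan = IndividualScan(
            subject_id=str(row.subject_id),
            dataset=str(row.dataset),
            age_years=float(row.age_years),
            sex=str(row.sex),
            tiv_cm3=float(row.tiv_cm3),
            gmv_cm3=float(row.gmv_cm3),
            wmv_cm3=float(row.wmv_cm3),
        )
        scan.validate()
        scans.append(scan)
    return scans


def write_scans(scans: Sequence[IndividualScan], path) -> None:
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(s) for s in scans], columns=list(SCAN_COLUMNS)).to_csv(
        path, index=False
    )
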