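"""Least-squares fits of the aftereffect models.

Three model classes are fit to per-face aftereffects as a function of the
pre-adaptation perceived age:

* **Constrained repulsion** — one Gaussian-derivative shape shared by all
  adapting conditions, with the zero-crossing forced to each condition's
  adapting age.  Two free parameters: peak amplitude ``A`` and bandwidth
  ``sigma``.  This is the repulsion model a multichannel account actually
  licenses: the null sits at the adaptor and the strength and spread of
  adaptation are the same at every adapting level.

* **Renormalization** — constant aftereffect ``k * (norm - adapt)`` per
  condition.  One free parameter ``k``, linear in the data, solved in closed
  form.

* **Unconstrained per-condition GD** — three free parameters
  ``(A, sigma, mu)`` fit separately to each condition, with deliberately wide
  ``mu`` bounds so optima may drift far outside the stimulus range.  This
  replicates the curve-fitting procedure whose unconstrained nulls (e.g. a
  zero-crossing at a negative age) motivate constraining the repulsion model
  in the first place.

Nonlinear fits use multi-start trust-region least squares (bounded); for a
fixed shape the amplitude is linear, so each restart starts from its
closed-form amplitude.  Restarts are ranked by SSE with a deterministic
tie-break (smallest sigma, then smallest |A|).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    DegenerateRegressionError,
    EmptyDataError,
    FitFailureError,
    InsufficientDataError,
)
from .models_core import (
    CONDITIONS,
    GDRepulsionParams,
    NormalizationParams,
    StudyDesign,
)
from .synthetic_data import RatingDataset

_SQRT_E = math.sqrt(math.e)

SIGMA_START_GRID = (2.0, 5.0, 10.0, 20.0, 40.0, 80.0)
AMPLITUDE_BOUNDS = (-20.0, 20.0)
SIGMA_BOUNDS = (1.0, 100.0)
MU_BOUNDS = (-50.0, 150.0)
MU_START_STEP = 10.0
SSE_FTOL = 1e-8
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit."""

    model_label: str
    params: object  # model params, or dict of per-condition params
    sse: float
    n_points: int
    converged: bool
    n_restarts_used: int = 1
    message: str = ""

    @property
    def rms(self) -> float:
        return math.sqrt(self.sse / self.n_points)


def _gd_basis(x: np.ndarray, mu: np.ndarray | float, sigma: float) -> np.ndarray:
    """Unit-amplitude GD shape: sqrt(e)*u*exp(-u^2/2)."""
    u = (x - mu) / sigma
    return _SQRT_E * u * np.exp(-0.5 * u * u)


def _linear_amplitude(y: np.ndarray, basis: np.ndarray) -> float:
    denom = float(basis @ basis)
    if denom == 0.0:
        return 0.0
    return float(y @ basis) / denom


def _pick_best(candidates: list[tuple[float, float, float, bool]]):
    """Best (sse, sigma, A, converged) with deterministic tie-breaks.

    Ties in SSE (relative tolerance) break to smallest sigma, then |A|.
    """
    best_sse = min(c[0] for c in candidates)
    tol = abs(best_sse) * _TIE_RTOL + 1e-12
    tied = [c for c in candidates if c[0] <= best_sse + tol]
    tied.sort(key=lambda c: (c[1], abs(c[2])))
    return tied[0]


def _profile_sigma_minima(
    pre: np.ndarray,
    after: np.ndarray,
    mu: np.ndarray | float,
    sigma_bounds: tuple[float, float],
    amplitude_bounds: tuple[float, float],
    n_scan: int = 199,
) -> list[float]:
    """Sigmas at local minima of the amplitude-profiled SSE."""
    scan = np.linspace(sigma_bounds[0], sigma_bounds[1], n_scan)
    sse = np.empty(n_scan)
    for i, s in enumerate(scan):
        g = _gd_basis(pre, mu, s)
        a = _linear_amplitude(after, g)
        a = min(max(a, amplitude_bounds[0]), amplitude_bounds[1])
        r = after - a * g
        sse[i] = r @ r
    interior = (sse[1:-1] <= sse[:-2]) & (sse[1:-1] <= sse[2:])
    minima = [float(scan[i + 1]) for i in np.flatnonzero(interior)]
    # bound-adjacent basins
    if sse[0] <= sse[1]:
        minima.append(float(scan[0]))
    if sse[-1] <= sse[-2]:
        minima.append(float(scan[-1]))
    return minima


def fit_constrained_repulsion(
    data: RatingDataset,
    design: StudyDesign,
    sigma_grid: Sequence[float] = SIGMA_START_GRID,
    amplitude_bounds: tuple[float, float] = AMPLITUDE_BOUNDS,
    sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
) -> FitResult:
    """Joint (A, sigma) fit with the null pinned at each adapting age.

    Pools squared residuals over all conditions present.  Requires at least
    two conditions with >= 3 points each.
    """
    if len(data) == 0:
        raise EmptyDataError("constrained repulsion fit received no data")
    counts = {c: len(data.subset(c)) for c in data.conditions()}
    if sum(1 for n in counts.values() if n >= 3) < 2:
        raise InsufficientDataError(
            f"need >= 2 conditions with >= 3 points each, got {counts}"
        )
    pre, after, cond = data.arrays()
    mu = np.array([design.adapt_age(c) for c in cond])

    def residuals(theta: np.ndarray) -> np.ndarray:
        amp, sigma = theta
        return after - amp * _gd_basis(pre, mu, sigma)

    lo = np.array([amplitude_bounds[0], sigma_bounds[0]])
    hi = np.array([amplitude_bounds[1], sigma_bounds[1]])
    # the SSE profiled over the (closed-form) amplitude can have several
    # basins in sigma; a dense profile scan locates them so every restart
    # basin is covered, not just the coarse grid
    starts = list(sigma_grid) + _profile_sigma_minima(
        pre, after, mu, sigma_bounds, amplitude_bounds
    )
    candidates = []
    for sigma0 in starts:
        sigma0 = min(max(sigma0, sigma_bounds[0]), sigma_bounds[1])
        a0 = _linear_amplitude(after, _gd_basis(pre, mu, sigma0))
        a0 = min(max(a0, amplitude_bounds[0]), amplitude_bounds[1])
        res = optimize.least_squares(
            residuals, x0=[a0, sigma0], bounds=(lo, hi), ftol=SSE_FTOL,
            xtol=1e-12, gtol=1e-12,
        )
        sse = 2.0 * res.cost
        candidates.append((sse, float(res.x[1]), float(res.x[0]), res.status > 0))
    if not any(c[3] for c in candidates):
        raise FitFailureError(
            "no restart converged; restart diagnostics: "
            + ", ".join(f"(sse={c[0]:.4g}, sigma={c[1]:.4g})" for c in candidates)
        )
    sse, sigma, amp, converged = _pick_best(candidates)
    message = ""
    if abs(amp) < 1e-12:
        message = "sigma unidentifiable at A = 0; reported at its initialization"
    return FitResult(
        model_label="constrained_repulsion",
        params=GDRepulsionParams(amplitude_A=amp, sigma=sigma, mu=None),
        sse=float(sse),
        n_points=len(data),
        converged=converged,
        n_restarts_used=len(candidates),
        message=message,
    )


def fit_normalization(data: RatingDataset, design: StudyDesign) -> FitResult:
    """Closed-form gain fit: k = sum(y_i d_i) / sum(d_i^2), d = norm - adapt.

    The middle condition (d = 0) contributes residuals against a zero
    prediction but no information about k.
    """
    if len(data) == 0:
        raise EmptyDataError("normalization fit received no data")
    _, after, cond = data.arrays()
    d = np.array([design.norm_age - design.adapt_age(c) for c in cond])
    denom = float(d @ d)
    message = ""
    if denom == 0.0:
        gain = 0.0
        message = "gain unidentifiable: all conditions adapt at the norm"
    else:
        gain = float(after @ d) / denom
    resid = after - gain * d
    return FitResult(
        model_label="normalization",
        params=NormalizationParams(gain_k=gain, norm_age=design.norm_age),
        sse=float(resid @ resid),
        n_points=len(data),
        converged=True,
        n_restarts_used=1,
        message=message,
    )


def fit_unconstrained_gd(
    data: RatingDataset,
    condition: str,
    sigma_grid: Sequence[float] = SIGMA_START_GRID,
    mu_bounds: tuple[float, float] = MU_BOUNDS,
    mu_step: float = MU_START_STEP,
    amplitude_bounds: tuple[float, float] = AMPLITUDE_BOUNDS,
    sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
) -> FitResult:
    """Per-condition (A, sigma, mu) GD fit with wide mu bounds.

    The zero-crossing may settle far outside the stimulus range: with broad
    tuning and a remote null the GD approximates a straight line over the
    measured ages, which is exactly the behavior that makes unconstrained
    per-condition fits uninterpretable as a repulsion model.
    """
    sub = data.subset(condition)
    if len(sub) < 4:
        raise InsufficientDataError(
            f"condition {condition!r} has {len(sub)} points; need >= 4 for a "
            "3-parameter fit"
        )
    pre, after, _ = sub.arrays()

    def residuals(theta: np.ndarray) -> np.ndarray:
        amp, sigma, mu = theta
        return after - amp * _gd_basis(pre, mu, sigma)

    lo = np.array([amplitude_bounds[0], sigma_bounds[0], mu_bounds[0]])
    hi = np.array([amplitude_bounds[1], sigma_bounds[1], mu_bounds[1]])
    mu_starts = np.arange(mu_bounds[0], mu_bounds[1] + 0.5 * mu_step, mu_step)
    candidates = []
    for sigma0 in sigma_grid:
        sigma0 = min(max(sigma0, sigma_bounds[0]), sigma_bounds[1])
        for mu0 in mu_starts:
            a0 = _linear_amplitude(after, _gd_basis(pre, mu0, sigma0))
            a0 = min(max(a0, amplitude_bounds[0]), amplitude_bounds[1])
            res = optimize.least_squares(
                residuals, x0=[a0, sigma0, mu0], bounds=(lo, hi), ftol=SSE_FTOL,
                xtol=1e-12, gtol=1e-12,
            )
            candidates.append(
                (
                    2.0 * res.cost,
                    float(res.x[1]),
                    float(res.x[0]),
                    res.status > 0,
                    float(res.x[2]),
                )
            )
    if not any(c[3] for c in candidates):
        raise FitFailureError("no restart converged for unconstrained GD fit")
    best_sse = min(c[0] for c in candidates)
    tol = abs(best_sse) * _TIE_RTOL + 1e-12
    tied = [c for c in candidates if c[0] <= best_sse + tol]
    tied.sort(key=lambda c: (c[1], abs(c[2])))
    sse, sigma, amp, converged, mu = tied[0]
    return FitResult(
        model_label="unconstrained_gd",
        params=GDRepulsionParams(amplitude_A=amp, sigma=sigma, mu=mu),
        sse=float(sse),
        n_points=len(sub),
        converged=converged,
        n_restarts_used=len(candidates),
    )


def fit_linear_regression(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, np.ndarray]:
    """Ordinary least squares; returns (slope, intercept-at-age-0, residuals)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise InsufficientDataError("need >= 2 paired (x, y) values")
    if np.ptp(x) == 0.0:
        raise DegenerateRegressionError("x is constant; slope undefined")
    fit = stats.linregress(x, y)
    residuals = y - (fit.slope * x + fit.intercept)
    return float(fit.slope), float(fit.intercept), residuals
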