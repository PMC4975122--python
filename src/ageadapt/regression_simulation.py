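"""Regression-line diagnostics that separate renormalization from repulsion.

The original slope/intercept analysis fits ordinary least-squares lines to
age judgments before and after adaptation.  A uniform renormalization shifts
the intercept by the (constant) aftereffect without changing the slope, and
the intercept shifts have *opposite* signs for young versus old adaptors
(+A, 0, -A for adapting below, at, or above the norm).  Local repulsion
instead steepens the slope and pushes the intercept in the *same* (negative)
direction at every adapting level.

``intercept_curve`` quantifies the repulsion prediction: it evaluates a
Gaussian-derivative aftereffect curve (peak +/-A, zero-crossing at the
condition's adapting age) at integer ages across the test range, fits an OLS
line, and records the intercept as a function of the GD bandwidth, next to
the uniform-renormalization reference intercept for that condition.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .fitting import fit_linear_regression
from .models_core import CONDITIONS, GDRepulsionParams, StudyDesign, predict_condition

# Bandwidths spanning the values unconstrained per-condition fits can reach
# (from a few years up to several decades).
DEFAULT_SIGMA_GRID = (2.0, 5.0, 10.0, 20.0, 30.0, 40.0, 48.0, 50.0, 80.0)


@dataclass(frozen=True)
class InterceptCurve:
    condition: str
    sigma_grid: tuple[float, ...]
    intercepts: tuple[float, ...]
    renorm_reference_intercept: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "sigma": self.sigma_grid,
                "intercept": self.intercepts,
                "renorm_reference": self.renorm_reference_intercept,
            }
        )


def age_grid(design: StudyDesign) -> np.ndarray:
    """Integer test ages spanning the design range (inclusive)."""
    return np.arange(
        int(np.ceil(design.test_age_min)), int(np.floor(design.test_age_max)) + 1
    ).astype(float)


def renorm_reference_intercept(
    design: StudyDesign, condition: str, amplitude_A: float
) -> float:
    """Uniform-renormalization intercept: +A (young), 0 (middle), -A (old)."""
    adapt = design.adapt_age(condition)
    if adapt < design.norm_age:
        return +amplitude_A
    if adapt > design.norm_age:
        return -amplitude_A
    return 0.0


def intercept_curve(
    design: StudyDesign,
    condition: str,
    amplitude_A: float = 2.4,
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID,
) -> InterceptCurve:
    """OLS intercepts of GD aftereffect curves across bandwidths.

    For each sigma the GD (zero-crossing at the condition's adapting age,
    peak aftereffect +/-A) is evaluated at integer ages over the test range
    and an unweighted OLS line is fit; the intercept at age 0 is recorded.
    """
    if any(s <= 0 for s in sigma_grid):
        raise InvalidParameterError("all sigma values must be > 0")
    ages = age_grid(design)
    intercepts = []
    for sigma in sigma_grid:
        params = GDRepulsionParams(amplitude_A=amplitude_A, sigma=float(sigma))
        curve = predict_condition(design, condition, params, ages)
        _, intercept, _ = fit_linear_regression(ages, curve)
        intercepts.append(intercept)
    return InterceptCurve(
        condition=condition,
        sigma_grid=tuple(float(s) for s in sigma_grid),
        intercepts=tuple(intercepts),
        renorm_reference_intercept=renorm_reference_intercept(
            design, condition, amplitude_A
        ),
    )


def intercept_curves(
    design: StudyDesign,
    amplitude_A: float = 2.4,
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID,
) -> list[InterceptCurve]:
    """Intercept curves for all three adapting conditions."""
    return [
        intercept_curve(design, c, amplitude_A, sigma_grid) for c in CONDITIONS
    ]


def write_intercepts_csv(curves: Sequence[InterceptCurve], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat([c.to_dataframe() for c in curves], ignore_index=True).to_csv(
        path, index=False, float_format="%.10g"
    )
    return path


def plot_intercept_curves(curves: Sequence[InterceptCurve], path: str | Path) -> Path:
    """Three-panel plot of intercept vs. bandwidth with the renorm reference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(curves), figsize=(4 * len(curves), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, curve in zip(axes, curves):
        ax.plot(curve.sigma_grid, curve.intercepts, "b-o", ms=3, label="GD intercept")
        ax.axhline(
            curve.renorm_reference_intercept, color="k", lw=1.2, label="renorm shift"
        )
        ax.axhline(0.0, color="0.7", lw=0.6)
        ax.set_title(curve.condition)
        ax.set_xlabel("GD bandwidth $\\sigma$ (years)")
    axes[0].set_ylabel("regression intercept (years)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def slope_intercept_change(
    pre_ages: Sequence[float],
    post_ages: Sequence[float],
    axis: Sequence[float],
) -> tuple[float, float]:
    """Post-minus-pre change in OLS slope and intercept against a common axis.

    A uniform aftereffect changes the intercept only; a perceptual expansion
    about some pivot changes the slope as well.
    """
    pre = np.asarray(pre_ages, dtype=float)
    post = np.asarray(post_ages, dtype=float)
    x = np.asarray(axis, dtype=float)
    if not (pre.size == post.size == x.size) or pre.size < 3:
        raise InvalidParameterError("need >= 3 matched pre/post/axis values")
    slope_pre, inter_pre, _ = fit_linear_regression(x, pre)
    slope_post, inter_post, _ = fit_linear_regression(x, post)
    return slope_post - slope_pre, inter_post - inter_pre
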