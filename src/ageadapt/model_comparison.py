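"""RMS-error scoring and Wilcoxon signed-rank comparison of fitted models.

Each fitted model is scored by the root-mean-square of its residuals against
the observed per-face aftereffects, per adapting condition and pooled across
conditions, alongside a *no-model* baseline (zero predicted aftereffect
everywhere).  Because the renormalization and constrained-repulsion models
have different numbers of free parameters, they are compared not by RMS
alone but with a paired Wilcoxon signed-rank test on the per-point absolute
residuals — a rank test makes minimal distributional assumptions and does
not reward the model with more parameters.

The signed-rank test is implemented here in full: exact enumeration of the
2^n sign assignments (with midranks for tied magnitudes) when n <= 12 usable
pairs, and the normal approximation with tie correction and a continuity
correction for larger n.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DataValidationError,
    DegenerateTestError,
    InsufficientDataError,
)
from .fitting import FitResult
from .models_core import CONDITIONS, StudyDesign
from .synthetic_data import RatingDataset

EXACT_N_MAX = 12
MIN_PAIRS = 5

SCOPES = CONDITIONS + ("combined",)


@dataclass(frozen=True)
class ScopeComparison:
    """Model-comparison summary for one scope (a condition or 'combined')."""

    scope: str
    rms_normalization: float
    rms_repulsion: float
    rms_no_model: float
    wilcoxon_z: float  # positive: repulsion errors larger (normalization better)
    wilcoxon_p: float
    n_pairs: int
    better_model: str  # 'normalization' | 'constrained_repulsion' | 'tie'


@dataclass(frozen=True)
class ModelComparisonReport:
    scopes: dict[str, ScopeComparison]
    alpha: float = 0.05

    @property
    def combined(self) -> ScopeComparison:
        return self.scopes["combined"]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "scopes": {
                name: {
                    "rms_normalization": s.rms_normalization,
                    "rms_repulsion": s.rms_repulsion,
                    "rms_no_model": s.rms_no_model,
                    "wilcoxon_z": s.wilcoxon_z,
                    "wilcoxon_p": s.wilcoxon_p,
                    "n_pairs": s.n_pairs,
                    "better_model": s.better_model,
                }
                for name, s in self.scopes.items()
            },
        }

    def to_table(self) -> str:
        header = (
            f"{'scope':<10}{'RMS norm':>10}{'RMS rep':>10}{'RMS none':>10}"
            f"{'z':>8}{'p':>9}{'n':>5}  better"
        )
        lines = [header, "-" * len(header)]
        for name in SCOPES:
            if name not in self.scopes:
                continue
            s = self.scopes[name]
            z = f"{s.wilcoxon_z:8.2f}" if math.isfinite(s.wilcoxon_z) else "      --"
            p = f"{s.wilcoxon_p:9.3g}" if math.isfinite(s.wilcoxon_p) else "       --"
            lines.append(
                f"{name:<10}{s.rms_normalization:10.3f}{s.rms_repulsion:10.3f}"
                f"{s.rms_no_model:10.3f}{z}{p}{s.n_pairs:5d}  {s.better_model}"
            )
        return "\n".join(lines)


def rms_error(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square residual, in years."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise DataValidationError(
            f"observed/predicted shapes {obs.shape} vs {pred.shape} (need equal, non-empty)"
        )
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def _exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all 2^n sign assignments of the (mid)ranks."""
    n = ranks.size
    w_all = np.fromiter(
        (float(np.dot(bits, ranks)) for bits in itertools.product((0.0, 1.0), repeat=n)),
        dtype=float,
        count=2**n,
    )
    eps = 1e-9
    p_le = np.mean(w_all <= w_plus + eps)
    p_ge = np.mean(w_all >= w_plus - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    errors_model_a: Sequence[float], errors_model_b: Sequence[float]
) -> tuple[float, float, int]:
    """Paired two-sided signed-rank test on per-point error differences.

    Returns ``(z, p, n_pairs)``.  ``z`` is signed so that positive z means
    ``errors_model_a`` are larger.  Zero differences are dropped; tied
    magnitudes receive midranks.  Exact enumeration for n_pairs <= 12, else
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(errors_model_a, dtype=float)
    b = np.asarray(errors_model_b, dtype=float)
    if a.shape != b.shape:
        raise DataValidationError("error series must have equal length")
    d = a - b
    if a.size and np.all(d == 0.0):
        raise DegenerateTestError("all paired differences are zero")
    d = d[d != 0.0]
    n = d.size
    if n < MIN_PAIRS:
        raise InsufficientDataError(
            f"only {n} non-zero pairs; need >= {MIN_PAIRS}"
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        np.sum(tie_counts**3 - tie_counts)
    ) / 48.0
    sd_w = math.sqrt(var_w)
    dev = w_plus - mean_w
    if dev == 0.0 or sd_w == 0.0:
        z = 0.0
    else:
        z = (dev - 0.5 * math.copysign(1.0, dev)) / sd_w
    if n <= EXACT_N_MAX:
        p = _exact_p(ranks, w_plus)
    else:
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return z, p, n


def _scope_comparison(
    scope: str,
    observed: np.ndarray,
    pred_norm: np.ndarray,
    pred_rep: np.ndarray,
    alpha: float,
) -> ScopeComparison:
    rms_norm = rms_error(observed, pred_norm)
    rms_rep = rms_error(observed, pred_rep)
    rms_none = rms_error(observed, np.zeros_like(observed))
    err_norm = np.abs(observed - pred_norm)
    err_rep = np.abs(observed - pred_rep)
    try:
        # z > 0 <=> repulsion has larger errors, i.e. normalization better
        z, p, n_pairs = wilcoxon_signed_rank(err_rep, err_norm)
    except (DegenerateTestError, InsufficientDataError):
        z, p, n_pairs = float("nan"), float("nan"), 0
    if math.isfinite(p) and p < alpha and rms_norm != rms_rep:
        better = "normalization" if rms_norm < rms_rep else "constrained_repulsion"
    else:
        better = "tie"
    return ScopeComparison(
        scope=scope,
        rms_normalization=rms_norm,
        rms_repulsion=rms_rep,
        rms_no_model=rms_none,
        wilcoxon_z=z,
        wilcoxon_p=p,
        n_pairs=n_pairs,
        better_model=better,
    )


def compare_models(
    data: RatingDataset,
    fit_norm: FitResult,
    fit_rep: FitResult,
    design: StudyDesign | None = None,
    alpha: float = 0.05,
) -> ModelComparisonReport:
    """Score both fitted models per condition and combined.

    ``better_model`` is the lower-RMS model when the signed-rank test on
    paired absolute residuals rejects at ``alpha``, otherwise 'tie'.
    """
    from .models_core import predict_condition  # local to avoid cycle noise

    if design is None:
        if isinstance(data.config_echo, object) and hasattr(data.config_echo, "design"):
            design = data.config_echo.design
        else:
            design = StudyDesign()
    pre, after, cond = data.arrays()
    pred_norm = np.empty_like(after)
    pred_rep = np.empty_like(after)
    for condition in data.conditions():
        mask = cond == condition
        pred_norm[mask] = predict_condition(
            design, condition, fit_norm.params, pre[mask]
        )
        pred_rep[mask] = predict_condition(
            design, condition, fit_rep.params, pre[mask]
        )
    scopes: dict[str, ScopeComparison] = {}
    for condition in data.conditions():
        mask = cond == condition
        scopes[condition] = _scope_comparison(
            condition, after[mask], pred_norm[mask], pred_rep[mask], alpha
        )
    scopes["combined"] = _scope_comparison(
        "combined", after, pred_norm, pred_rep, alpha
    )
    return ModelComparisonReport(scopes=scopes, alpha=alpha)
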