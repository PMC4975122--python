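"""Prediction functions for two accounts of facial age adaptation.

A face *aftereffect* is the change in a face's perceived age (in years)
after prolonged viewing of an adapting face, measured as the post-adaptation
minus pre-adaptation age judgment.  Two families of models make sharply
different predictions about how the aftereffect varies with the test face's
age:

* **Renormalization (norm-based coding).**  Faces are encoded relative to a
  prototype.  Adaptation pulls the prototype toward the adaptor, so every
  test face is biased by the same constant amount, and adapting to the norm
  itself produces no aftereffect.  The bias grows with the distance of the
  adaptor from the norm:  ``aftereffect = k * (norm_age - adapt_age)``,
  independent of the test age.

* **Local repulsion (multichannel coding).**  Faces are encoded by channels
  tuned to absolute age.  Adaptation repels test ages away from the adapting
  age, in opposite directions on either side of it, with a null exactly at
  the adaptor.  The canonical descriptive shape is the first derivative of a
  Gaussian (GD), parameterized here by its peak aftereffect ``A``, bandwidth
  ``sigma`` and zero-crossing ``mu``:

      aftereffect(t) = A * sqrt(e) * u * exp(-u^2 / 2),   u = (t - mu) / sigma

  The ``sqrt(e)`` factor makes the extrema equal exactly ``+/-A`` at
  ``mu +/- sigma``, so ``A`` is read directly as the peak aftereffect in
  years.

All predictions are functions of the *pre-adaptation perceived age* of the
test face (the abscissa on which the aftereffects are analyzed), not the
physical stimulus age.  Sign convention: positive aftereffect = the face
looks older after adapting.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np

from .exceptions import ConfigError, InvalidParameterError

CONDITIONS = ("young", "middle", "old")

_SQRT_E = math.sqrt(math.e)


@dataclass(frozen=True)
class StudyDesign:
    """Adapting ages, norm age, and the span of test ages (all in years).

    ``norm_age`` defaults to the middle adapting age: middle-aged faces act
    as the perceptual norm for age, so adapting to them should produce no
    aftereffect under renormalization.
    """

    adapt_age_young: float = 35.0
    adapt_age_middle: float = 57.0
    adapt_age_old: float = 65.0
    norm_age: float | None = None
    test_age_min: float = 18.0
    test_age_max: float = 89.0

    def __post_init__(self) -> None:
        if self.norm_age is None:
            object.__setattr__(self, "norm_age", self.adapt_age_middle)
        if not self.test_age_min < self.test_age_max:
            raise ConfigError(
                f"test_age_min ({self.test_age_min}) must be < "
                f"test_age_max ({self.test_age_max})"
            )
        for label in CONDITIONS:
            age = self.adapt_age(label)
            if not self.test_age_min <= age <= self.test_age_max:
                raise ConfigError(
                    f"adapt age for {label!r} ({age}) outside test range "
                    f"[{self.test_age_min}, {self.test_age_max}]"
                )

    def adapt_age(self, condition: str) -> float:
        """Adapting age for a named condition (young / middle / old)."""
        try:
            return {
                "young": self.adapt_age_young,
                "middle": self.adapt_age_middle,
                "old": self.adapt_age_old,
            }[condition]
        except KeyError:
            raise ConfigError(f"unknown condition label {condition!r}") from None


@dataclass(frozen=True)
class GDRepulsionParams:
    """Gaussian-derivative repulsion parameters.

    amplitude_A : signed peak aftereffect in years (extrema are ``+/-A``)
    sigma       : bandwidth in years (> 0); extrema sit at ``mu +/- sigma``
    mu          : zero-crossing (null) age in years.  ``None`` means the null
                  is pinned to each condition's adapting age (the constrained
                  repulsion model); a number is required to evaluate the
                  curve directly.
    """

    amplitude_A: float
    sigma: float
    mu: float | None = None

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class NormalizationParams:
    """Renormalization parameters: dimensionless gain and the norm age."""

    gain_k: float
    norm_age: float = 57.0


@dataclass(frozen=True)
class AftereffectPoint:
    """One test face in one adapting condition.

    ``aftereffect`` is stored redundantly and must equal
    ``post_age - pre_age`` to within ``tol``.
    """

    condition: str
    face_id: str
    pre_age: float
    post_age: float
    aftereffect: float | None = None
    tol: float = field(default=1e-6, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition label {self.condition!r}")
        if self.aftereffect is None:
            object.__setattr__(self, "aftereffect", self.post_age - self.pre_age)
        elif abs(self.aftereffect - (self.post_age - self.pre_age)) > self.tol:
            raise ConfigError(
                f"face {self.face_id!r}: aftereffect {self.aftereffect} != "
                f"post - pre = {self.post_age - self.pre_age}"
            )


ArrayLike = Union[float, Sequence[float], np.ndarray]


def gd_aftereffect(test_age: ArrayLike, params: GDRepulsionParams) -> ArrayLike:
    """Gaussian-derivative (repulsion) aftereffect at ``test_age``.

    Evaluates ``A * sqrt(e) * u * exp(-u^2/2)`` with ``u = (t - mu)/sigma``.
    Odd-symmetric about ``mu``; zero at ``mu``; extrema ``+/-A`` at
    ``mu +/- sigma``; decays to 0 far from ``mu``.
    """
    if params.mu is None:
        raise InvalidParameterError(
            "mu is None (condition-pinned); use predict_condition instead"
        )
    t = np.asarray(test_age, dtype=float)
    u = (t - params.mu) / params.sigma
    out = params.amplitude_A * _SQRT_E * u * np.exp(-0.5 * u * u)
    return float(out) if np.isscalar(test_age) else out


def normalization_aftereffect(
    test_age: ArrayLike, adapt_age: float, params: NormalizationParams
) -> ArrayLike:
    """Renormalization aftereffect: ``k * (norm_age - adapt_age)``.

    Constant in ``test_age``; zero when adapting to the norm; positive
    (faces look older) when the adaptor is younger than the norm.
    """
    value = params.gain_k * (params.norm_age - adapt_age)
    if np.isscalar(test_age):
        return float(value)
    return np.full(np.asarray(test_age, dtype=float).shape, value)


def predict_condition(
    design: StudyDesign,
    condition: str,
    model: GDRepulsionParams | NormalizationParams,
    test_ages: ArrayLike,
) -> np.ndarray:
    """Predicted aftereffects for one adapting condition.

    For ``GDRepulsionParams`` the zero-crossing is pinned to the condition's
    adapting age (the constrained repulsion model); any ``mu`` on the params
    is ignored.  For ``NormalizationParams`` the prediction is the constant
    ``k * (norm - adapt)``.
    """
    ages = np.atleast_1d(np.asarray(test_ages, dtype=float))
    if ages.size == 0:
        raise ConfigError("test_ages must be non-empty")
    adapt = design.adapt_age(condition)
    if isinstance(model, GDRepulsionParams):
        pinned = replace(model, mu=adapt)
        return np.asarray(gd_aftereffect(ages, pinned))
    if isinstance(model, NormalizationParams):
        return np.asarray(normalization_aftereffect(ages, adapt, model))
    raise ConfigError(f"unknown model parameter type {type(model).__name__}")
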