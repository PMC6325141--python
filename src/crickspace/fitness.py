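"""Precision-economy fitness theory of transcription and translation rates.

Expressing a gene costs fitness twice over. Transcription consumes limited
polymerase/nucleotide resources: a transcript of length ``l_m`` made at rate
``beta_m`` costs ``Delta_f_m = c_m * l_m * beta_m`` with ``c_m`` the fitness
penalty per transcribed nucleotide, itself estimable from the growth rate
and the cell's total transcriptional output as
``c_m = mu / (l_m * sum(beta_m))``. Stochastic fluctuations cost the noise
load ``Delta_f_noise = |f''(p*)| * sigma^2 / 2`` for a fitness function
``f(p)`` peaking at ``p*`` with curvature ``f''(p*) < 0``.

Balancing the two at fixed protein abundance gives a closed-form optimum:
``beta_m = sqrt(alpha_p * alpha_m * Q * p* / C)`` and
``beta_p / beta_m = C / Q``, where ``C = c_m * l_m * alpha_m`` is the
transcription cost per mRNA and ``Q = |f''(p*)| * p* / 2`` the gene's noise
sensitivity. The noise floor ``cv0`` caps how noise-sensitive a selectable
gene can be (``Q_max``), which turns the optimum into a prediction for the
depleted-region boundary:

    k = C / Q_max = beta_p_max * cv0 / sqrt(rho * alpha_p * sum(beta_m))

with ``rho`` the fraction of the growth rate a gene can contribute
(``rho = 1`` for essential genes; smaller ``rho`` raises the boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .constants import CellularConstants
from .exceptions import InvalidParameterError

__all__ = [
    "FitnessSpec",
    "OptimalRates",
    "BoundaryPrediction",
    "transcription_cost",
    "cm_from_constants",
    "cm_per_mrna",
    "noise_load",
    "mean_fitness",
    "optimal_rates",
    "curvature_from_rates",
    "q_max",
    "predict_k",
    "is_selectable",
]


@dataclass(frozen=True)
class FitnessSpec:
    """Quadratic fitness peak of one gene plus its transcription cost scale.

    The fitness function is represented by its second-order expansion around
    the optimum: peak value ``f_max`` [h^-1], optimal abundance ``p_star``
    [proteins], and curvature ``f''(p*) <= 0`` [h^-1 protein^-2]. ``c_m``,
    ``l_m`` and ``alpha_m`` set the gene's transcription cost per mRNA.
    """

    f_max: float
    p_star: float
    curvature: float
    c_m: float
    l_m: float
    alpha_m: float

    def __post_init__(self) -> None:
        if not self.f_max > 0:
            raise InvalidParameterError("f_max must be strictly positive")
        if not self.p_star > 0:
            raise InvalidParameterError("p_star must be strictly positive")
        if self.curvature > 0:
            raise InvalidParameterError("curvature must be <= 0 (fitness maximum)")
        if self.c_m < 0 or self.l_m <= 0 or self.alpha_m <= 0:
            raise InvalidParameterError("c_m >= 0 and l_m, alpha_m > 0 required")

    @property
    def Q(self) -> float:
        """Noise sensitivity |f''(p*)| * p* / 2, h^-1 protein^-1."""
        return 0.5 * abs(self.curvature) * self.p_star

    @property
    def C(self) -> float:
        """Transcription cost per mRNA molecule, c_m * l_m * alpha_m, h^-1."""
        return self.c_m * self.l_m * self.alpha_m


@dataclass(frozen=True)
class OptimalRates:
    beta_m: float
    beta_p: float
    ratio: float  # beta_p / beta_m = C / Q
    exceeds_beta_p_max: bool


@dataclass(frozen=True)
class BoundaryPrediction:
    """Predicted depleted-region boundary intercept and its provenance."""

    k_pred: float
    Q_max: float
    rho: float
    inputs: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"k_pred": self.k_pred, "Q_max": self.Q_max, "rho": self.rho,
                "inputs": dict(self.inputs)}


def transcription_cost(beta_m: float, l_m: float, c_m: float) -> float:
    """Fitness cost of transcription, c_m * l_m * beta_m [h^-1]."""
    if beta_m < 0 or l_m < 0 or c_m < 0:
        raise InvalidParameterError("inputs must be non-negative")
    return c_m * l_m * beta_m


def cm_from_constants(mu: float, total_transcription: float, l_m: float) -> float:
    """Fitness cost per transcribed nucleotide, mu / (l_m * sum(beta_m)) [nt^-1]."""
    if not (mu > 0 and total_transcription > 0 and l_m > 0):
        raise InvalidParameterError("all inputs must be strictly positive")
    return mu / (l_m * total_transcription)


def cm_per_mrna(mu: float, N_m: float) -> float:
    """Fitness cost per mRNA copy, mu / N_m [mRNA^-1]."""
    if not (mu > 0 and N_m > 0):
        raise InvalidParameterError("all inputs must be strictly positive")
    return mu / N_m


def noise_load(curvature: float, sigma2: float) -> float:
    """Fitness lost to fluctuations: |f''(p*)| * sigma^2 / 2 [h^-1]."""
    if curvature > 0:
        raise InvalidParameterError("curvature must be <= 0 (not a fitness maximum)")
    if sigma2 < 0:
        raise InvalidParameterError("variance must be non-negative")
    return 0.5 * abs(curvature) * sigma2


def mean_fitness(spec: FitnessSpec, consts: CellularConstants, beta_m) -> float | np.ndarray:
    """Average fitness <F> = f_max - noise load - transcription cost at fixed p*.

    Protein abundance is held at the optimum ``p*`` (translation co-varies
    with transcription), so only the alpha_p / beta_m term of the variance
    depends on ``beta_m``:

        sigma^2 = p*^2 (1/p* + alpha_p/beta_m + cv0^2)
    """
    beta_m = np.asarray(beta_m, dtype=float)
    if np.any(beta_m <= 0):
        raise InvalidParameterError("beta_m must be strictly positive")
    p = spec.p_star
    sigma2 = p * p * (1.0 / p + consts.alpha_p / beta_m + consts.cv0**2)
    out = spec.f_max - 0.5 * abs(spec.curvature) * sigma2 \
        - transcription_cost(beta_m, spec.l_m, spec.c_m)
    return float(out) if out.ndim == 0 else out


def optimal_rates(spec: FitnessSpec, consts: CellularConstants) -> OptimalRates:
    """Closed-form fitness-maximizing rates at fixed protein abundance p*.

    beta_m = sqrt(alpha_p * alpha_m * Q * p* / C); translation follows from
    p* = beta_m * beta_p / (alpha_m * alpha_p). The result is flagged when
    the required translation rate exceeds the organism's beta_p_max.
    """
    if spec.Q == 0:
        raise InvalidParameterError(
            "Q = 0 (flat fitness peak): economy is unbounded, no interior optimum"
        )
    if spec.C <= 0:
        raise InvalidParameterError("C must be strictly positive")
    beta_m = math.sqrt(consts.alpha_p * spec.alpha_m * spec.Q * spec.p_star / spec.C)
    beta_p = spec.p_star * spec.alpha_m * consts.alpha_p / beta_m
    return OptimalRates(
        beta_m=beta_m,
        beta_p=beta_p,
        ratio=spec.C / spec.Q,
        exceeds_beta_p_max=beta_p > consts.beta_p_max,
    )


def curvature_from_rates(beta_p_over_beta_m: float, C: float, p_star: float) -> float:
    """Fitness-peak curvature implied by a gene's translation/transcription ratio.

    Inverts the optimality condition ratio = C/Q: |f''(p*)| = 2C / (p* * ratio).
    Returns the (negative) curvature.
    """
    if not (beta_p_over_beta_m > 0 and C > 0 and p_star > 0):
        raise InvalidParameterError("ratio, C and p_star must be strictly positive")
    return -2.0 * C / (p_star * beta_p_over_beta_m)


def is_selectable(f_max: float, curvature: float, p_star: float, cv2: float) -> bool:
    """Whether the fitness peak survives fluctuations: f_max - noise load > 0."""
    sigma2 = cv2 * p_star * p_star
    return f_max - noise_load(curvature, sigma2) > 0


def q_max(consts: CellularConstants, rho: float | None = None) -> float:
    """Maximal selectable noise sensitivity Q_max [h^-1 protein^-1].

    Q_max = sqrt(alpha_p * alpha_m * rho * mu * C) / (beta_p_max * cv0),
    with C the organismal transcription cost per mRNA. Genes with Q above
    this bound would have negative mean fitness given the noise floor.
    """
    rho = consts.rho if rho is None else rho
    if not 0 < rho <= 1:
        raise InvalidParameterError("rho must lie in (0, 1]")
    c_m = cm_from_constants(consts.mu, consts.total_transcription, consts.l_m)
    C = c_m * consts.l_m * consts.alpha_m
    return math.sqrt(consts.alpha_p * consts.alpha_m * rho * consts.mu * C) / (
        consts.beta_p_max * consts.cv0
    )


def predict_k(consts: CellularConstants, rho: float | None = None) -> BoundaryPrediction:
    """Predicted depleted-region boundary k from organism-level constants.

    k = beta_p_max * cv0 / sqrt(rho * alpha_p * sum(beta_m)); equivalently
    C / Q_max, which the returned object reproduces to floating-point
    accuracy.
    """
    rho = consts.rho if rho is None else rho
    if not 0 < rho <= 1:
        raise InvalidParameterError("rho must lie in (0, 1]")
    k_pred = consts.beta_p_max * consts.cv0 / math.sqrt(
        rho * consts.alpha_p * consts.total_transcription
    )
    return BoundaryPrediction(
        k_pred=k_pred,
        Q_max=q_max(consts, rho),
        rho=rho,
        inputs={
            "beta_p_max": consts.beta_p_max,
            "cv0": consts.cv0,
            "alpha_p": consts.alpha_p,
            "alpha_m": consts.alpha_m,
            "total_transcription": consts.total_transcription,
            "mu": consts.mu,
        },
    )
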