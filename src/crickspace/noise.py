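"""Analytic noise theory for the two-state (telegraph) gene model.

A promoter switches on at rate ``k_on`` and off at rate ``k_off``; while on
it transcribes at rate ``delta``. mRNAs decay at ``alpha_m``, are translated
at ``beta_p``, and proteins decay at ``alpha_p``. The effective transcription
rate is ``beta_m = delta * P_on`` with ``P_on = k_on / (k_on + k_off)``, and
each activation produces a transcriptional burst of mean size
``b = delta / k_off``.

At stationarity the squared coefficient of variation of protein abundance
has a closed form with three contributions:

* Poisson noise of the protein birth-death process, ``1/p``;
* amplification of small-mRNA-number fluctuations,
  ``alpha_p * alpha_m / (beta_m * (alpha_p + alpha_m))``;
* promoter activation/inactivation noise (the bursting term).

Two regime approximations rewrite the exact form in terms of measurable
quantities: a fast-mRNA-turnover form suited to prokaryotes
(``1/p + alpha_p/beta_m + alpha_p (1 - beta_m/delta) / k_on``) and a burst
form suited to eukaryotes (``1/p + (alpha_p/beta_m) * phi`` with
``phi = (q/(1+q)) (1 + b (1-P_on)^2)``, ``q = alpha_m/alpha_p``). Saturating
activation kinetics at high transcription yield an expression for the noise
floor ``cv0``; folding it back in gives the phenomenological form
``1/p + alpha_p/beta_m + cv0^2`` used throughout the fitness theory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import InvalidParameterError

__all__ = [
    "TelegraphParams",
    "DerivedTelegraph",
    "NoiseEstimate",
    "cv2_exact",
    "cv2_simplified",
    "cv2_prokaryote",
    "cv2_eukaryote",
    "activation_noise_term",
    "phi_factor",
    "noise_floor_from_activation",
]

REGIME_MARGIN = 10.0  # fold-separation expected by the regime approximations


@dataclass(frozen=True)
class TelegraphParams:
    """Kinetic parameters of the two-state gene model (all per hour)."""

    k_on: float
    k_off: float
    delta: float
    beta_p: float
    alpha_m: float
    alpha_p: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "delta", "beta_p", "alpha_m", "alpha_p"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.k_on + self.k_off <= 0:
            raise InvalidParameterError("k_on + k_off must be strictly positive")

    def derived(self) -> "DerivedTelegraph":
        if self.alpha_m <= 0 or self.alpha_p <= 0:
            raise InvalidParameterError("decay rates must be strictly positive")
        p_on = self.k_on / (self.k_on + self.k_off)
        return DerivedTelegraph(
            P_on=p_on,
            beta_m=self.delta * p_on,
            b=self.delta / self.k_off if self.k_off > 0 else math.inf,
            q=self.alpha_m / self.alpha_p,
        )

    def steady_state_protein(self) -> float:
        """Mean protein abundance beta_m * beta_p / (alpha_m * alpha_p)."""
        d = self.derived()
        return d.beta_m * self.beta_p / (self.alpha_m * self.alpha_p)


@dataclass(frozen=True)
class DerivedTelegraph:
    """Quantities derived from the telegraph kinetics."""

    P_on: float   # fraction of time the promoter is active
    beta_m: float  # effective transcription rate, delta * P_on
    b: float      # mean transcriptional burst size, delta / k_off
    q: float      # decay-rate ratio alpha_m / alpha_p

    @property
    def phi(self) -> float:
        """Gene-activation factor (q/(1+q)) * (1 + b (1-P_on)^2)."""
        return phi_factor(self.q, self.b, self.P_on)


@dataclass(frozen=True)
class NoiseEstimate:
    """Squared protein CV with its additive component breakdown."""

    cv2: float
    poisson: float     # 1/p
    low_mrna: float    # small-mRNA-copy-number amplification
    activation: float  # promoter switching / bursting (or noise-floor) term
    model_tag: str

    def __post_init__(self) -> None:
        total = self.poisson + self.low_mrna + self.activation
        if not math.isclose(total, self.cv2, rel_tol=1e-9, abs_tol=1e-300):
            raise InvalidParameterError("noise components do not sum to cv2")

    @property
    def cv(self) -> float:
        return math.sqrt(self.cv2)


def _check_p(p: float) -> None:
    if not p > 0:
        raise InvalidParameterError("protein abundance p must be strictly positive")


def cv2_exact(params: TelegraphParams, p: float) -> NoiseEstimate:
    """Exact stationary squared CV of protein abundance for the telegraph model."""
    _check_p(p)
    if params.alpha_m <= 0 or params.alpha_p <= 0:
        raise InvalidParameterError("decay rates must be strictly positive")
    if params.k_on <= 0:
        raise InvalidParameterError("k_on must be strictly positive (gene never activates)")
    am, ap = params.alpha_m, params.alpha_p
    kon, koff = params.k_on, params.k_off
    d = params.derived()
    if d.beta_m <= 0:
        raise InvalidParameterError("effective transcription rate is zero")
    poisson = 1.0 / p
    low_mrna = ap * am / (d.beta_m * (ap + am))
    activation = (
        ap * am * koff * (ap + am + koff + kon)
        / (kon * (ap + am) * (ap + koff + kon) * (am + koff + kon))
    )
    return NoiseEstimate(
        cv2=poisson + low_mrna + activation,
        poisson=poisson,
        low_mrna=low_mrna,
        activation=activation,
        model_tag="exact",
    )


def cv2_simplified(p: float, beta_m: float, alpha_p: float, cv0: float) -> NoiseEstimate:
    """Phenomenological squared CV: 1/p + alpha_p/beta_m + cv0**2."""
    _check_p(p)
    if not beta_m > 0:
        raise InvalidParameterError("beta_m must be strictly positive")
    if cv0 < 0:
        raise InvalidParameterError("cv0 must be non-negative")
    poisson = 1.0 / p
    low_mrna = alpha_p / beta_m
    floor = cv0 * cv0
    return NoiseEstimate(
        cv2=poisson + low_mrna + floor,
        poisson=poisson,
        low_mrna=low_mrna,
        activation=floor,
        model_tag="simplified",
    )


def activation_noise_term(alpha_p: float, k_on: float, beta_m: float = 0.0,
                          delta: float = math.inf) -> float:
    """Promoter-activation noise term alpha_p * (1 - beta_m/delta) / k_on.

    With ``beta_m`` omitted (or ``delta`` infinite) this is the
    ``beta_m << delta`` limit ``alpha_p / k_on``.
    """
    if not k_on > 0:
        raise InvalidParameterError("k_on must be strictly positive")
    if beta_m > delta:
        raise InvalidParameterError("beta_m cannot exceed delta (P_on > 1 impossible)")
    frac = 0.0 if math.isinf(delta) else beta_m / delta
    return alpha_p * (1.0 - frac) / k_on


def _warn_regime(condition: bool, message: str) -> None:
    if not condition:
        warnings.warn(f"regime assumption violated: {message}", stacklevel=3)


def cv2_prokaryote(params: TelegraphParams, p: float) -> NoiseEstimate:
    """Fast-mRNA-turnover approximation of the squared CV.

    Valid when mRNA decay and promoter inactivation are both much faster
    than protein decay (``alpha_m >> alpha_p`` and ``k_off >> alpha_p``);
    a warning is emitted when either ratio falls below 10.
    """
    _check_p(p)
    d = params.derived()
    if d.beta_m > params.delta:
        raise InvalidParameterError("beta_m cannot exceed delta")
    if d.beta_m <= 0:
        raise InvalidParameterError("effective transcription rate is zero")
    _warn_regime(params.alpha_m >= REGIME_MARGIN * params.alpha_p, "alpha_m >> alpha_p")
    _warn_regime(params.k_off >= REGIME_MARGIN * params.alpha_p, "k_off >> alpha_p")
    poisson = 1.0 / p
    low_mrna = params.alpha_p / d.beta_m
    activation = activation_noise_term(params.alpha_p, params.k_on, d.beta_m, params.delta)
    return NoiseEstimate(
        cv2=poisson + low_mrna + activation,
        poisson=poisson,
        low_mrna=low_mrna,
        activation=activation,
        model_tag="prokaryote",
    )


def phi_factor(q: float, b: float, P_on: float) -> float:
    """Gene-activation factor phi = (q/(1+q)) * (1 + b * (1 - P_on)**2)."""
    if q < 0 or b < 0:
        raise InvalidParameterError("q and b must be non-negative")
    if not 0 <= P_on <= 1:
        raise InvalidParameterError("P_on must lie in [0, 1]")
    return (q / (1.0 + q)) * (1.0 + b * (1.0 - P_on) ** 2)


def cv2_eukaryote(params: TelegraphParams, p: float) -> NoiseEstimate:
    """Burst-size approximation of the squared CV: 1/p + (alpha_p/beta_m) * phi.

    Valid when activation dynamics are much faster than protein decay
    (``k_on + k_off >> alpha_p``). The activation component equals the
    high-expression split (q/(1+q)) (1-P_on)^2 alpha_p / (k_off P_on)
    exactly, since b = beta_m / (P_on * k_off).
    """
    _check_p(p)
    d = params.derived()
    if d.beta_m <= 0:
        raise InvalidParameterError("effective transcription rate is zero")
    _warn_regime(
        params.k_on + params.k_off >= REGIME_MARGIN * params.alpha_p,
        "k_on + k_off >> alpha_p",
    )
    poisson = 1.0 / p
    frac = d.q / (1.0 + d.q)
    low_mrna = (params.alpha_p / d.beta_m) * frac
    activation = (params.alpha_p / d.beta_m) * frac * d.b * (1.0 - d.P_on) ** 2
    return NoiseEstimate(
        cv2=poisson + low_mrna + activation,
        poisson=poisson,
        low_mrna=low_mrna,
        activation=activation,
        model_tag="eukaryote",
    )


def noise_floor_from_activation(P_on: float, k_off: float, q: float, alpha_p: float) -> float:
    """Noise floor implied by saturated activation kinetics.

    cv0 = sqrt( (q/(1+q)) * (1-P_on)^2 * alpha_p / (k_off * P_on) ) — the
    high-transcription limit of the burst-form CV, where further expression
    gains come only from larger bursts.
    """
    if not 0 < P_on < 1:
        raise InvalidParameterError("P_on must lie strictly inside (0, 1)")
    if not (k_off > 0 and alpha_p > 0 and q > 0):
        raise InvalidParameterError("k_off, alpha_p and q must be strictly positive")
    cv0_sq = (q / (1.0 + q)) * (1.0 - P_on) ** 2 * alpha_p / (k_off * P_on)
    return math.sqrt(cv0_sq)
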