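"""Deterministic steady-state model of the central dogma.

Each gene is summarized by four reaction rates: transcription ``beta_m``
[mRNA h^-1], translation ``beta_p`` [protein mRNA^-1 h^-1], mRNA decay
``alpha_m`` [h^-1] and protein decay ``alpha_p`` [h^-1]. The mRNA and
protein copy-number dynamics

    dm/dt = beta_m - alpha_m * m
    dp/dt = beta_p * m - alpha_p * p

have the unique steady state m = beta_m / alpha_m and
p = beta_m * beta_p / (alpha_m * alpha_p). The plane of (beta_m, beta_p),
usually drawn in log10 coordinates, is referred to as Crick space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

__all__ = ["GeneRates", "steady_state", "max_translation_rate", "rates_from_abundance"]

SECONDS_PER_HOUR = 3600.0
NT_PER_CODON = 3.0


@dataclass(frozen=True)
class GeneRates:
    """Central-dogma rates and derived steady-state abundances of one gene."""

    gene_id: str
    beta_m: float
    beta_p: float
    alpha_m: float
    alpha_p: float

    def __post_init__(self) -> None:
        if self.beta_m <= 0 or self.beta_p < 0:
            raise InvalidParameterError("beta_m must be > 0 and beta_p >= 0")
        if self.alpha_m <= 0 or self.alpha_p <= 0:
            raise InvalidParameterError("decay rates must be strictly positive")

    @property
    def m(self) -> float:
        """Steady-state mRNA copy number."""
        return self.beta_m / self.alpha_m

    @property
    def p(self) -> float:
        """Steady-state protein copy number."""
        return self.beta_m * self.beta_p / (self.alpha_m * self.alpha_p)

    @property
    def ratio(self) -> float:
        """Translation/transcription ratio beta_p / beta_m."""
        return self.beta_p / self.beta_m


def steady_state(beta_m, beta_p, alpha_m, alpha_p):
    """Steady-state (m, p) copy numbers for given central-dogma rates.

    Accepts scalars or numpy arrays (broadcast elementwise). Decay rates
    must be strictly positive.
    """
    beta_m = np.asarray(beta_m, dtype=float)
    beta_p = np.asarray(beta_p, dtype=float)
    alpha_m = np.asarray(alpha_m, dtype=float)
    alpha_p = np.asarray(alpha_p, dtype=float)
    for name, arr in (("beta_m", beta_m), ("beta_p", beta_p),
                      ("alpha_m", alpha_m), ("alpha_p", alpha_p)):
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError(f"{name} must be finite")
    if np.any(alpha_m <= 0) or np.any(alpha_p <= 0):
        raise InvalidParameterError("decay rates must be strictly positive")
    m = beta_m / alpha_m
    p = beta_m * beta_p / (alpha_m * alpha_p)
    if m.ndim == 0:
        return float(m), float(p)
    return m, p


def max_translation_rate(v: float, footprint_nt: float) -> float:
    """Maximal translation rate of a single mRNA, protein mRNA^-1 h^-1.

    When initiation is saturating, ribosomes queue along the transcript and
    the protein flux is limited by how fast one ribosome clears the footprint
    of the next: v / L, with elongation speed v [aa s^-1] and footprint
    L = footprint_nt / 3 codons (kept as a real number, not rounded).
    """
    if not (v > 0 and footprint_nt > 0):
        raise InvalidParameterError("v and footprint_nt must be strictly positive")
    codons = footprint_nt / NT_PER_CODON
    return SECONDS_PER_HOUR * v / codons


def rates_from_abundance(m, p, alpha_m, alpha_p):
    """Invert the steady state: rates (beta_m, beta_p) producing given (m, p)."""
    m = np.asarray(m, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(m <= 0):
        raise InvalidParameterError("m must be strictly positive to invert")
    beta_m = m * np.asarray(alpha_m, dtype=float)
    beta_p = p * np.asarray(alpha_p, dtype=float) / m
    if beta_m.ndim == 0:
        return float(beta_m), float(beta_p)
    return beta_m, beta_p
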