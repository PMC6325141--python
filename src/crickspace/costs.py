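"""Fitness costs of mRNA and protein from growth-competition experiments.

Two experimental designs are supported. In a pooled clone-library
competition, clones expressing a reporter at mRNA level ``m`` and protein
level ``p`` grow exponentially; after time ``t`` the log abundance of each
clone relative to a low-expression reference class follows

    log(x_{m,p}(t) / x_{0,0}(t)) = -t*c_p*p - t*c_m*m

so a linear regression recovers the composite cost coefficients ``t*c_m``
and ``t*c_p``, and a nested F-test (protein-only vs protein+mRNA model)
asks whether mRNA carries a measurable cost at all.

In a gene-copy-number titration, the relative growth rate falls linearly
with the construct copy number ``n``; comparing the slope ``s_N`` of the
full construct with the slope ``s_D`` of a destabilized (DAmP) variant —
which keeps transcription but reduces protein output by the factor ``phi``
— isolates the transcription-attributable cost per nucleotide:

    c_m = mu_0 * (s_D - s_N * phi) / (l_m * beta_m * (1 - phi))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DegenerateInputError, InvalidParameterError

__all__ = [
    "TitrationMeasurement",
    "CloneRegressionResult",
    "clone_cost_regression",
    "predict_clone_logratio",
    "predicted_cm_cp_ratio",
    "estimate_cm_titration",
    "fit_titration_slope",
    "DAMP_PHI_RANGE",
]

# the protein-reduction factor of DAmP constructs is known only to lie
# between 10- and 30-fold
DAMP_PHI_RANGE = (1.0 / 30.0, 1.0 / 10.0)


@dataclass(frozen=True)
class TitrationMeasurement:
    """Slopes and constants of a copy-number titration experiment."""

    s_N: float       # slope of mu/mu0 vs copy number, full construct
    s_D: float       # slope of mu/mu0 vs copy number, DAmP construct
    phi_damp: float  # protein-reduction factor of the DAmP construct (< 1)
    l_m: float       # construct mRNA length, nt
    beta_m: float    # construct transcription rate, mRNA h^-1
    mu_0: float      # wild-type growth rate, h^-1

    def __post_init__(self) -> None:
        if not 0 < self.phi_damp < 1:
            raise InvalidParameterError("phi_damp must lie strictly inside (0, 1)")
        if not (self.l_m > 0 and self.beta_m > 0 and self.mu_0 > 0):
            raise InvalidParameterError("l_m, beta_m and mu_0 must be strictly positive")
        if not (np.isfinite(self.s_N) and np.isfinite(self.s_D)):
            raise InvalidParameterError("slopes must be finite")


@dataclass(frozen=True)
class CloneRegressionResult:
    t_cm: float       # composite mRNA cost, t * c_m (per mRNA)
    t_cp: float       # composite protein cost, t * c_p (per protein)
    t_cm_se: float
    t_cp_se: float
    f_test_p: float   # nested F-test: does adding m improve on p alone?
    n: int


def clone_cost_regression(records: pd.DataFrame, intercept: bool = False) -> CloneRegressionResult:
    """Fit composite mRNA/protein costs from clone relative abundances.

    ``records`` needs columns ``m``, ``p`` and ``log_rel_abundance``. The
    regression is anchored to the reference clone class, so no intercept is
    fit by default (``intercept=True`` adds one as a robustness check). The
    returned coefficients are sign-flipped to the cost convention
    (positive = deleterious).
    """
    if len(records) < 10:
        raise InvalidParameterError("need at least 10 clone records")
    m = records["m"].to_numpy(float)
    p = records["p"].to_numpy(float)
    y = records["log_rel_abundance"].to_numpy(float)
    if not np.all(np.isfinite(np.concatenate([m, p, y]))):
        raise InvalidParameterError("clone records must be finite")

    X_full = np.column_stack([p, m])
    X_red = p[:, None]
    if intercept:
        X_full = sm.add_constant(X_full)
        X_red = sm.add_constant(X_red)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise DegenerateInputError("m and p are collinear: costs are not identifiable")

    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, X_red).fit()
    _, f_p, _ = full.compare_f_test(reduced)

    i_p, i_m = (1, 2) if intercept else (0, 1)
    return CloneRegressionResult(
        t_cm=-float(full.params[i_m]),
        t_cp=-float(full.params[i_p]),
        t_cm_se=float(full.bse[i_m]),
        t_cp_se=float(full.bse[i_p]),
        f_test_p=float(f_p),
        n=len(records),
    )


def predict_clone_logratio(m, p, t: float, c_m: float, c_p: float):
    """Expected log relative clone abundance, -t*c_p*p - t*c_m*m."""
    if t < 0:
        raise InvalidParameterError("growth time t must be non-negative")
    m = np.asarray(m, dtype=float)
    p = np.asarray(p, dtype=float)
    out = -t * c_p * p - t * c_m * m
    return float(out) if out.ndim == 0 else out


def predicted_cm_cp_ratio(N_p: float, N_m: float) -> float:
    """Theoretical mRNA/protein cost ratio c_m/c_p = N_p/N_m."""
    if not (N_p > 0 and N_m > 0):
        raise InvalidParameterError("copy numbers must be strictly positive")
    return N_p / N_m


def fit_titration_slope(copies, rel_growth) -> float:
    """Slope s of mu/mu0 = 1 - n*s, least squares through the point (0, 1)."""
    n = np.asarray(copies, dtype=float)
    y = np.asarray(rel_growth, dtype=float)
    if n.size != y.size or n.size == 0:
        raise InvalidParameterError("copies and rel_growth must be equal-length, non-empty")
    denom = float(np.sum(n * n))
    if denom == 0:
        raise DegenerateInputError("all copy numbers are zero")
    return float(np.sum(n * (1.0 - y)) / denom)


def estimate_cm_titration(
    meas: TitrationMeasurement, phi_range: tuple[float, float] | None = None
):
    """Transcription cost per nucleotide from titration slopes.

    Returns ``c_m`` evaluated at ``meas.phi_damp``. If ``phi_range`` is given
    (``estimate_cm_titration(meas, phi_range=DAMP_PHI_RANGE)``), also returns
    the (low, high) interval of ``c_m`` over that range of the imprecisely
    known protein-reduction factor.
    """

    def _cm(phi: float) -> float:
        return meas.mu_0 * (meas.s_D - meas.s_N * phi) / (meas.l_m * meas.beta_m * (1.0 - phi))

    c_m = _cm(meas.phi_damp)
    if phi_range is None:
        return c_m
    lo, hi = phi_range
    if not 0 < lo <= hi < 1:
        raise InvalidParameterError("phi_range must satisfy 0 < lo <= hi < 1")
    ends = sorted((_cm(lo), _cm(hi)))
    return c_m, (ends[0], ends[1])
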