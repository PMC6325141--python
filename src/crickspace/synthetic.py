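"""Synthetic datasets with the statistical structure the pipeline assumes.

Every input the analysis consumes can be generated here with known ground
truth: gene tables in Crick space observed through Poisson sequencing noise,
per-gene protein-noise labels, clone-library competitions and copy-number
titration series. Generators always return the planted truth alongside the
observable table, and are bit-reproducible given a seed.

The gene generator samples protein abundance lognormally (about three
decades of spread, as observed in rapidly growing cells) and relative
translation strengths log-uniformly over ``beta_p_decades`` decades, then
rescales globally so the truth obeys the whole-cell budgets the rate
estimator anchors to (sum of mRNAs = N_m, sum of proteins = N_p).
Transcription rates follow from supplying each protein abundance at steady
state. The ``hard-boundary`` mode instead samples
translation/transcription ratios log-uniformly above a planted boundary
``k_true``, reproducing the depleted region; the budgets then determine the
ratio spread, which is solved for rather than chosen. Sequencing reads are Poisson draws with
expectations proportional to mRNA copy number (mRNA-seq) and to
protein-synthesis flux (ribosome profiling); gene lengths are held constant
so RPKMs are proportional to counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import CellularConstants
from .exceptions import InfeasibleSpecError, InvalidParameterError

__all__ = [
    "GeneTableSpec",
    "CloneLibrarySpec",
    "generate_gene_table",
    "generate_cv_labels",
    "generate_clone_library",
    "generate_titration_series",
]


@dataclass(frozen=True)
class GeneTableSpec:
    """Specification of a synthetic gene table in Crick space."""

    n_genes: int = 5000
    k_true: float | None = None          # planted boundary ratio (hard-boundary mode)
    depletion_mode: str = "none"         # "none" | "hard-boundary"
    beta_p_max: float | None = None      # optional validation cap on translation rates
    beta_p_decades: float = 3.0          # translation spread; ignored in hard-boundary mode
    log10_p_mean: float = 4.0            # lognormal protein abundance, log10 units
    log10_p_sd: float = 0.8
    seq_depth_mrna: float = 5e6          # total mRNA-seq reads
    seq_depth_rp: float = 5e6            # total ribosome-profiling reads
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise InvalidParameterError("n_genes must be at least 2")
        if self.seq_depth_mrna <= 0 or self.seq_depth_rp <= 0:
            raise InvalidParameterError("sequencing depths must be strictly positive")
        if self.depletion_mode not in ("none", "hard-boundary"):
            raise InvalidParameterError(f"unknown depletion_mode {self.depletion_mode!r}")
        if self.depletion_mode == "hard-boundary" and not (self.k_true and self.k_true > 0):
            raise InvalidParameterError("hard-boundary mode requires a positive k_true")


@dataclass(frozen=True)
class CloneLibrarySpec:
    """Specification of a synthetic clone-competition library."""

    n_clones: int = 1000
    t_cm: float = 4.0e-2     # planted composite mRNA cost, per mRNA
    t_cp: float = 2.2e-6     # planted composite protein cost, per protein
    log10_m_range: tuple[float, float] = (0.0, 2.0)
    log10_p_range: tuple[float, float] = (3.0, 6.0)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        if self.n_clones < 2:
            raise InvalidParameterError("n_clones must be at least 2")


def _sample_crick_points(spec: GeneTableSpec, consts: CellularConstants,
                         rng: np.random.Generator):
    """Sample (p, beta_p) subject to budgets and the optional hard boundary.

    The rate estimator anchors relative measurements to the whole-cell
    budgets, so a consistent ground truth must satisfy sum(m) = N_m and
    sum(p) = N_p exactly. Protein abundances are drawn lognormally and pinned
    to the protein budget. Without a planted boundary, relative translation
    strengths are log-uniform and the mRNA budget sets their scale. With a
    hard boundary, translation/transcription ratios are log-uniform above
    ``k_true`` and the budgets leave no freedom in the ratio spread, which is
    solved from the mRNA-budget equation instead.
    """
    n = spec.n_genes
    p_raw = 10.0 ** rng.normal(spec.log10_p_mean, spec.log10_p_sd, size=n)
    p = p_raw * (consts.N_p / p_raw.sum())

    if spec.depletion_mode == "hard-boundary":
        # Ratios are sampled log-uniformly above the planted boundary. With
        # both budgets fixed, the ratio spread d is no longer free: it is the
        # unique root of the mRNA-budget equation and is solved for here.
        k = spec.k_true
        v = rng.uniform(0.0, 1.0, size=n)
        root = np.sqrt(p * consts.alpha_p / (consts.alpha_m * k))

        def mrna_budget_gap(d: float) -> float:
            return float(np.sum(root * 10.0 ** (-0.5 * d * v))) - consts.N_m

        lo, hi = 1e-6, 12.0
        if mrna_budget_gap(lo) < 0:
            raise InfeasibleSpecError(
                f"k_true={k} exceeds what the whole-cell budgets allow for "
                f"n_genes={n}: even a zero-width ratio distribution cannot "
                "supply the organism's mRNA count"
            )
        if mrna_budget_gap(hi) > 0:
            raise InfeasibleSpecError(
                f"k_true={k} is too far below the budget-implied ratio scale: "
                "no ratio spread up to 12 decades closes the mRNA budget"
            )
        d = float(brentq(mrna_budget_gap, lo, hi, xtol=1e-12))
        ratio = k * 10.0 ** (d * v)
        m = np.sqrt(p * consts.alpha_p / (ratio * consts.alpha_m))
        beta_m = m * consts.alpha_m
        beta_p = ratio * beta_m
    else:
        # relative translation strengths, scale set by the protein budget
        u = 10.0 ** rng.uniform(-spec.beta_p_decades, 0.0, size=n)
        m_rel = p / u
        m = m_rel * (consts.N_m / m_rel.sum())
        beta_p = p * consts.alpha_p / m
        beta_m = m * consts.alpha_m

    if spec.beta_p_max is not None and beta_p.max() > spec.beta_p_max:
        raise InfeasibleSpecError(
            "the requested beta_p_max cap is incompatible with the whole-cell "
            "budgets for this specification"
        )
    return p, beta_p, beta_m


def generate_gene_table(spec: GeneTableSpec, consts: CellularConstants):
    """Generate ground-truth gene rates and their noisy sequencing observation.

    Returns ``(truth, measurements)``: ``truth`` has columns ``gene_id, m, p,
    beta_m, beta_p, alpha_m, alpha_p``; ``measurements`` has the observable
    columns ``gene_id, rpkm_mrna, rpkm_rp, reads_mrna, reads_rp``.
    """
    rng = np.random.default_rng(spec.seed)
    p, beta_p, beta_m = _sample_crick_points(spec, consts, rng)
    m = beta_m / consts.alpha_m
    gene_ids = np.array([f"g{i:05d}" for i in range(spec.n_genes)])

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "m": m,
            "p": p,
            "beta_m": beta_m,
            "beta_p": beta_p,
            "alpha_m": consts.alpha_m,
            "alpha_p": consts.alpha_p,
        }
    )

    lam_mrna = spec.seq_depth_mrna * m / m.sum()
    flux = beta_p * m  # protein synthesis flux, what RP footprints sample
    lam_rp = spec.seq_depth_rp * flux / flux.sum()
    reads_mrna = rng.poisson(lam_mrna)
    reads_rp = rng.poisson(lam_rp)

    measurements = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "rpkm_mrna": reads_mrna / spec.seq_depth_mrna * 1e6,
            "rpkm_rp": reads_rp / spec.seq_depth_rp * 1e6,
            "reads_mrna": reads_mrna,
            "reads_rp": reads_rp,
        }
    )
    return truth, measurements


def generate_cv_labels(
    truth: pd.DataFrame,
    consts: CellularConstants,
    extra_noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene protein CV labels from the phenomenological noise model.

    cv_i = sqrt(1/p_i + alpha_p/beta_m_i + cv0^2), multiplied by lognormal
    measurement scatter with log-sd ``extra_noise_sd`` (0 disables it).
    """
    if extra_noise_sd < 0:
        raise InvalidParameterError("extra_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    p = truth["p"].to_numpy(float)
    beta_m = truth["beta_m"].to_numpy(float)
    cv2 = 1.0 / p + consts.alpha_p / beta_m + consts.cv0**2
    cv = np.sqrt(cv2)
    if extra_noise_sd > 0:
        cv = cv * rng.lognormal(0.0, extra_noise_sd, size=cv.size)
    return pd.DataFrame({"gene_id": truth["gene_id"].to_numpy(), "cv": cv})


def generate_clone_library(spec: CloneLibrarySpec) -> pd.DataFrame:
    """Clone-competition records from the linear cost model.

    log_rel_abundance = -t_cp * p - t_cm * m + Gaussian(0, noise_sd).
    """
    rng = np.random.default_rng(spec.seed)
    m = 10.0 ** rng.uniform(*spec.log10_m_range, size=spec.n_clones)
    p = 10.0 ** rng.uniform(*spec.log10_p_range, size=spec.n_clones)
    y = -spec.t_cp * p - spec.t_cm * m + rng.normal(0.0, spec.noise_sd, size=spec.n_clones)
    return pd.DataFrame(
        {
            "clone_id": [f"c{i:05d}" for i in range(spec.n_clones)],
            "m": m,
            "p": p,
            "log_rel_abundance": y,
        }
    )


def generate_titration_series(
    copies,
    c_m: float,
    c_p: float,
    phi: float,
    p: float,
    beta_m: float,
    l_m: float,
    mu_0: float,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Copy-number titration tables for the full and DAmP constructs.

    The relative growth rate falls as mu/mu0 = 1 - n*s with
    s_N = (c_p*p + c_m*l_m*beta_m) / mu_0 for the full construct and
    s_D = (c_p*phi*p + c_m*l_m*beta_m) / mu_0 for the destabilized one,
    plus Gaussian noise. Returns ``(full_table, damp_table, truth)`` where
    ``truth`` records the exact slopes.
    """
    if not 0 < phi < 1:
        raise InvalidParameterError("phi must lie strictly inside (0, 1)")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = np.asarray(copies, dtype=float)
    s_N = (c_p * p + c_m * l_m * beta_m) / mu_0
    s_D = (c_p * phi * p + c_m * l_m * beta_m) / mu_0
    full = pd.DataFrame(
        {"copies": n, "rel_growth": 1.0 - n * s_N + rng.normal(0.0, noise_sd, n.size)}
    )
    damp = pd.DataFrame(
        {"copies": n, "rel_growth": 1.0 - n * s_D + rng.normal(0.0, noise_sd, n.size)}
    )
    return full, damp, {"s_N": s_N, "s_D": s_D}
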