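"""Absolute transcription and translation rates from omics tables.

mRNA-seq RPKMs give each gene's share of the cell's mRNA pool; ribosome
profiling (RP) RPKMs give its share of the protein-synthesis flux. Anchoring
those shares to the whole-cell totals N_m (mRNAs per cell) and N_p * alpha_p
(proteins synthesized per hour) converts relative abundances into absolute
per-gene rates:

    m_i      = N_m * r_i / sum_j r_j
    beta_m,i = m_i * alpha_m
    beta_p,i = (N_p * alpha_p / m_i) * s_i / sum_j s_j

with r_i the mRNA-seq RPKM and s_i the RP RPKM. Genes with too few reads are
discarded first: Poisson counting noise puts the sampling error on log10
abundance below ``epsilon`` only when n > (1 / (10**epsilon - 1))**2 reads.

The expected input is a table (TSV/CSV or DataFrame) with columns
``gene_id, rpkm_mrna, rpkm_rp, reads_mrna, reads_rp`` and optional per-gene
``alpha_m, alpha_p`` overrides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CellularConstants
from .exceptions import DegenerateInputError, EmptyTableError, InvalidParameterError

__all__ = [
    "FilterConfig",
    "min_reads_for_error",
    "apply_filters",
    "estimate_rates",
    "percentile_align",
    "read_measurement_table",
]

MEASUREMENT_COLUMNS = ["gene_id", "rpkm_mrna", "rpkm_rp", "reads_mrna", "reads_rp"]


@dataclass
class FilterConfig:
    """Coverage and blacklist filters applied before rate estimation.

    Defaults reproduce the operational thresholds used on the published
    datasets (10 mRNA-seq reads, 20 RP reads); ``from_epsilon`` derives both
    thresholds from a target log10-abundance error instead.
    """

    min_reads_mrna: int = 10
    min_reads_rp: int = 20
    blacklist: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.min_reads_mrna < 0 or self.min_reads_rp < 0:
            raise InvalidParameterError("read thresholds must be non-negative")
        self.blacklist = frozenset(self.blacklist)

    @classmethod
    def from_epsilon(cls, epsilon: float, blacklist=()) -> "FilterConfig":
        n_min = min_reads_for_error(epsilon)
        return cls(min_reads_mrna=n_min, min_reads_rp=n_min, blacklist=frozenset(blacklist))


def min_reads_for_error(epsilon: float) -> int:
    """Minimum read count keeping Poisson error on log10 abundance below epsilon.

    With n reads and Poisson noise sigma = sqrt(n), requiring
    log10((n + sigma)/n) < epsilon gives n > (1 / (10**epsilon - 1))**2;
    the ceiling of that bound is returned (at least 1).
    """
    if not epsilon > 0:
        raise InvalidParameterError("epsilon must be strictly positive")
    bound = (1.0 / (10.0**epsilon - 1.0)) ** 2
    return max(math.ceil(bound), 1)


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    """Read a gene measurement table from TSV (default) or CSV."""
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep)
    missing = set(MEASUREMENT_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidParameterError(f"measurement table lacks columns: {sorted(missing)}")
    return table


def _validate_measurements(table: pd.DataFrame) -> pd.DataFrame:
    if len(table) == 0:
        raise EmptyTableError("measurement table is empty")
    missing = set(MEASUREMENT_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidParameterError(f"measurement table lacks columns: {sorted(missing)}")
    if (table["rpkm_mrna"] < 0).any() or (table["rpkm_rp"] < 0).any():
        raise InvalidParameterError("RPKMs must be non-negative")
    if (table["reads_mrna"] < 0).any() or (table["reads_rp"] < 0).any():
        raise InvalidParameterError("read counts must be non-negative")
    return table


def apply_filters(table: pd.DataFrame, cfg: FilterConfig | None = None):
    """Drop low-coverage and blacklisted genes.

    Returns ``(retained, report)`` where ``report`` maps exclusion reason
    (``low_mrna_coverage``, ``low_rp_coverage``, ``blacklist``) to the number
    of genes excluded for that reason (first matching reason wins) and
    ``report["retained"]`` counts the survivors. The returned table carries
    an ``excluded_reason`` column ("" for retained genes) covering all input
    genes under ``report["table"]``.
    """
    cfg = cfg or FilterConfig()
    table = _validate_measurements(table).copy()

    reason = np.full(len(table), "", dtype=object)
    in_blacklist = table["gene_id"].isin(cfg.blacklist).to_numpy()
    low_mrna = (table["reads_mrna"] < cfg.min_reads_mrna).to_numpy()
    low_rp = (table["reads_rp"] < cfg.min_reads_rp).to_numpy()
    reason[low_rp] = "low_rp_coverage"
    reason[low_mrna] = "low_mrna_coverage"
    reason[in_blacklist] = "blacklist"
    table["excluded_reason"] = reason

    retained = table[reason == ""].drop(columns="excluded_reason").reset_index(drop=True)
    if len(retained) == 0:
        raise EmptyTableError("no gene passes the coverage filters")
    report = {
        "blacklist": int(in_blacklist.sum()),
        "low_mrna_coverage": int((reason == "low_mrna_coverage").sum()),
        "low_rp_coverage": int((reason == "low_rp_coverage").sum()),
        "retained": int(len(retained)),
        "table": table,
    }
    return retained, report


def estimate_rates(
    table: pd.DataFrame,
    consts: CellularConstants,
    normalize: str = "post-filter",
    unfiltered: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Estimate absolute per-gene rates from a filtered measurement table.

    Normalization sums run over the retained genes (``normalize="post-filter"``,
    the default) or over an ``unfiltered`` table (``normalize="pre-filter"``).
    Per-gene ``alpha_m`` / ``alpha_p`` columns, when present, override the
    organism medians. Genes with zero mRNA RPKM cannot be placed in rate space
    and are dropped with a warning.

    Returns a DataFrame with columns ``gene_id, m, p, beta_m, beta_p,
    log10_beta_m, log10_beta_p, alpha_m, alpha_p``.
    """
    table = _validate_measurements(table)
    if normalize not in ("post-filter", "pre-filter"):
        raise InvalidParameterError(f"unknown normalization mode {normalize!r}")

    zero_r = (table["rpkm_mrna"] == 0).to_numpy()
    if zero_r.any():
        warnings.warn(
            f"dropping {int(zero_r.sum())} retained gene(s) with zero mRNA RPKM",
            stacklevel=2,
        )
        table = table[~zero_r].reset_index(drop=True)
    if len(table) == 0:
        raise EmptyTableError("no gene with positive mRNA abundance")

    norm_table = table if normalize == "post-filter" else _validate_measurements(unfiltered)
    sum_r = float(norm_table["rpkm_mrna"].sum())
    sum_s = float(norm_table["rpkm_rp"].sum())
    if sum_r <= 0 or sum_s <= 0:
        raise InvalidParameterError("normalization sums must be strictly positive")

    alpha_m = table.get("alpha_m", pd.Series(consts.alpha_m, index=table.index)).to_numpy(float)
    alpha_p = table.get("alpha_p", pd.Series(consts.alpha_p, index=table.index)).to_numpy(float)

    m = consts.N_m * table["rpkm_mrna"].to_numpy(float) / sum_r
    beta_m = m * alpha_m
    # share s_i / sum(s) of the cellwide protein synthesis flux N_p * alpha_p,
    # expressed per mRNA copy
    beta_p = (consts.N_p * alpha_p / m) * table["rpkm_rp"].to_numpy(float) / sum_s
    p = beta_m * beta_p / (alpha_m * alpha_p)

    with np.errstate(divide="ignore"):
        out = pd.DataFrame(
            {
                "gene_id": table["gene_id"].to_numpy(),
                "m": m,
                "p": p,
                "beta_m": beta_m,
                "beta_p": beta_p,
                "log10_beta_m": np.log10(beta_m),
                "log10_beta_p": np.log10(beta_p),
                "alpha_m": alpha_m,
                "alpha_p": alpha_p,
            }
        )
    return out


def percentile_align(
    relative_beta_m: np.ndarray,
    relative_beta_p: np.ndarray,
    reference: pd.DataFrame,
    q: float = 99.0,
):
    """Place relative construct measurements on the absolute rate scale.

    Synthetic construct libraries report transcription proportional to mRNA
    level and translation proportional to the protein/mRNA ratio, each up to
    an unknown factor. Assuming the strongest constructs rival the strongest
    natural genes, each axis is rescaled so its q-th percentile matches the
    q-th percentile of the reference ``beta_m`` (resp. ``beta_p``).

    Returns ``(aligned_beta_m, aligned_beta_p, scale_m, scale_p)``.
    """
    if not 0 < q < 100:
        raise InvalidParameterError("q must lie in (0, 100)")
    rel_m = np.asarray(relative_beta_m, dtype=float)
    rel_p = np.asarray(relative_beta_p, dtype=float)
    if rel_m.size == 0 or len(reference) == 0:
        raise EmptyTableError("both construct and reference sets must be non-empty")
    if rel_m.size > 1 and (np.ptp(rel_m) == 0 or np.ptp(rel_p) == 0):
        raise DegenerateInputError("zero-variance construct axis: alignment undefined")
    ref_m = np.percentile(reference["beta_m"].to_numpy(float), q)
    ref_p = np.percentile(reference["beta_p"].to_numpy(float), q)
    con_m = np.percentile(rel_m, q)
    con_p = np.percentile(rel_p, q)
    if con_m <= 0 or con_p <= 0:
        raise DegenerateInputError("construct percentiles must be strictly positive")
    scale_m = ref_m / con_m
    scale_p = ref_p / con_p
    return rel_m * scale_m, rel_p * scale_p, scale_m, scale_p
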