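"""Organism-level cellular constants.

A :class:`CellularConstants` object bundles the handful of whole-cell numbers
that the rate-estimation and boundary-prediction machinery needs: total mRNA
and protein copy numbers, growth and decay rates, the protein-noise floor, and
the maximal translation rate. Four presets covering the organisms commonly
profiled under rapid growth (budding yeast, E. coli, mouse 3T3 fibroblasts,
human HeLa cells) ship with the package as commented YAML files.

All rates are stored per hour. Half-lives given in minutes convert as
``rate = 60 * ln(2) / half_life_min``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exceptions import InvalidParameterError

__all__ = [
    "CellularConstants",
    "load_constants",
    "preset_names",
    "PRESET_FILES",
]

#: preset name -> bundled YAML file
PRESET_FILES = {
    "s_cerevisiae": "s_cerevisiae.yaml",
    "yeast": "s_cerevisiae.yaml",
    "e_coli": "e_coli.yaml",
    "m_musculus": "m_musculus.yaml",
    "mouse": "m_musculus.yaml",
    "h_sapiens": "h_sapiens.yaml",
    "human": "h_sapiens.yaml",
}

# Published constants are rounded to 2-3 significant figures, so derived
# identities (alpha_p = alpha_deg + mu, total transcription = N_m * alpha_m)
# only close to within that rounding.
_ROUNDING_RTOL = 0.02


@dataclass(frozen=True)
class CellularConstants:
    """Whole-cell parameters of one organism under one growth condition.

    Parameters
    ----------
    N_m, N_p
        Total mRNA and protein copies per cell.
    mu
        Growth (dilution) rate, h^-1.
    alpha_m
        Median mRNA decay rate, h^-1.
    alpha_deg
        Protein degradation rate, h^-1 (dilution excluded).
    alpha_p
        Protein decay rate, h^-1; defaults to ``alpha_deg + mu``.
    cv0
        Noise floor: minimal coefficient of variation of protein abundance
        in clonal populations.
    l_m
        Typical (pre-)mRNA length, nt.
    total_transcription
        Combined transcriptional output of all genes (sum of beta_m), mRNA
        h^-1; defaults to ``N_m * alpha_m``.
    v, footprint_nt
        Ribosome elongation speed (aa s^-1) and footprint (nt); optional,
        used to derive the mechanistic maximal translation rate.
    beta_p_max
        Maximal translation rate, protein mRNA^-1 h^-1 (in the presets: the
        top percentile of measured translation rates).
    rho
        Fraction of the growth rate a single gene can contribute to fitness
        (1 for essential genes, < 1 otherwise).
    reference
        Published reference values (measured/predicted boundary intercepts
        and their standard errors). Metadata only; nothing computes from it.
    """

    organism_label: str
    N_m: float
    N_p: float
    mu: float
    alpha_m: float
    alpha_deg: float
    cv0: float
    l_m: float
    beta_p_max: float
    alpha_p: float | None = None
    total_transcription: float | None = None
    v: float | None = None
    footprint_nt: float | None = None
    rho: float = 1.0
    reference: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alpha_p is None:
            object.__setattr__(self, "alpha_p", self.alpha_deg + self.mu)
        if self.total_transcription is None:
            object.__setattr__(self, "total_transcription", self.N_m * self.alpha_m)
        for name in ("N_m", "N_p", "mu", "alpha_m", "alpha_p", "cv0", "l_m",
                     "beta_p_max", "total_transcription"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")
        if self.alpha_deg < 0:
            raise InvalidParameterError("alpha_deg must be non-negative")
        if not 0 < self.cv0 < 1:
            raise InvalidParameterError(f"cv0 must lie in (0, 1), got {self.cv0}")
        if not 0 < self.rho <= 1:
            raise InvalidParameterError(f"rho must lie in (0, 1], got {self.rho}")
        expected_ap = self.alpha_deg + self.mu
        if abs(self.alpha_p - expected_ap) > _ROUNDING_RTOL * expected_ap:
            raise InvalidParameterError(
                f"alpha_p={self.alpha_p} inconsistent with alpha_deg + mu = {expected_ap:.4g}"
            )
        expected_tt = self.N_m * self.alpha_m
        if abs(self.total_transcription - expected_tt) > _ROUNDING_RTOL * expected_tt:
            raise InvalidParameterError(
                f"total_transcription={self.total_transcription} inconsistent with "
                f"N_m * alpha_m = {expected_tt:.4g}"
            )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "CellularConstants":
        known = {f for f in cls.__dataclass_fields__}
        data = {k: v for k, v in mapping.items() if k in known}
        unknown = set(mapping) - known
        if unknown:
            raise InvalidParameterError(f"unknown constants keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CellularConstants":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def with_rho(self, rho: float) -> "CellularConstants":
        """Copy of these constants with a different fitness-contribution fraction."""
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["rho"] = rho
        return CellularConstants(**data)


def preset_names() -> list[str]:
    """Canonical names of the bundled organism presets."""
    return ["s_cerevisiae", "e_coli", "m_musculus", "h_sapiens"]


def load_constants(name_or_path: str | Path) -> CellularConstants:
    """Load cellular constants from a preset name or a YAML/JSON file path.

    ``load_constants("yeast")`` and ``load_constants("s_cerevisiae")`` both
    resolve to the bundled S. cerevisiae preset; any other string is treated
    as a path.
    """
    key = str(name_or_path).lower()
    if key in PRESET_FILES:
        ref = resources.files("crickspace.data") / PRESET_FILES[key]
        return CellularConstants.from_mapping(yaml.safe_load(ref.read_text()))
    return CellularConstants.from_yaml(name_or_path)
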