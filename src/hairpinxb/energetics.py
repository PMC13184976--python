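"""Boltzmann energetics and interaction-energy bookkeeping.

The folded-population shift between a halogen-bond-capable compound and
its interaction-free reference estimates the interaction's contribution
to folding stability.  Two conventions are offered:

* ``population_ratio``:  ddG = -RT ln(p / p_ref)   (default)
* ``odds_ratio``:        ddG = -RT ln[(p/(1-p)) / (p_ref/(1-p_ref))]

with R = 8.314 J mol^-1 K^-1 and T in Kelvin; results in kJ mol^-1.
Relative DFT dimer energies are pure reference subtraction, and the
correlation report relates relative energies to halogen-bonded
populations by Pearson and Spearman coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DomainError, LabelingError

R_GAS = 8.314  # J mol^-1 K^-1


@dataclass(frozen=True)
class EnergeticsConfig:
    R: float = R_GAS
    T: float = 298.15  # K
    convention: str = "population_ratio"  # or "odds_ratio"

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ConfigError("temperature must be positive")
        if self.convention not in ("population_ratio", "odds_ratio"):
            raise ConfigError(f"unknown convention {self.convention!r}")


@dataclass
class DimerEnergyRecord:
    """One model dimer: label, interaction energy, energy vs reference."""

    label: str
    dE: float  # kJ mol^-1
    ddE: float = float("nan")  # kJ mol^-1, filled by relative_energies


def boltzmann_ddg(
    p: float, p_ref: float, cfg: EnergeticsConfig = EnergeticsConfig()
) -> float:
    """Stabilization free energy (kJ/mol) from two folded fractions.

    Negative values mean the test compound folds more than the reference.
    Fractions must lie strictly inside (0, 1).
    """
    for val in (p, p_ref):
        if not (0.0 < val < 1.0):
            raise DomainError(f"folded fraction {val} outside (0, 1)")
    rt = cfg.R * cfg.T / 1000.0  # kJ/mol
    if cfg.convention == "population_ratio":
        return float(-rt * math.log(p / p_ref))
    return float(-rt * math.log((p / (1 - p)) / (p_ref / (1 - p_ref))))


def inverse_boltzmann(
    ddg: float, p_ref: float, cfg: EnergeticsConfig = EnergeticsConfig()
) -> float:
    """Folded fraction implied by a ddG against a reference fraction."""
    if not (0.0 < p_ref < 1.0):
        raise DomainError(f"reference fraction {p_ref} outside (0, 1)")
    rt = cfg.R * cfg.T / 1000.0
    x = math.exp(-ddg / rt)
    if cfg.convention == "population_ratio":
        return float(p_ref * x)
    odds = (p_ref / (1 - p_ref)) * x
    return float(odds / (1 + odds))


def relative_energies(
    records: Sequence[DimerEnergyRecord] | Sequence[tuple[str, float]],
    reference_label: str,
) -> list[DimerEnergyRecord]:
    """Fill ddE = dE - dE(reference) for a set of dimer energies."""
    recs = [
        r if isinstance(r, DimerEnergyRecord) else DimerEnergyRecord(r[0], float(r[1]))
        for r in records
    ]
    ref = [r for r in recs if r.label == reference_label]
    if len(ref) != 1:
        raise LabelingError(
            f"reference label {reference_label!r} must appear exactly once"
        )
    e_ref = ref[0].dE
    return [DimerEnergyRecord(r.label, r.dE, r.dE - e_ref) for r in recs]


def fold_ratio(p: float, p_ref: float) -> tuple[float, str]:
    """Fold change p / p_ref with a nearest-integer rendering for reports."""
    if p_ref <= 0:
        raise DomainError("reference fraction must be positive")
    ratio = p / p_ref
    return float(ratio), f"{round(ratio):d}-fold"


def local_sensitivity(
    p: float, cfg: EnergeticsConfig = EnergeticsConfig()
) -> float:
    """Percent change in folded population per kJ/mol at population p.

    dp/d(ddG) of the chosen convention, reported as percentage points per
    kJ mol^-1 (positive = stabilization increases folding).
    """
    if not (0.0 < p < 1.0):
        raise DomainError(f"folded fraction {p} outside (0, 1)")
    rt = cfg.R * cfg.T / 1000.0
    if cfg.convention == "population_ratio":
        return float(100.0 * p / rt)
    return float(100.0 * p * (1.0 - p) / rt)


def correlation_report(
    dde: Sequence[float], xb_percent: Sequence[float]
) -> dict[str, float | str]:
    """Pearson/Spearman correlation of relative energies vs XB populations.

    The relation between computed dimer energies and fitted halogen-bonded
    populations is expected to be monotone but not necessarily linear, so
    both coefficients are reported with that caveat attached.
    """
    x = np.asarray(dde, dtype=float)
    y = np.asarray(xb_percent, dtype=float)
    if x.shape != y.shape:
        raise LabelingError("energy and population lists differ in length")
    if len(x) < 3:
        raise ConfigError("need at least 3 points for a correlation report")
    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "spearman_rho": float(spearman.statistic),
        "spearman_p": float(spearman.pvalue),
        "caveat": (
            "monotone association expected; the energy-population relation "
            "need not be linear"
        ),
    }
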