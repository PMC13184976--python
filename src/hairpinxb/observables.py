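"""NMR observable reduction and forward models.

Three observable kinds drive the ensemble analysis:

* **NOE buildups** — cross-peak intensity vs. mixing time.  Under the
  isolated spin pair approximation the initial buildup rate sigma scales
  as r^-6, so an unknown distance follows from internal referencing to a
  pair of fixed, known separation (geminal methylene protons, 1.78 A):
  ``r = r_ref * (sigma_ref / sigma)**(1/6)``.
* **3J(NH-HAlpha) couplings** — related to the backbone phi torsion by the
  Karplus curve ``J = A cos^2(theta) + B cos(theta) + C`` with
  ``theta = phi + phase``.
* **1H-13C RDCs** — obtained as the difference between the one-bond
  coupling measured on the aligned (compressed-gel) and isotropic sample,
  ``D = T_strong - T_weak``.

Forward models predict population-averaged observables from a conformer
pool and a weight vector: NOE distances average as <r^-6>^{-1/6} (a
<r^-3> variant is available), J couplings average linearly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    ConfigError,
    DegenerateGeometryError,
    FormatError,
    InsufficientDataError,
)
from .structures import Conformer, ConformerPool, Selector, backbone_phi, distance

#: reference distance between geminal methylene protons, Angstrom
GEMINAL_REFERENCE_DISTANCE = 1.78


@dataclass
class MixingSeries:
    """One NOE buildup: intensities over increasing mixing times."""

    pair: tuple[Selector, Selector]
    mixing_times: np.ndarray  # seconds, strictly increasing
    intensities: np.ndarray  # arbitrary units
    reference_flag: bool = False  # marks the geminal calibration pair

    def __post_init__(self) -> None:
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mixing_times.shape != self.intensities.shape:
            raise ConfigError("mixing_times and intensities length mismatch")
        if len(self.mixing_times) < 3:
            raise InsufficientDataError("a buildup series needs >= 3 time points")
        if np.any(np.diff(self.mixing_times) <= 0):
            raise ConfigError("mixing times must be strictly increasing")


@dataclass
class NoeDistanceRestraint:
    """Calibrated interproton distance with the rate it came from."""

    pair: tuple[Selector, Selector]
    r_obs: float  # Angstrom
    error: float  # Angstrom
    sigma: float = float("nan")  # buildup rate, intensity * s^-1

    def __post_init__(self) -> None:
        if self.r_obs <= 0:
            raise ConfigError("NOE distance must be positive")
        if self.error <= 0:
            raise ConfigError("NOE distance error must be positive")


@dataclass
class JRestraint:
    residue: int
    j_obs: float  # Hz
    error: float  # Hz

    def __post_init__(self) -> None:
        if self.error <= 0:
            raise ConfigError("J restraint error must be positive")


@dataclass(frozen=True)
class KarplusCoefficients:
    """J(phi) = A cos^2(phi + phase) + B cos(phi + phase) + C, in Hz.

    The default is a standard HN-HA parameterization; the coefficients are
    fully configurable because published sets differ by several tenths of
    a Hz.
    """

    A: float = 6.51
    B: float = -1.76
    C: float = 1.60
    phase: float = -60.0  # degrees


@dataclass
class CouplingPair:
    """One-bond C-H total couplings with and without gel compression."""

    pair: tuple[Selector, Selector]
    t_strong: float  # Hz, aligned sample
    t_weak: float  # Hz, isotropic sample


@dataclass
class RdcRestraint:
    pair: tuple[Selector, Selector]  # (C, H) selectors
    d_obs: float  # Hz
    error: float  # Hz

    def __post_init__(self) -> None:
        if self.error <= 0:
            raise ConfigError("RDC error must be positive")


# ---------------------------------------------------------------------------
# data reduction
# ---------------------------------------------------------------------------

def fit_buildup(series: MixingSeries, through_origin: bool = False) -> float:
    """Buildup rate: slope of intensity vs. mixing time.

    Ordinary least squares with a free intercept by default (robust to
    baseline offsets); ``through_origin=True`` forces the line through 0.
    """
    t = series.mixing_times
    y = series.intensities
    if through_origin:
        return float(np.dot(t, y) / np.dot(t, t))
    slope, _intercept = np.polyfit(t, y, 1)
    return float(slope)


def rate_to_distance(
    sigma: float, sigma_ref: float, r_ref: float = GEMINAL_REFERENCE_DISTANCE
) -> float:
    """Distance from a buildup rate by internal r^-6 referencing."""
    if sigma <= 0 or sigma_ref <= 0:
        raise CalibrationError("buildup rates must be positive for calibration")
    return float(r_ref * (sigma_ref / sigma) ** (1.0 / 6.0))


def distance_to_rate(
    r: float, sigma_ref: float, r_ref: float = GEMINAL_REFERENCE_DISTANCE
) -> float:
    """Inverse of :func:`rate_to_distance`; used by the forward simulator."""
    if r <= 0:
        raise CalibrationError("distance must be positive")
    return float(sigma_ref * (r_ref / r) ** 6)


def reduce_noe_series(
    series: Sequence[MixingSeries],
    r_ref: float = GEMINAL_REFERENCE_DISTANCE,
    rel_error: float = 0.10,
    rate_rel_error: float | None = None,
    through_origin: bool = False,
) -> list[NoeDistanceRestraint]:
    """Turn buildup series into calibrated distance restraints.

    Exactly one series must carry ``reference_flag``; its rate anchors the
    calibration.  Restraint errors default to ``rel_error`` (10%) of the
    distance, the fallback used when no per-peak error estimate exists.
    When the relative uncertainty of the buildup rates themselves is known
    pass ``rate_rel_error``; it propagates through the sixth-root
    calibration as dr/r = (dsigma/sigma)/6, which weights the restraints
    far more sharply than the distance-level fallback.
    """
    if rate_rel_error is not None:
        rel_error = rate_rel_error / 6.0
    refs = [s for s in series if s.reference_flag]
    if len(refs) != 1:
        raise CalibrationError(
            f"need exactly one reference buildup series, found {len(refs)}"
        )
    sigma_ref = fit_buildup(refs[0], through_origin=through_origin)
    if sigma_ref <= 0:
        raise CalibrationError("reference buildup rate is non-positive")
    out = []
    for s in series:
        if s.reference_flag:
            continue
        sigma = fit_buildup(s, through_origin=through_origin)
        if sigma <= 0:
            continue  # vanished cross peak: no usable distance
        r = rate_to_distance(sigma, sigma_ref, r_ref)
        out.append(NoeDistanceRestraint(s.pair, r, rel_error * r, sigma))
    return out


def karplus_j(phi: float, k: KarplusCoefficients = KarplusCoefficients()) -> float:
    """Three-bond coupling from the backbone phi torsion (degrees -> Hz)."""
    theta = np.radians(phi + k.phase)
    c = np.cos(theta)
    return float(k.A * c * c + k.B * c + k.C)


def rdc_from_couplings(cp: CouplingPair) -> RdcRestraint:
    """RDC as the aligned-minus-isotropic coupling difference."""
    d = cp.t_strong - cp.t_weak
    return RdcRestraint(cp.pair, float(d), max(abs(d) * 0.10, 0.1))


# ---------------------------------------------------------------------------
# population-averaged forward models
# ---------------------------------------------------------------------------

def _check_weights(weights: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ConfigError(f"weight vector length {w.shape} != pool size {n}")
    if np.any(w < -1e-12):
        raise ConfigError("population weights must be nonnegative")
    s = w.sum()
    if not np.isclose(s, 1.0, atol=1e-6):
        raise ConfigError(f"population weights must sum to 1 (got {s:.6g})")
    return np.clip(w, 0.0, None)


def predict_noe_distance(
    pool: ConformerPool,
    weights: np.ndarray,
    pair: tuple[Selector, Selector],
    exponent: int = 6,
) -> float:
    """Effective NOE distance <r^-n>^{-1/n} over the weighted pool (n=6)."""
    w = _check_weights(weights, len(pool))
    r = np.array([distance(c, pair[0], pair[1]) for c in pool])
    if np.any(r <= 1e-9):
        raise DegenerateGeometryError("zero interproton distance in pool")
    return float(np.sum(w * r ** (-float(exponent))) ** (-1.0 / exponent))


def predict_j(
    pool: ConformerPool,
    weights: np.ndarray,
    residue: int,
    k: KarplusCoefficients = KarplusCoefficients(),
) -> float:
    """Population-averaged Karplus coupling for one residue's phi."""
    w = _check_weights(weights, len(pool))
    vals = np.array([karplus_j(backbone_phi(c, residue), k) for c in pool])
    return float(np.dot(w, vals))


# ---------------------------------------------------------------------------
# table I/O (CSV, long format)
# ---------------------------------------------------------------------------

def write_noe_series_csv(series: Sequence[MixingSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        (ri, ai), (rj, aj) = s.pair
        for t, inten in zip(s.mixing_times, s.intensities):
            rows.append(
                dict(
                    res_i=ri, atom_i=ai, res_j=rj, atom_j=aj,
                    mixing_time=t, intensity=inten,
                    is_reference=int(s.reference_flag),
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_noe_series_csv(path: str | Path) -> list[MixingSeries]:
    df = pd.read_csv(path)
    required = {"res_i", "atom_i", "res_j", "atom_j", "mixing_time", "intensity"}
    if not required.issubset(df.columns):
        raise FormatError(f"NOE series table missing columns {required - set(df.columns)}")
    out = []
    keys = ["res_i", "atom_i", "res_j", "atom_j"]
    for (ri, ai, rj, aj), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("mixing_time")
        ref = bool(grp["is_reference"].iloc[0]) if "is_reference" in grp else False
        out.append(
            MixingSeries(
                ((int(ri), str(ai)), (int(rj), str(aj))),
                grp["mixing_time"].to_numpy(),
                grp["intensity"].to_numpy(),
                ref,
            )
        )
    return out


def write_j_csv(restraints: Sequence[JRestraint], path: str | Path) -> None:
    pd.DataFrame(
        [dict(residue=r.residue, j_obs=r.j_obs, error=r.error) for r in restraints]
    ).to_csv(path, index=False)


def read_j_csv(path: str | Path) -> list[JRestraint]:
    df = pd.read_csv(path)
    if not {"residue", "j_obs"}.issubset(df.columns):
        raise FormatError("J table must have 'residue' and 'j_obs' columns")
    out = []
    for _, row in df.iterrows():
        err = float(row["error"]) if "error" in df.columns else abs(row["j_obs"]) * 0.10
        out.append(JRestraint(int(row["residue"]), float(row["j_obs"]), err))
    return out


def write_rdc_csv(restraints: Sequence[RdcRestraint], path: str | Path) -> None:
    rows = []
    for r in restraints:
        (ri, ai), (rj, aj) = r.pair
        rows.append(
            dict(res_c=ri, atom_c=ai, res_h=rj, atom_h=aj, d_obs=r.d_obs, error=r.error)
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rdc_csv(path: str | Path) -> list[RdcRestraint]:
    """Read an RDC table; accepts either a ``d_obs`` column or the raw
    ``t_strong``/``t_weak`` coupling pair columns."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        pair = (
            (int(row["res_c"]), str(row["atom_c"])),
            (int(row["res_h"]), str(row["atom_h"])),
        )
        if "d_obs" in df.columns:
            err = float(row["error"]) if "error" in df.columns else max(
                abs(float(row["d_obs"])) * 0.10, 0.1
            )
            out.append(RdcRestraint(pair, float(row["d_obs"]), err))
        elif {"t_strong", "t_weak"}.issubset(df.columns):
            cp = CouplingPair(pair, float(row["t_strong"]), float(row["t_weak"]))
            r = rdc_from_couplings(cp)
            if "error" in df.columns:
                r.error = float(row["error"])
            out.append(r)
        else:
            raise FormatError("RDC table needs 'd_obs' or 't_strong'/'t_weak' columns")
    return out
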