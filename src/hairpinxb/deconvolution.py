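"""Backbone-stage ensemble deconvolution.

Population-averaged NOE distances and 3J couplings are linear in the
conformer populations once NOE distances are mapped to r^-6 space, so the
fit is a weighted non-negative least-squares problem

    min || W (A p - y) ||^2 + lambda^2 (sum(p) - 1)^2,   p >= 0,

solved by NNLS on the system augmented with a soft unit-sum row.  The
recovered populations are renormalized to sum exactly to one and the
folded fraction is the summed weight of conformers passing the hairpin
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .errors import ConfigError, LabelingError, SingularFitError
from .observables import (
    JRestraint,
    KarplusCoefficients,
    NoeDistanceRestraint,
    karplus_j,
)
from .structures import ConformerPool, backbone_phi, distance

#: weighted design matrices with condition numbers beyond this are flagged
CONDITION_LIMIT = 1e8


@dataclass
class ObservableMatrix:
    """Linearized restraint system: one row per restraint, one column per
    conformer.  NOE rows live in r^-6 space (value = r^-6, error propagated
    as 6 r^-7 dr); J rows are raw Hz."""

    A: np.ndarray  # (n_rows, n_conformers) predicted values
    y: np.ndarray  # (n_rows,) observed values, same space as A
    w: np.ndarray  # (n_rows,) weights = 1 / transformed error
    kinds: list[str]  # "noe" | "j" | "rdc" per row
    row_meta: list[object] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        n_rows = self.A.shape[0]
        if self.y.shape != (n_rows,) or self.w.shape != (n_rows,):
            raise ConfigError("ObservableMatrix row dimensions disagree")
        if len(self.kinds) != n_rows:
            raise ConfigError("kinds length must equal the number of rows")
        if np.any(self.w <= 0):
            raise ConfigError("row weights must be positive")

    @property
    def n_conformers(self) -> int:
        return self.A.shape[1]


@dataclass
class PopulationFit:
    populations: np.ndarray  # nonnegative, summing to 1
    rmsd_by_kind: dict[str, float]  # natural units (A for NOE, Hz for J/RDC)
    sum_deviation: float  # |sum(p) - 1| before renormalization
    condition_flag: bool
    condition_number: float


def build_design_matrix(
    pool: ConformerPool,
    noe: Sequence[NoeDistanceRestraint] = (),
    j: Sequence[JRestraint] = (),
    k: KarplusCoefficients = KarplusCoefficients(),
) -> ObservableMatrix:
    """Assemble the linear system from NOE and J restraints.

    NOE restraints are transformed to r^-6 so population averaging is
    linear; the restraint error dr propagates to the transformed space as
    6 r^-7 dr.  J restraints enter untransformed via the Karplus curve of
    each conformer's phi.
    """
    if not noe and not j:
        raise ConfigError("need at least one restraint to build a design matrix")
    rows, obs, wts, kinds, meta = [], [], [], [], []
    for r in noe:
        pred = np.array([distance(c, r.pair[0], r.pair[1]) ** -6 for c in pool])
        rows.append(pred)
        obs.append(r.r_obs ** -6)
        wts.append(1.0 / (6.0 * r.r_obs ** -7 * r.error))
        kinds.append("noe")
        meta.append(r)
    for restr in j:
        pred = np.array([karplus_j(backbone_phi(c, restr.residue), k) for c in pool])
        rows.append(pred)
        obs.append(restr.j_obs)
        wts.append(1.0 / restr.error)
        kinds.append("j")
        meta.append(restr)
    return ObservableMatrix(
        np.array(rows), np.array(obs), np.array(wts), kinds, meta
    )


def nnls_unit_sum(
    A: np.ndarray, y: np.ndarray, w: np.ndarray, lambda_sum: float
) -> tuple[np.ndarray, float]:
    """Weighted NNLS with a soft unit-sum constraint row.

    Returns the raw (unnormalized) solution and |sum(p) - 1|.
    """
    Aw = A * w[:, None]
    yw = y * w
    A_aug = np.vstack([Aw, np.full((1, A.shape[1]), lambda_sum)])
    y_aug = np.concatenate([yw, [lambda_sum]])
    p, _ = nnls(A_aug, y_aug)
    return p, float(abs(p.sum() - 1.0))


def fit_populations(
    m: ObservableMatrix, lambda_sum: float | None = None
) -> PopulationFit:
    """Non-negative least-squares deconvolution of conformer populations.

    ``lambda_sum`` defaults to 10x the largest row weight, a soft penalty
    strong enough to pin the total population near one without distorting
    the data rows; the result is renormalized to sum exactly to one.
    """
    if not np.any(m.A != 0):
        raise SingularFitError("design matrix is identically zero")
    if lambda_sum is None:
        lambda_sum = 10.0 * float(np.max(m.w))
    if lambda_sum <= 0:
        raise ConfigError("lambda_sum must be positive")
    p_raw, sum_dev = nnls_unit_sum(m.A, m.y, m.w, lambda_sum)
    total = p_raw.sum()
    if total <= 0:
        raise SingularFitError("NNLS returned an all-zero population vector")
    p = p_raw / total

    sv = np.linalg.svd(m.A * m.w[:, None], compute_uv=False)
    rank_deficient = sv[-1] < sv[0] * 1e-12 or len(sv) < m.n_conformers
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    flag = bool(rank_deficient or cond > CONDITION_LIMIT)

    resid = _residuals_by_kind(m, p)
    return PopulationFit(p, resid, sum_dev, flag, cond)


def _residuals_by_kind(m: ObservableMatrix, p: np.ndarray) -> dict[str, float]:
    """RMS residuals in natural units: NOE rows back-transformed to A."""
    pred = m.A @ p
    out: dict[str, float] = {}
    kinds = np.array(m.kinds)
    for kind in sorted(set(m.kinds)):
        mask = kinds == kind
        if kind == "noe":
            # clip guards bootstrap-perturbed rows that strayed below zero
            r_pred = np.clip(pred[mask], 1e-12, None) ** (-1.0 / 6.0)
            r_obs = np.clip(m.y[mask], 1e-12, None) ** (-1.0 / 6.0)
            out[kind] = float(np.sqrt(np.mean((r_pred - r_obs) ** 2)))
        else:
            out[kind] = float(np.sqrt(np.mean((pred[mask] - m.y[mask]) ** 2)))
    return out


def folded_fraction(fit: PopulationFit, labels: Sequence[bool]) -> float:
    """Folded beta-hairpin population in percent."""
    labels = np.asarray(labels, dtype=bool)
    if labels.shape != fit.populations.shape:
        raise LabelingError(
            f"label length {labels.shape} != population length {fit.populations.shape}"
        )
    return float(100.0 * fit.populations[labels].sum())


def bootstrap_populations(
    m: ObservableMatrix,
    labels: Sequence[bool],
    n_boot: int,
    seed: int,
    lambda_sum: float | None = None,
) -> np.ndarray:
    """Residual-resampling bootstrap distribution of folded fractions.

    Weighted residuals of the base fit are resampled with replacement and
    added back to the fitted observables; each perturbed system is refit.
    Deterministic for a given seed.
    """
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    labels = np.asarray(labels, dtype=bool)
    if labels.shape[0] != m.n_conformers:
        raise LabelingError("label length does not match the pool size")
    base = fit_populations(m, lambda_sum)
    y_hat = m.A @ base.populations
    resid_w = (m.y - y_hat) * m.w
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(resid_w), size=len(resid_w))
        y_star = y_hat + resid_w[idx] / m.w
        m_star = ObservableMatrix(m.A, y_star, m.w, list(m.kinds))
        try:
            fit_star = fit_populations(m_star, lambda_sum)
            out[b] = folded_fraction(fit_star, labels)
        except SingularFitError:
            out[b] = np.nan
    return out
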