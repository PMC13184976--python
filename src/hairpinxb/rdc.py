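"""Side-chain stage: SVD alignment-tensor fitting against 1H-13C RDCs.

A residual dipolar coupling of a C-H bond with unit direction b under an
alignment described by the traceless symmetric Saupe matrix S is linear
in the five independent tensor components,

    D = S_yy (b_y^2 - b_x^2) + S_zz (b_z^2 - b_x^2)
        + 2 S_xy b_x b_y + 2 S_xz b_x b_z + 2 S_yz b_y b_z,

with the dipolar prefactor absorbed into the tensor scale.  Five or more
independent RDCs determine the tensor by linear least squares (SVD); the
condition number of the design matrix gauges how well the bond
orientations span the five dimensions (CN < 30 is considered robust).

For a conformer mixture a single common tensor is shared by all
conformers and the design matrix is population-averaged.  The joint
problem (tensor x populations) is bilinear and solved by alternating the
SVD tensor update with an NNLS population update under nonnegativity and
a soft unit-sum constraint, tracking the Cornilescu quality factor

    Q = rms(D_obs - D_calc) / rms(D_obs),

with Q < 0.3 a good and Q < 0.4 an acceptable fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .deconvolution import nnls_unit_sum
from .errors import (
    ConfigError,
    ConvergenceError,
    DegenerateGeometryError,
    DomainError,
    InsufficientDataError,
    LabelingError,
    SingularFitError,
)
from .observables import RdcRestraint
from .structures import Conformer, ConformerPool, Selector

#: condition numbers at or above this mark the tensor as unreliable
CN_UNRELIABLE = 30.0
#: Q-factor classification thresholds
Q_GOOD = 0.3
Q_ACCEPTABLE = 0.4


@dataclass
class SaupeTensor:
    """Five independent components (S_yy, S_zz, S_xy, S_xz, S_yz) of the
    traceless symmetric order matrix, dipolar prefactor absorbed."""

    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (5,) or not np.all(np.isfinite(self.s)):
            raise ConfigError("SaupeTensor needs 5 finite components")

    def to_matrix(self) -> np.ndarray:
        syy, szz, sxy, sxz, syz = self.s
        return np.array(
            [
                [-syy - szz, sxy, sxz],
                [sxy, syy, syz],
                [sxz, syz, szz],
            ]
        )

    @classmethod
    def from_matrix(cls, S: np.ndarray) -> "SaupeTensor":
        S = np.asarray(S, dtype=float)
        if S.shape != (3, 3) or abs(np.trace(S)) > 1e-9 * max(
            np.linalg.norm(S), 1e-30
        ):
            raise ConfigError("matrix must be 3x3 and traceless")
        return cls(np.array([S[1, 1], S[2, 2], S[0, 1], S[0, 2], S[1, 2]]))

    def scaled(self, factor: float) -> "SaupeTensor":
        return SaupeTensor(self.s * factor)


@dataclass
class RdcFit:
    tensor: SaupeTensor
    populations: np.ndarray
    q: float  # Cornilescu quality factor
    cn: float  # condition number of the averaged design matrix
    d_calc: np.ndarray  # back-calculated RDCs, Hz
    reliable: bool  # cn < 30
    q_class: str  # "good" | "acceptable" | "poor"
    n_iter: int = 0

    @property
    def unreliable(self) -> bool:
        return not self.reliable


def _q_class(q: float) -> str:
    if q < Q_GOOD:
        return "good"
    if q < Q_ACCEPTABLE:
        return "acceptable"
    return "poor"


def rdc_design_row(bond: np.ndarray) -> np.ndarray:
    """Five coefficients mapping Saupe components to the RDC of a bond."""
    b = np.asarray(bond, dtype=float)
    n = np.linalg.norm(b)
    if n < 1e-9:
        raise DegenerateGeometryError("zero-length bond vector for RDC row")
    bx, by, bz = b / n
    return np.array(
        [by * by - bx * bx, bz * bz - bx * bx, 2 * bx * by, 2 * bx * bz, 2 * by * bz]
    )


def bond_vector(c: Conformer, pair: tuple[Selector, Selector]) -> np.ndarray:
    """Unit vector along the C->H bond of an RDC pair."""
    v = c.position(pair[1]) - c.position(pair[0])
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegenerateGeometryError(f"coincident atoms in RDC pair {pair}")
    return v / n


def conformer_design(c: Conformer, pairs: Sequence[tuple[Selector, Selector]]) -> np.ndarray:
    """(n_pairs, 5) design block of one conformer."""
    return np.array([rdc_design_row(bond_vector(c, p)) for p in pairs])


def _check_weights(weights: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ConfigError("population vector length does not match pool size")
    if np.any(w < -1e-12) or not np.isclose(w.sum(), 1.0, atol=1e-6):
        raise ConfigError("populations must be nonnegative and sum to 1")
    return np.clip(w, 0.0, None)


def predict_rdc(
    pool: ConformerPool,
    weights: np.ndarray,
    tensor: SaupeTensor,
    pairs: Sequence[tuple[Selector, Selector]],
) -> np.ndarray:
    """Population-averaged back-calculated RDCs under one common tensor."""
    w = _check_weights(weights, len(pool))
    G = np.zeros((len(pairs), 5))
    for wk, c in zip(w, pool):
        G += wk * conformer_design(c, pairs)
    return G @ tensor.s


def svd_fit_tensor(
    pool: ConformerPool,
    weights: np.ndarray,
    rdcs: Sequence[RdcRestraint],
) -> tuple[SaupeTensor, float]:
    """Least-squares Saupe tensor for fixed populations, via SVD.

    Returns the tensor and the condition number (ratio of extreme singular
    values) of the weighted population-averaged design matrix.
    """
    if len(rdcs) < 5:
        raise InsufficientDataError(
            f"alignment tensor determination needs >= 5 RDCs, got {len(rdcs)}"
        )
    w = _check_weights(weights, len(pool))
    pairs = [r.pair for r in rdcs]
    G = np.zeros((len(pairs), 5))
    for wk, c in zip(w, pool):
        G += wk * conformer_design(c, pairs)
    row_w = np.array([1.0 / r.error for r in rdcs])
    d_obs = np.array([r.d_obs for r in rdcs])
    Gw = G * row_w[:, None]
    dw = d_obs * row_w
    U, sv, Vt = np.linalg.svd(Gw, full_matrices=False)
    if sv[-1] < sv[0] * 1e-10:
        raise SingularFitError(
            "RDC design matrix is rank deficient (bond vectors not independent)"
        )
    s = Vt.T @ ((U.T @ dw) / sv)
    return SaupeTensor(s), float(sv[0] / sv[-1])


def q_factor(d_obs: np.ndarray, d_calc: np.ndarray) -> float:
    """Cornilescu quality factor rms(D_obs - D_calc) / rms(D_obs)."""
    d_obs = np.asarray(d_obs, dtype=float)
    d_calc = np.asarray(d_calc, dtype=float)
    if d_obs.shape != d_calc.shape:
        raise ConfigError("d_obs and d_calc length mismatch")
    denom = np.sqrt(np.mean(d_obs ** 2))
    if denom == 0:
        raise DomainError("Q factor undefined for all-zero observations")
    return float(np.sqrt(np.mean((d_obs - d_calc) ** 2)) / denom)


def fit_tensor_and_populations(
    pool: ConformerPool,
    rdcs: Sequence[RdcRestraint],
    init: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-12,
    lambda_sum: float | None = None,
    n_starts: int = 6,
    group_constraints: Sequence[tuple[np.ndarray, float]] = (),
) -> RdcFit:
    """Joint alignment-tensor / population fit by alternating optimization.

    Each cycle solves the SVD tensor update for the current populations,
    then the NNLS population update (nonnegative, soft unit-sum) for the
    current tensor, accepting steps while Q decreases.  The bilinear
    problem can have local minima, so in addition to the uniform start
    (or a caller-supplied ``init``) a deterministic set of vertex and
    Dirichlet starting points is tried and the lowest-Q solution kept.

    ``group_constraints`` pins summed populations of conformer subsets
    (boolean mask, target fraction) via soft augmented rows — used by the
    staged pipeline to hold the backbone-determined folded total fixed
    while the side-chain orientations are redistributed.
    """
    n = len(pool)
    if len(rdcs) < 5:
        raise InsufficientDataError(
            f"alignment tensor determination needs >= 5 RDCs, got {len(rdcs)}"
        )
    d_obs = np.array([r.d_obs for r in rdcs])
    row_w = np.array([1.0 / r.error for r in rdcs])
    pairs = [r.pair for r in rdcs]
    blocks = np.stack([conformer_design(c, pairs) for c in pool])  # (n, m, 5)
    if lambda_sum is None:
        lambda_sum = 10.0 * float(np.max(row_w))

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(_check_weights(np.asarray(init, dtype=float), n))
    starts.append(np.full(n, 1.0 / n))
    if n > 1:
        for k in range(min(n, max(0, n_starts - 2))):
            v = np.full(n, 0.5 / max(n - 1, 1))
            v[k] = 0.5 + 0.5 / n
            starts.append(v / v.sum())
        rng = np.random.default_rng(0)
        while len(starts) < n_starts + (init is not None):
            starts.append(rng.dirichlet(np.ones(n)))

    constraints = [
        (np.asarray(mask, dtype=float), float(target))
        for mask, target in group_constraints
    ]
    for mask, _ in constraints:
        if mask.shape != (n,):
            raise ConfigError("group constraint mask length != pool size")

    best: RdcFit | None = None
    last_trace: list[float] = []
    for p0 in starts:
        try:
            fit = _alternate(
                blocks, d_obs, row_w, p0, max_iter, tol, lambda_sum, constraints
            )
        except ConvergenceError as exc:
            last_trace = exc.q_trace
            continue
        if best is None or fit.q < best.q:
            best = fit
    if best is None:
        raise ConvergenceError(
            "alternating tensor/population fit failed to converge", last_trace
        )
    return best


def _alternate(
    blocks: np.ndarray,
    d_obs: np.ndarray,
    row_w: np.ndarray,
    p0: np.ndarray,
    max_iter: int,
    tol: float,
    lambda_sum: float,
    constraints: Sequence[tuple[np.ndarray, float]] = (),
) -> RdcFit:
    n = blocks.shape[0]
    p = p0.copy()
    q_trace: list[float] = []
    best = None  # (q, s, p, cn, d_calc, it)
    for it in range(max_iter):
        G = np.tensordot(p, blocks, axes=(0, 0))  # (m, 5)
        Gw = G * row_w[:, None]
        U, sv, Vt = np.linalg.svd(Gw, full_matrices=False)
        if sv[-1] < sv[0] * 1e-12:
            raise SingularFitError("averaged RDC design matrix is rank deficient")
        s = Vt.T @ ((U.T @ (d_obs * row_w)) / sv)
        cn = float(sv[0] / sv[-1])

        # population update for fixed tensor: columns are per-conformer RDCs
        M = (blocks @ s).T  # (m, n)
        M_fit, d_fit, w_fit = M, d_obs, row_w
        if constraints:
            extra_rows = np.array([mask for mask, _ in constraints])
            extra_y = np.array([target for _, target in constraints])
            M_fit = np.vstack([M, extra_rows])
            d_fit = np.concatenate([d_obs, extra_y])
            w_fit = np.concatenate([row_w, np.full(len(constraints), lambda_sum)])
        p_new, _ = nnls_unit_sum(M_fit, d_fit, w_fit, lambda_sum)
        total = p_new.sum()
        if total <= 0:
            raise SingularFitError("population update collapsed to zero")
        p_new = p_new / total

        d_calc = M @ p_new
        q = q_factor(d_obs, d_calc)
        q_trace.append(q)
        if best is None or q < best[0] - 1e-15:
            best = (q, s, p_new, cn, d_calc, it + 1)
            p = p_new
        else:
            break  # Q stopped decreasing: converged (or started oscillating)
        if len(q_trace) >= 2 and abs(q_trace[-2] - q_trace[-1]) < tol:
            break
    if best is None:
        raise ConvergenceError("no accepted iteration in alternating fit", q_trace)
    q, s, p, cn, d_calc, n_iter = best
    return RdcFit(
        tensor=SaupeTensor(s),
        populations=p,
        q=q,
        cn=cn,
        d_calc=d_calc,
        reliable=cn < CN_UNRELIABLE,
        q_class=_q_class(q),
        n_iter=n_iter,
    )


def xb_population(fit: RdcFit, xb_labels: Sequence[bool]) -> float:
    """Halogen-bonded population in percent."""
    labels = np.asarray(xb_labels, dtype=bool)
    if labels.shape != fit.populations.shape:
        raise LabelingError("xb label length does not match the population vector")
    return float(100.0 * fit.populations[labels].sum())
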