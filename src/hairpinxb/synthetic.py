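"""Synthetic hairpin ensembles with known ground truth.

This module stands in for the conformational-search and NMR-acquisition
stages of a real study: it builds an idealized 12-residue beta-hairpin
with a central D-Pro-Gly type II' turn, cross-strand halogen-bond donor
(halo-imidazole) and acceptor ((thio)ether) side chains, samples folded
and unfolded conformer pools around it, and forward-simulates noisy NOE
buildup series, 3J couplings and RDCs from a known population vector and
alignment tensor.

Residues are alanine-like three-heavy-atom backbones (N, CA, C) with
amide H, carbonyl O and HAlpha; only the two interaction side chains
carry full heavy-atom detail.  All stochastic operations are pure
functions of their inputs and an explicit seed.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .classify import (
    VdwTable,
    XbCriteria,
    classify_folded,
    classify_xb,
    default_hairpin_criteria,
)
from .errors import (
    ConfigError,
    ConstructionError,
    EnrichmentError,
)
from .observables import (
    JRestraint,
    KarplusCoefficients,
    MixingSeries,
    RdcRestraint,
    distance_to_rate,
    karplus_j,
    predict_noe_distance,
)
from .rdc import SaupeTensor, conformer_design
from .structures import (
    Atom,
    Conformer,
    ConformerPool,
    Selector,
    backbone_phi,
    backbone_psi,
    dihedral_points,
)

# ---------------------------------------------------------------------------
# ideal covalent geometry (Angstrom / degrees)
# ---------------------------------------------------------------------------

_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_B_C_O, _B_N_H, _B_C_H = 1.231, 1.010, 1.090
_B_C_C = 1.525
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O = 120.8
_OMEGA = 180.0
# half-angle between paired tetrahedral substituents; chosen so the two
# geminal HAlpha protons (C-H 1.09 A) sit exactly at the 1.78 A NOE
# calibration distance: 2 * 1.09 * sin(theta) = 1.78
_TETRA_HALF = float(np.degrees(np.arcsin(0.89 / 1.09)))  # 54.744 deg

#: covalent bond lengths from a ring/chain carbon to the donor atom X
_CX_BOND = {"Br": 1.89, "I": 2.10, "H": 1.08}
#: covalent bond lengths from a chain carbon to the acceptor atom Y
_CY_BOND = {"O": 1.41, "S": 1.81, "C": 1.52}

#: canonical type II' beta-turn torsions for turn residues i+1, i+2
TURN_TORSIONS = ((60.0, -120.0), (-80.0, 0.0))
#: idealized antiparallel beta-strand torsions used as the optimizer start
_STRAND_PHI, _STRAND_PSI = -139.0, 135.0

#: mixing times of the simulated NOE buildup series, seconds
MIXING_TIMES = np.arange(0.100, 0.701, 0.100)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic hairpin system.

    ``donor_element`` / ``acceptor_element`` mirror the compound series of
    the underlying model system: (Br, O), (Br, S), (I, O), (I, S) are
    halogen-bond-capable; (H, C) is the interaction-free reference.
    """

    n_residues: int = 12
    turn_position: int = 6  # residue index of the D-Pro turn inducer
    n_folded: int = 10
    n_unfolded: int = 10
    folded_fraction: float = 0.5  # ground-truth folded population
    dihedral_jitter: float = 8.0  # Gaussian sigma on backbone torsions, degrees
    sidechain_jitter: float = 40.0  # Gaussian sigma on side-chain torsions
    seed: int | None = None
    donor_element: str = "Br"
    acceptor_element: str = "O"
    donor_res: int = 4
    acceptor_res: int = 9

    def __post_init__(self) -> None:
        if self.n_residues < 6:
            raise ConfigError("need at least 6 residues for a hairpin")
        if not (2 <= self.turn_position <= self.n_residues - 2):
            raise ConfigError("turn must sit at an interior position")
        if self.n_folded < 0 or self.n_unfolded < 0:
            raise ConfigError("conformer counts must be nonnegative")
        if not (0.0 <= self.folded_fraction <= 1.0):
            raise ConfigError("folded_fraction must lie in [0, 1]")
        if self.donor_element not in _CX_BOND:
            raise ConfigError(f"unsupported donor element {self.donor_element!r}")
        if self.acceptor_element not in _CY_BOND:
            raise ConfigError(f"unsupported acceptor element {self.acceptor_element!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian observation noise, one level per observable kind."""

    noe_rate_rel: float = 0.05  # relative sigma on NOE buildup rates
    j_hz: float = 0.3  # absolute sigma on 3J couplings, Hz
    rdc_hz: float = 0.3  # absolute sigma on RDCs, Hz

    def __post_init__(self) -> None:
        if min(self.noe_rate_rel, self.j_hz, self.rdc_hz) < 0:
            raise ConfigError("noise levels must be nonnegative")


@dataclass
class GroundTruth:
    """What the generator knows and the fits must recover."""

    populations: np.ndarray
    tensor: SaupeTensor
    folded_labels: np.ndarray
    xb_labels: np.ndarray


@dataclass
class SyntheticObservables:
    noe_series: list[MixingSeries]
    j: list[JRestraint]
    rdc: list[RdcRestraint]


# ---------------------------------------------------------------------------
# internal-coordinate construction (NeRF)
# ---------------------------------------------------------------------------

def _place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position atom d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _tetra_pair(u1: np.ndarray, u2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two remaining tetrahedral directions at a center with unit bond
    directions u1, u2 already placed."""
    b = -(u1 + u2)
    b /= np.linalg.norm(b)
    p = np.cross(u1, u2)
    p /= np.linalg.norm(p)
    th = np.radians(_TETRA_HALF)
    return np.cos(th) * b + np.sin(th) * p, np.cos(th) * b - np.sin(th) * p


@dataclass
class _BuildParams:
    """Torsions that fully determine a toy conformer's coordinates."""

    phi: np.ndarray  # (n,) degrees; phi[0] unused
    psi: np.ndarray  # (n,) degrees; psi[-1] orients the final carbonyl
    donor_chis: np.ndarray  # (chi1, chi2)
    acceptor_chis: np.ndarray  # (chi1, chi2, chi3)

    def copy(self) -> "_BuildParams":
        return _BuildParams(
            self.phi.copy(), self.psi.copy(),
            self.donor_chis.copy(), self.acceptor_chis.copy(),
        )


def _build_backbone(phi: np.ndarray, psi: np.ndarray) -> dict[tuple[int, str], np.ndarray]:
    """Backbone N/CA/C/O/H coordinates from torsions (1-based residues)."""
    n_res = len(phi)
    xyz: dict[tuple[int, str], np.ndarray] = {}
    xyz[(1, "N")] = np.zeros(3)
    xyz[(1, "CA")] = np.array([_B_N_CA, 0.0, 0.0])
    th = np.radians(180.0 - _A_N_CA_C)
    xyz[(1, "C")] = xyz[(1, "CA")] + _B_CA_C * np.array([np.cos(th), np.sin(th), 0.0])
    for r in range(1, n_res):
        xyz[(r + 1, "N")] = _place(
            xyz[(r, "N")], xyz[(r, "CA")], xyz[(r, "C")], _B_C_N, _A_CA_C_N, psi[r - 1]
        )
        xyz[(r + 1, "CA")] = _place(
            xyz[(r, "CA")], xyz[(r, "C")], xyz[(r + 1, "N")], _B_N_CA, _A_C_N_CA, _OMEGA
        )
        xyz[(r + 1, "C")] = _place(
            xyz[(r, "C")], xyz[(r + 1, "N")], xyz[(r + 1, "CA")], _B_CA_C, _A_N_CA_C, phi[r]
        )
    for r in range(1, n_res + 1):
        xyz[(r, "O")] = _place(
            xyz[(r, "N")], xyz[(r, "CA")], xyz[(r, "C")], _B_C_O, _A_CA_C_O,
            psi[r - 1] + 180.0,
        )
    # amide hydrogens: planar N, H anti to the preceding carbonyl direction
    for r in range(2, n_res + 1):
        u1 = xyz[(r - 1, "C")] - xyz[(r, "N")]
        u1 /= np.linalg.norm(u1)
        u2 = xyz[(r, "CA")] - xyz[(r, "N")]
        u2 /= np.linalg.norm(u2)
        xyz[(r, "H")] = xyz[(r, "N")] - _B_N_H * (u1 + u2) / np.linalg.norm(u1 + u2)
    xyz[(1, "H")] = _place(xyz[(1, "C")], xyz[(1, "CA")], xyz[(1, "N")], _B_N_H, 118.0, 180.0)
    return xyz


def _ha_directions(xyz, r: int) -> tuple[np.ndarray, np.ndarray]:
    u1 = xyz[(r, "N")] - xyz[(r, "CA")]
    u1 /= np.linalg.norm(u1)
    u2 = xyz[(r, "C")] - xyz[(r, "CA")]
    u2 /= np.linalg.norm(u2)
    return _tetra_pair(u1, u2)


def _add_ch(xyz, center: tuple[int, str], nbr1, nbr2, name: str) -> None:
    """One tetrahedral-ish hydrogen on a side-chain carbon (for RDC bonds)."""
    c = xyz[center]
    u1 = xyz[nbr1] - c
    u1 /= np.linalg.norm(u1)
    u2 = xyz[nbr2] - c
    u2 /= np.linalg.norm(u2)
    d1, _ = _tetra_pair(u1, u2)
    xyz[(center[0], name)] = c + _B_C_H * d1


def _build_sidechains(
    xyz: dict, cfg: GeneratorConfig, donor_chis: np.ndarray, acceptor_chis: np.ndarray
) -> None:
    """Attach the halo-imidazole donor and (thio)ether acceptor side chains."""
    d, a = cfg.donor_res, cfg.acceptor_res
    # --- donor: CB-CG-(imidazole ring)-X -------------------------------
    _, d_side = _ha_directions(xyz, d)
    xyz[(d, "CB")] = xyz[(d, "CA")] + _B_C_C * d_side
    xyz[(d, "CG")] = _place(
        xyz[(d, "N")], xyz[(d, "CA")], xyz[(d, "CB")], 1.50, 114.0, donor_chis[0]
    )
    xyz[(d, "ND1")] = _place(
        xyz[(d, "CA")], xyz[(d, "CB")], xyz[(d, "CG")], 1.37, 126.0, donor_chis[1]
    )
    xyz[(d, "CE1")] = _place(
        xyz[(d, "CB")], xyz[(d, "CG")], xyz[(d, "ND1")], 1.37, 108.0, 180.0
    )
    xyz[(d, "NE2")] = _place(
        xyz[(d, "CG")], xyz[(d, "ND1")], xyz[(d, "CE1")], 1.37, 108.0, 0.0
    )
    xyz[(d, "CD2")] = _place(
        xyz[(d, "ND1")], xyz[(d, "CE1")], xyz[(d, "NE2")], 1.37, 108.0, 0.0
    )
    xyz[(d, "XD")] = _place(
        xyz[(d, "CE1")], xyz[(d, "NE2")], xyz[(d, "CD2")],
        _CX_BOND[cfg.donor_element], 126.0, 180.0,
    )
    _add_ch(xyz, (d, "CB"), (d, "CA"), (d, "CG"), "HB")
    # --- acceptor: CB-CG-Y-CD ------------------------------------------
    _, a_side = _ha_directions(xyz, a)
    xyz[(a, "CB")] = xyz[(a, "CA")] + _B_C_C * a_side
    xyz[(a, "CG")] = _place(
        xyz[(a, "N")], xyz[(a, "CA")], xyz[(a, "CB")], 1.52, 114.0, acceptor_chis[0]
    )
    xyz[(a, "Y")] = _place(
        xyz[(a, "CA")], xyz[(a, "CB")], xyz[(a, "CG")],
        _CY_BOND[cfg.acceptor_element], 112.0, acceptor_chis[1],
    )
    xyz[(a, "CD")] = _place(
        xyz[(a, "CB")], xyz[(a, "CG")], xyz[(a, "Y")],
        _CY_BOND[cfg.acceptor_element], 112.0, acceptor_chis[2],
    )
    _add_ch(xyz, (a, "CB"), (a, "CA"), (a, "CG"), "HB")
    _add_ch(xyz, (a, "CG"), (a, "CB"), (a, "Y"), "HG")


_SIDECHAIN_ORDER = {
    "donor": ("CB", "HB", "CG", "ND1", "CE1", "NE2", "CD2", "XD"),
    "acceptor": ("CB", "HB", "CG", "HG", "Y", "CD"),
}


def _residue_name(cfg: GeneratorConfig, r: int) -> str:
    if r == cfg.turn_position:
        return "DPR"
    if r == cfg.turn_position + 1:
        return "GLY"
    if r == cfg.donor_res:
        return "HIX"
    if r == cfg.acceptor_res:
        return "ETX"
    return "ALA"


def _element_of(name: str, cfg: GeneratorConfig) -> str:
    if name == "XD":
        return cfg.donor_element
    if name == "Y":
        return cfg.acceptor_element
    if name.startswith("H"):
        return "H"
    if name.startswith("N"):
        return "N"
    if name.startswith("O"):
        return "O"
    return "C"


def build_conformer(cfg: GeneratorConfig, params: _BuildParams, id: str = "model") -> Conformer:
    """Realize a conformer from backbone and side-chain torsions."""
    xyz = _build_backbone(params.phi, params.psi)
    gly = cfg.turn_position + 1
    for r in range(1, cfg.n_residues + 1):
        d1, d2 = _ha_directions(xyz, r)
        if r == gly:
            xyz[(r, "HA1")] = xyz[(r, "CA")] + _B_C_H * d1
            xyz[(r, "HA2")] = xyz[(r, "CA")] + _B_C_H * d2
        else:
            xyz[(r, "HA")] = xyz[(r, "CA")] + _B_C_H * d1
    _build_sidechains(xyz, cfg, params.donor_chis, params.acceptor_chis)

    atoms: list[Atom] = []
    for r in range(1, cfg.n_residues + 1):
        res_name = _residue_name(cfg, r)
        names = ["N", "H", "CA"]
        names += ["HA1", "HA2"] if r == gly else ["HA"]
        if r == cfg.donor_res:
            names += list(_SIDECHAIN_ORDER["donor"])
        elif r == cfg.acceptor_res:
            names += list(_SIDECHAIN_ORDER["acceptor"])
        names += ["C", "O"]
        for nm in names:
            atoms.append(Atom(nm, _element_of(nm, cfg), r, res_name, xyz[(r, nm)]))
    return Conformer(id, atoms)


def _params_from_conformer(c: Conformer, cfg: GeneratorConfig) -> _BuildParams:
    """Measure the build torsions back from an existing conformer."""
    n = cfg.n_residues
    phi = np.full(n, _STRAND_PHI)
    psi = np.full(n, _STRAND_PSI)
    for r in range(2, n + 1):
        phi[r - 1] = backbone_phi(c, r)
    for r in range(1, n):
        psi[r - 1] = backbone_psi(c, r)
    psi[n - 1] = dihedral_points(
        c.position((n, "N")), c.position((n, "CA")), c.position((n, "C")),
        c.position((n, "O")),
    ) - 180.0
    d, a = cfg.donor_res, cfg.acceptor_res
    donor_chis = np.array([
        dihedral_points(c.position((d, "N")), c.position((d, "CA")),
                        c.position((d, "CB")), c.position((d, "CG"))),
        dihedral_points(c.position((d, "CA")), c.position((d, "CB")),
                        c.position((d, "CG")), c.position((d, "ND1"))),
    ])
    acceptor_chis = np.array([
        dihedral_points(c.position((a, "N")), c.position((a, "CA")),
                        c.position((a, "CB")), c.position((a, "CG"))),
        dihedral_points(c.position((a, "CA")), c.position((a, "CB")),
                        c.position((a, "CG")), c.position((a, "Y"))),
        dihedral_points(c.position((a, "CB")), c.position((a, "CG")),
                        c.position((a, "Y")), c.position((a, "CD"))),
    ])
    return _BuildParams(phi, psi, donor_chis, acceptor_chis)


# ---------------------------------------------------------------------------
# folded template: backbone register optimization + side-chain posing
# ---------------------------------------------------------------------------

def _turn_indices(cfg: GeneratorConfig) -> tuple[int, int]:
    return cfg.turn_position, cfg.turn_position + 1


def _strand_residues(cfg: GeneratorConfig) -> list[int]:
    t1, t2 = _turn_indices(cfg)
    return [r for r in range(1, cfg.n_residues + 1) if r not in (t1, t2)]


#: pre-refined strand torsions of the default 12-residue, turn-at-6 hairpin
#: (the output of the register optimization below for that geometry)
_DEFAULT_FOLDED_PHI = (
    -139.0, -72.895, -127.273, -98.757, -141.414, 60.0,
    -80.0, -112.217, -158.278, -138.867, -143.934, -97.472,
)
_DEFAULT_FOLDED_PSI = (
    119.537, 107.964, 108.956, 135.773, 76.603, -120.0,
    0.0, 161.856, 144.366, 157.709, 116.4, 71.273,
)


@functools.lru_cache(maxsize=8)
def _folded_backbone(n_residues: int, turn_position: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Strand torsions that close the interstrand hydrogen-bond register.

    Starting from ideal antiparallel-strand torsions with the turn fixed
    at canonical type II' values, the strand (phi, psi) are refined so
    the six designated N...O=C contacts reach hydrogen-bond range and the
    cross-strand CA-CA register stays tight.  The default geometry uses a
    stored solution of the same refinement.
    """
    if (n_residues, turn_position) == (12, 6):
        return _DEFAULT_FOLDED_PHI, _DEFAULT_FOLDED_PSI
    cfg = GeneratorConfig(n_residues=n_residues, turn_position=turn_position)
    crit = default_hairpin_criteria(n_residues, turn_position)
    t1, t2 = _turn_indices(cfg)
    strand = _strand_residues(cfg)

    # variable layout: phi for strand residues except residue 1, psi for all
    phi_vars = [r for r in strand if r != 1]
    psi_vars = list(strand)

    def unpack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        phi = np.full(n_residues, _STRAND_PHI)
        psi = np.full(n_residues, _STRAND_PSI)
        phi[t1 - 1], psi[t1 - 1] = TURN_TORSIONS[0]
        phi[t2 - 1], psi[t2 - 1] = TURN_TORSIONS[1]
        for i, r in enumerate(phi_vars):
            phi[r - 1] = x[i]
        for i, r in enumerate(psi_vars):
            psi[r - 1] = x[len(phi_vars) + i]
        return phi, psi

    hbonded = {frozenset(p) for p in crit.hbond_pairs}
    # backbone heavy-atom pairs allowed closer than the generic clash floor:
    # only the designated cross-strand N...O hydrogen-bond contacts
    allowed_close = {frozenset(((d, "N"), (a, "O"))) for d, a in crit.hbond_pairs}
    heavy_names = ("N", "CA", "C", "O")
    clash_pairs = []
    for i in range(1, n_residues + 1):
        for j in range(i + 2, n_residues + 1):
            for ni in heavy_names:
                for nj in heavy_names:
                    key = frozenset(((i, ni), (j, nj)))
                    if key not in allowed_close:
                        clash_pairs.append(((i, ni), (j, nj)))

    def objective(x: np.ndarray) -> float:
        phi, psi = unpack(x)
        xyz = _build_backbone(phi, psi)
        pen = 0.0
        for dres, ares in crit.hbond_pairs:
            dist = np.linalg.norm(xyz[(dres, "N")] - xyz[(ares, "O")])
            pen += 2.0 * (dist - 2.95) ** 2
            # hinge keeps every designated bond inside hydrogen-bond range
            pen += 8.0 * max(0.0, dist - 3.25) ** 2
            h = xyz[(dres, "H")]
            v1 = xyz[(dres, "N")] - h
            v2 = xyz[(ares, "O")] - h
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            pen += (max(0.0, 155.0 - theta) / 25.0) ** 2
        # antiparallel-sheet CA register: ~5.4 A for H-bonded pairs,
        # ~4.7 A for the intervening non-H-bonded pairs
        for i, j in crit.ca_pairs:
            target = 5.4 if frozenset((i, j)) in hbonded else 4.7
            d = np.linalg.norm(xyz[(i, "CA")] - xyz[(j, "CA")])
            pen += 0.5 * (d - target) ** 2
        p = np.array([xyz[k] for pair in clash_pairs for k in pair])
        d = np.linalg.norm(p[0::2] - p[1::2], axis=1)
        pen += 4.0 * float(np.sum(np.clip(3.2 - d, 0.0, None) ** 2))
        base = np.concatenate([
            np.full(len(phi_vars), _STRAND_PHI), np.full(len(psi_vars), _STRAND_PSI)
        ])
        pen += 0.01 * float(np.mean(((x - base) / 90.0) ** 2))
        return pen

    x0 = np.concatenate([
        np.full(len(phi_vars), _STRAND_PHI), np.full(len(psi_vars), _STRAND_PSI)
    ])
    res = minimize(objective, x0, method="L-BFGS-B",
                   options={"maxiter": 800, "ftol": 1e-12})
    phi, psi = unpack(res.x)
    return tuple(phi), tuple(psi)


@functools.lru_cache(maxsize=16)
def _posed_sidechain_chis(
    n_residues: int, turn_position: int, donor_res: int, acceptor_res: int,
    donor_element: str, acceptor_element: str,
) -> tuple[tuple[float, float], tuple[float, float, float]]:
    """Side-chain torsions posing the donor/acceptor pair at XB contact.

    Coarse grid search over the five chi torsions followed by Nelder-Mead
    polish, targeting d(X...Y) ~ 0.9 sum(vdW) with a near-linear C-X...Y
    angle.  For the halogen-free reference the same pose geometry is used
    with the C-H / CH2 surrogates.
    """
    cfg = GeneratorConfig(
        n_residues=n_residues, turn_position=turn_position,
        donor_res=donor_res, acceptor_res=acceptor_res,
        donor_element=donor_element, acceptor_element=acceptor_element,
    )
    phi, psi = _folded_backbone(n_residues, turn_position)
    bb_phi, bb_psi = np.array(phi), np.array(psi)
    vdw = VdwTable()
    try:
        target_d = 0.9 * vdw.sum(donor_element, acceptor_element)
    except Exception:
        target_d = 3.0
    d, a = donor_res, acceptor_res

    base_xyz = _build_backbone(bb_phi, bb_psi)
    bb_heavy = [
        base_xyz[(r, nm)] for r in range(1, n_residues + 1) for nm in ("N", "CA", "C", "O")
    ]

    def pose_penalty(chis: np.ndarray) -> float:
        xyz = dict(base_xyz)
        _build_sidechains(xyz, cfg, chis[:2], chis[2:])
        x = xyz[(d, "XD")]
        y = xyz[(a, "Y")]
        cd2 = xyz[(d, "CD2")]
        dist = np.linalg.norm(x - y)
        v1 = cd2 - x
        v2 = y - x
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        pen = (dist - target_d) ** 2 + (max(0.0, 150.0 - theta) / 20.0) ** 2
        # soft clash of side-chain heavies against the backbone
        for nm_r, nm in ((d, "CG"), (d, "XD"), (a, "CG"), (a, "Y"), (a, "CD")):
            p = xyz[(nm_r, nm)]
            for q in bb_heavy:
                dq = np.linalg.norm(p - q)
                if dq < 2.4:
                    pen += (2.4 - dq) ** 2
        return pen

    grid = np.array([-144.0, -72.0, 0.0, 72.0, 144.0])
    best_x, best_f = None, np.inf
    for c1 in grid:
        for c2 in grid:
            for c3 in grid:
                for c4 in grid:
                    for c5 in grid:
                        x = np.array([c1, c2, c3, c4, c5])
                        f = pose_penalty(x)
                        if f < best_f:
                            best_x, best_f = x, f
    res = minimize(pose_penalty, best_x, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-4, "fatol": 1e-10})
    chis = res.x if res.fun < best_f else best_x
    return (float(chis[0]), float(chis[1])), (float(chis[2]), float(chis[3]), float(chis[4]))


def template_params(cfg: GeneratorConfig) -> _BuildParams:
    """Build torsions of the idealized folded, XB-posed template."""
    phi, psi = _folded_backbone(cfg.n_residues, cfg.turn_position)
    dchis, achis = _posed_sidechain_chis(
        cfg.n_residues, cfg.turn_position, cfg.donor_res, cfg.acceptor_res,
        cfg.donor_element, cfg.acceptor_element,
    )
    return _BuildParams(np.array(phi), np.array(psi), np.array(dchis), np.array(achis))


def build_folded_template(cfg: GeneratorConfig) -> Conformer:
    """Idealized folded hairpin with the donor/acceptor pair at contact.

    Guaranteed to pass the folded-hairpin classifier; raises
    :class:`ConstructionError` if the requested geometry cannot be closed.
    """
    params = template_params(cfg)
    c = build_conformer(cfg, params, id="template")
    c.labels.add("folded")
    c.labels.add("template")
    crit = default_hairpin_criteria(cfg.n_residues, cfg.turn_position)
    if not classify_folded(c, crit):
        raise ConstructionError(
            "template optimization failed to close the hairpin register "
            f"(n_residues={cfg.n_residues}, turn={cfg.turn_position})"
        )
    return c


def donor_selectors(cfg: GeneratorConfig) -> tuple[Selector, Selector]:
    """(C, X) selector pair of the covalent donor bond."""
    return ((cfg.donor_res, "CD2"), (cfg.donor_res, "XD"))


def acceptor_selector(cfg: GeneratorConfig) -> Selector:
    return (cfg.acceptor_res, "Y")


def _xb_label(c: Conformer, cfg: GeneratorConfig) -> bool:
    if cfg.donor_element not in ("Br", "I"):
        return False
    return classify_xb(
        c, donor_selectors(cfg), acceptor_selector(cfg),
        VdwTable(), XbCriteria(strict=False),
    )


# ---------------------------------------------------------------------------
# pool sampling
# ---------------------------------------------------------------------------

def _has_clash(c: Conformer, vdw: VdwTable, scale: float = 0.7) -> bool:
    """Steric clash: heavy atoms from non-adjacent residues closer than
    ``scale`` times the sum of their vdW radii."""
    heavy = [a for a in c.atoms if not a.is_hydrogen]
    coords = np.array([a.xyz for a in heavy])
    radii = np.array([vdw.radius(a.element) for a in heavy])
    res = np.array([a.res_index for a in heavy])
    dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    limit = scale * (radii[:, None] + radii[None, :])
    sep = np.abs(res[:, None] - res[None, :])
    mask = np.triu(sep >= 2, k=1)
    return bool(np.any(dmat[mask] < limit[mask]))


def sample_pool(cfg: GeneratorConfig) -> tuple[ConformerPool, GroundTruth]:
    """Sample a labeled conformer pool and its ground truth.

    Folded conformers are torsion-jittered copies of the template that
    still pass the folded classifier (re-jittered otherwise); unfolded
    conformers draw strand torsions uniformly from the beta/PPII basin
    with the turn kept canonical, rejected on steric clash or accidental
    folding.  Populations split ``folded_fraction`` evenly within each
    class; the alignment tensor is drawn once and scaled so the averaged
    RDCs span roughly the +-13 Hz range typical of a compressed-gel
    alignment.
    """
    if cfg.seed is None:
        raise ConfigError("sample_pool requires a seed")
    if cfg.n_folded + cfg.n_unfolded == 0:
        raise ConfigError("empty pool requested")
    rng = np.random.default_rng(cfg.seed)
    base = template_params(cfg)
    crit = default_hairpin_criteria(cfg.n_residues, cfg.turn_position)
    vdw = VdwTable()
    t1, t2 = _turn_indices(cfg)
    strand = _strand_residues(cfg)

    conformers: list[Conformer] = []
    for k in range(cfg.n_folded):
        for _attempt in range(80):
            p = base.copy()
            p.phi += rng.normal(0.0, cfg.dihedral_jitter, size=len(p.phi))
            p.psi += rng.normal(0.0, cfg.dihedral_jitter, size=len(p.psi))
            p.donor_chis += rng.normal(0.0, cfg.sidechain_jitter, size=2)
            p.acceptor_chis += rng.normal(0.0, cfg.sidechain_jitter, size=3)
            c = build_conformer(cfg, p, id=f"folded_{k}")
            if classify_folded(c, crit):
                c.labels.add("folded")
                conformers.append(c)
                break
        else:
            raise ConstructionError(
                f"could not jitter a folded conformer within tolerance "
                f"(jitter={cfg.dihedral_jitter} deg)"
            )
    for k in range(cfg.n_unfolded):
        for _attempt in range(200):
            p = base.copy()
            for r in strand:
                p.phi[r - 1] = rng.uniform(-180.0, -55.0)
                p.psi[r - 1] = rng.uniform(60.0, 180.0)
            p.donor_chis = rng.uniform(-180.0, 180.0, size=2)
            p.acceptor_chis = rng.uniform(-180.0, 180.0, size=3)
            c = build_conformer(cfg, p, id=f"unfolded_{k}")
            if _has_clash(c, vdw):
                continue
            if classify_folded(c, crit):
                continue
            conformers.append(c)
            break
        else:
            raise ConstructionError("could not sample a clash-free unfolded conformer")

    pool = ConformerPool(conformers)
    folded_labels = np.array(["folded" in c.labels for c in pool])
    xb_labels = np.array([_xb_label(c, cfg) for c in pool])

    populations = np.zeros(len(pool))
    nf, nu = cfg.n_folded, cfg.n_unfolded
    f = cfg.folded_fraction if (nf and nu) else (1.0 if nu == 0 else 0.0)
    if nf:
        populations[folded_labels] = f / nf
    if nu:
        populations[~folded_labels] = (1.0 - f) / nu
    populations /= populations.sum()

    tensor = _draw_tensor(pool, populations, rng)
    return pool, GroundTruth(populations, tensor, folded_labels, xb_labels)


def _draw_tensor(pool: ConformerPool, populations: np.ndarray, rng) -> SaupeTensor:
    s = rng.normal(0.0, 1.0, size=5)
    pairs = standard_rdc_pairs(pool[0])
    G = np.zeros((len(pairs), 5))
    for w, c in zip(populations, pool):
        G += w * conformer_design(c, pairs)
    d = G @ s
    peak = np.max(np.abs(d))
    if peak < 1e-12:
        raise ConstructionError("degenerate geometry: zero RDCs for any tensor")
    return SaupeTensor(s * 13.0 / peak)


# ---------------------------------------------------------------------------
# XB enrichment
# ---------------------------------------------------------------------------

def _resampled_rmsd(c1: Conformer, c2: Conformer, cfg: GeneratorConfig) -> float:
    """Heavy-atom RMSD over the two resampled interaction side chains,
    after Kabsch superposition on the backbone N/CA/C frame.

    Enrichment varies only these side chains, so redundancy is judged on
    them; whole-molecule RMSD would bury genuine pose differences under
    the unchanged backbone bulk.
    """
    from scipy.spatial.transform import Rotation

    bbsel = [(r, nm) for r in range(1, cfg.n_residues + 1) for nm in ("N", "CA", "C")]
    scsel = [
        a.key() for a in c1.atoms
        if a.res_index in (cfg.donor_res, cfg.acceptor_res)
        and not a.is_hydrogen and a.name not in ("N", "CA", "C", "O")
    ]
    x_bb = np.array([c1.position(s) for s in bbsel])
    y_bb = np.array([c2.position(s) for s in bbsel])
    xc, yc = x_bb.mean(axis=0), y_bb.mean(axis=0)
    rot, _ = Rotation.align_vectors(x_bb - xc, y_bb - yc)
    x_sc = np.array([c1.position(s) for s in scsel]) - xc
    y_sc = rot.apply(np.array([c2.position(s) for s in scsel]) - yc)
    return float(np.sqrt(np.mean(np.sum((x_sc - y_sc) ** 2, axis=1))))


def enrich_with_xb_conformers(
    pool: ConformerPool, cfg: GeneratorConfig, n: int, seed: int,
    rmsd_cutoff: float = 1.5,
) -> ConformerPool:
    """Append ``n`` conformers with constrained halogen-bond geometries.

    Side-chain torsions of folded pool members are resampled and locally
    refined until the XB distance/angle rule holds; appends within
    ``rmsd_cutoff`` RMSD of an earlier append (measured over the
    resampled side-chain heavy atoms after backbone superposition) are
    discarded as redundant.
    """
    if cfg.donor_element not in ("Br", "I"):
        raise EnrichmentError(
            f"donor element {cfg.donor_element!r} carries no sigma-hole; "
            "cannot constrain halogen-bond geometries"
        )
    if n < 1:
        raise ConfigError("n must be >= 1")
    folded_idx = [i for i, c in enumerate(pool) if "folded" in c.labels]
    if not folded_idx:
        crit = default_hairpin_criteria(cfg.n_residues, cfg.turn_position)
        folded_idx = [i for i, c in enumerate(pool) if classify_folded(c, crit)]
    if not folded_idx:
        raise EnrichmentError("pool contains no folded conformers to enrich from")

    rng = np.random.default_rng(seed)
    vdw = VdwTable()
    sum_vdw = vdw.sum(cfg.donor_element, cfg.acceptor_element)
    accepted: list[Conformer] = []
    attempts = 0
    max_attempts = 120 * n
    base_cache: dict[int, tuple[_BuildParams, dict]] = {}
    base_cycle: list[int] = []
    while len(accepted) < n and attempts < max_attempts:
        attempts += 1
        if not base_cycle:  # cycle folded bases in random order for diversity
            base_cycle = list(rng.permutation(folded_idx))
        idx = int(base_cycle.pop())
        if idx not in base_cache:
            params0 = _params_from_conformer(pool[idx], cfg)
            base_cache[idx] = (params0, _build_backbone(params0.phi, params0.psi))
        params, base_xyz = base_cache[idx]
        chis0 = rng.uniform(-180.0, 180.0, size=5)
        # vary the pose target inside the XB-allowed region so repeated
        # draws explore distinct contact geometries
        target_d = rng.uniform(0.82, 0.99) * sum_vdw
        target_a = rng.uniform(130.0, 172.0)

        def penalty(chis: np.ndarray) -> float:
            xyz = dict(base_xyz)
            _build_sidechains(xyz, cfg, chis[:2], chis[2:])
            x = xyz[(cfg.donor_res, "XD")]
            y = xyz[(cfg.acceptor_res, "Y")]
            cd2 = xyz[(cfg.donor_res, "CD2")]
            dist = np.linalg.norm(x - y)
            v1, v2 = cd2 - x, y - x
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            return (dist - target_d) ** 2 + (max(0.0, target_a - theta) / 20.0) ** 2

        res = minimize(penalty, chis0, method="Nelder-Mead",
                       options={"maxiter": 250, "fatol": 1e-8})
        p = params.copy()
        p.donor_chis = res.x[:2]
        p.acceptor_chis = res.x[2:]
        cand = build_conformer(cfg, p, id=f"xb_{len(accepted)}")
        if not _xb_label(cand, cfg):
            continue
        if any(_resampled_rmsd(cand, prev, cfg) < rmsd_cutoff for prev in accepted):
            continue
        cand.labels.update(pool[idx].labels - {"template"})
        cand.labels.add("xb_constrained")
        accepted.append(cand)
    if len(accepted) < n:
        raise EnrichmentError(
            f"could only construct {len(accepted)}/{n} XB-constrained "
            f"conformers in {max_attempts} attempts"
        )
    return pool.extended(accepted)


# ---------------------------------------------------------------------------
# restraint-set definitions and forward simulation
# ---------------------------------------------------------------------------

def _gly_residue(c: Conformer) -> int:
    for r, name in c.residue_names().items():
        if name == "GLY":
            return r
    raise ConfigError("pool topology has no GLY residue for the geminal reference")


def _turn_res(c: Conformer) -> int:
    for r, name in c.residue_names().items():
        if name == "DPR":
            return r
    raise ConfigError("pool topology has no DPR turn residue")


def _ha_name(c: Conformer, r: int) -> str:
    return "HA1" if c.has_atom((r, "HA1")) else "HA"


#: NOESY detectability horizon for simulated cross peaks, Angstrom
NOE_DETECTION_CUTOFF = 5.0


def standard_noe_pairs(
    c: Conformer,
) -> tuple[list[tuple[Selector, Selector]], tuple[Selector, Selector]]:
    """All backbone NH/HAlpha proton pairs, plus the geminal reference.

    Mirrors a real NOESY analysis in which every resolvable backbone
    amide/alpha cross peak is integrated; pairs outside the detection
    horizon are dropped later by :func:`simulate_observables` based on
    the population-averaged effective distance.
    """
    n = max(a.res_index for a in c.atoms)
    g = _gly_residue(c)
    reference = ((g, "HA1"), (g, "HA2"))
    protons: list[Selector] = []
    for r in range(1, n + 1):
        protons.append((r, "H"))
        protons.append((r, _ha_name(c, r)))
    pairs = [
        (protons[i], protons[j])
        for i in range(len(protons))
        for j in range(i + 1, len(protons))
    ]
    return pairs, reference


def standard_rdc_pairs(c: Conformer) -> list[tuple[Selector, Selector]]:
    """One CA-HA RDC per residue plus the three side-chain C-H bonds of
    the donor/acceptor side chains (15 for the default 12-mer)."""
    n = max(a.res_index for a in c.atoms)
    pairs = [((r, "CA"), (r, _ha_name(c, r))) for r in range(1, n + 1)]
    for r in range(1, n + 1):
        if c.has_atom((r, "ND1")):  # donor
            pairs.append(((r, "CB"), (r, "HB")))
        elif c.has_atom((r, "Y")):  # acceptor
            pairs.append(((r, "CB"), (r, "HB")))
            pairs.append(((r, "CG"), (r, "HG")))
    return pairs


def simulate_observables(
    pool: ConformerPool,
    truth: GroundTruth,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
    karplus: KarplusCoefficients = KarplusCoefficients(),
) -> SyntheticObservables:
    """Forward-simulate NOE buildups, 3J couplings and RDCs.

    NOE: each pair's population-averaged effective distance sets a buildup
    rate by r^-6 referencing to the geminal pair; relative Gaussian noise
    perturbs the rate and the series is the (noisy-rate x mixing-time)
    line over seven mixing times from 0.100 to 0.700 s.  J couplings are
    population-averaged Karplus values with absolute noise; RDCs are
    population-averaged Saupe projections with absolute noise.
    """
    if seed is None:
        raise ConfigError("simulate_observables requires a seed")
    p = np.asarray(truth.populations, dtype=float)
    if p.shape != (len(pool),):
        raise ConfigError("truth populations do not match the pool size")
    rng = np.random.default_rng(seed)
    ref_c = pool[0]
    n = max(a.res_index for a in ref_c.atoms)
    pairs, reference = standard_noe_pairs(ref_c)

    series: list[MixingSeries] = []
    for pair, is_ref in [(reference, True)] + [(q, False) for q in pairs]:
        r_eff = predict_noe_distance(pool, p, pair)
        if not is_ref and r_eff > NOE_DETECTION_CUTOFF:
            continue  # cross peak below the NOESY detection horizon
        sigma = distance_to_rate(r_eff, sigma_ref=1.0)
        if noise.noe_rate_rel > 0:
            sigma *= 1.0 + rng.normal(0.0, noise.noe_rate_rel)
        series.append(MixingSeries(pair, MIXING_TIMES.copy(), sigma * MIXING_TIMES, is_ref))

    j_restraints: list[JRestraint] = []
    j_err = max(noise.j_hz, 0.1)
    for r in range(2, n + 1):
        val = float(np.dot(p, [karplus_j(backbone_phi(c, r), karplus) for c in pool]))
        if noise.j_hz > 0:
            val += rng.normal(0.0, noise.j_hz)
        j_restraints.append(JRestraint(r, val, j_err))

    rdc_pairs = standard_rdc_pairs(ref_c)
    G = np.zeros((len(rdc_pairs), 5))
    for w, c in zip(p, pool):
        G += w * conformer_design(c, rdc_pairs)
    d = G @ truth.tensor.s
    if noise.rdc_hz > 0:
        d = d + rng.normal(0.0, noise.rdc_hz, size=len(d))
    rdc_err = max(noise.rdc_hz, 0.1)
    rdcs = [RdcRestraint(pair, float(val), rdc_err) for pair, val in zip(rdc_pairs, d)]

    return SyntheticObservables(series, j_restraints, rdcs)
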