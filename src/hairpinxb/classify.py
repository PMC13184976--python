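"""Geometric classifiers for folded hairpins and halogen-bonded conformers.

A conformer counts as a folded beta-hairpin when (i) the two central turn
residues sit at type II' beta-turn torsions within an angular tolerance,
(ii) the mean cross-strand CAlpha-CAlpha distance over the designated
strand pairs is at most 6 A, and (iii) at least four of the six designated
interstrand N-H...O=C hydrogen bonds are formed.

A conformer is halogen-bonded when the donor-acceptor distance d(X...Y)
is equal to or shorter than the sum of the van der Waals radii of X and Y
(inclusive) and the C-X...Y angle exceeds 120 degrees (strict), the
geometric signature of the sigma-hole interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import LabelingError, SelectionError, UnknownElementError
from .structures import (
    Conformer,
    Selector,
    angle,
    backbone_phi,
    backbone_psi,
    distance,
)

#: Bondi van der Waals radii, Angstrom
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "Br": 1.85,
    "I": 1.98,
}


@dataclass(frozen=True)
class VdwTable:
    """Element -> van der Waals radius (A); defaults to the Bondi set."""

    radii: Mapping[str, float] = field(default_factory=lambda: dict(BONDI_RADII))

    def radius(self, element: str) -> float:
        key = element.capitalize()
        try:
            r = self.radii[key]
        except KeyError:
            raise UnknownElementError(
                f"element {element!r} not in the vdW radius table"
            ) from None
        if r <= 0:
            raise UnknownElementError(f"non-positive vdW radius for {element!r}")
        return r

    def sum(self, elem_x: str, elem_y: str) -> float:
        return self.radius(elem_x) + self.radius(elem_y)


@dataclass
class HairpinCriteria:
    """Thresholds of the folded-hairpin classifier.

    ``turn_targets`` are (phi, psi) for turn residues i+1 and i+2 of the
    type II' turn; ``hbond_pairs`` lists the six designated interstrand
    hydrogen bonds as (donor residue, acceptor residue): N-H of the donor
    to O=C of the acceptor.  ``ca_pairs`` are the cross-strand residue
    pairs whose CA-CA distances are averaged (turn excluded).
    """

    turn_residues: tuple[int, int]
    turn_targets: tuple[tuple[float, float], tuple[float, float]] = (
        (60.0, -120.0),
        (-80.0, 0.0),
    )
    turn_tolerance: float = 30.0  # degrees
    max_mean_ca_ca: float = 6.0  # Angstrom
    hbond_pairs: tuple[tuple[int, int], ...] = ()
    min_hbonds: int = 4
    hbond_max_distance: float = 3.5  # donor-acceptor heavy-atom, Angstrom
    hbond_min_angle: float = 120.0  # D-H...A angle, degrees (inclusive)
    ca_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.hbond_pairs and self.min_hbonds > len(self.hbond_pairs):
            raise LabelingError("min_hbonds exceeds the number of listed pairs")


@dataclass
class XbCriteria:
    """Halogen-bond rule: d(X...Y) <= sum(vdW) and C-X...Y angle > 120."""

    min_angle: float = 120.0  # degrees, strict lower bound
    allowed_donors: tuple[str, ...] = ("Br", "I")
    allowed_acceptors: tuple[str, ...] = ("O", "S")
    strict: bool = True  # raise on a non-sigma-hole donor; else classify False

    def __post_init__(self) -> None:
        if not (90.0 < self.min_angle < 180.0):
            raise LabelingError("min_angle must lie in (90, 180) degrees")


def default_hairpin_criteria(
    n_residues: int = 12, turn_position: int = 6
) -> HairpinCriteria:
    """Criteria for an n-residue hairpin with the turn inducer at
    ``turn_position`` (turn residues i+1 = turn_position, i+2 = next).

    The hydrogen-bond register of the antiparallel strands pairs residue i
    with n+1-i; H-bonded pairs start at the turn-flanking pair and step
    outwards by two, each contributing both N-H...O=C directions.
    """
    t = turn_position
    hbond_pairs = []
    i = t - 1
    while i >= 1:
        j = n_residues + 1 - i
        hbond_pairs.append((i, j))
        hbond_pairs.append((j, i))
        i -= 2
    ca_pairs = tuple((i, n_residues + 1 - i) for i in range(1, t))
    return HairpinCriteria(
        turn_residues=(t, t + 1),
        hbond_pairs=tuple(hbond_pairs),
        ca_pairs=ca_pairs,
    )


def _angdiff(a: float, b: float) -> float:
    """Smallest absolute angular difference in degrees with wrap-around."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def classify_turn(c: Conformer, crit: HairpinCriteria) -> bool:
    """True iff both turn residues' (phi, psi) lie within tolerance of the
    type II' targets (with angular wrap-around)."""
    for res, (phi_t, psi_t) in zip(crit.turn_residues, crit.turn_targets):
        phi = backbone_phi(c, res)
        psi = backbone_psi(c, res)
        if _angdiff(phi, phi_t) > crit.turn_tolerance:
            return False
        if _angdiff(psi, psi_t) > crit.turn_tolerance:
            return False
    return True


def count_interstrand_hbonds(c: Conformer, crit: HairpinCriteria) -> int:
    """Number of designated N-H...O=C pairs meeting the geometry rule."""
    n = 0
    for donor_res, acceptor_res in crit.hbond_pairs:
        if not c.has_atom((donor_res, "H")):
            raise SelectionError(f"residue {donor_res} lacks an amide H")
        d = distance(c, (donor_res, "N"), (acceptor_res, "O"))
        if d > crit.hbond_max_distance:
            continue
        theta = angle(c, (donor_res, "N"), (donor_res, "H"), (acceptor_res, "O"))
        if theta >= crit.hbond_min_angle:
            n += 1
    return n


def mean_ca_ca(c: Conformer, crit: HairpinCriteria) -> float:
    d = [distance(c, (i, "CA"), (j, "CA")) for i, j in crit.ca_pairs]
    return float(np.mean(d))


def classify_folded(c: Conformer, crit: HairpinCriteria) -> bool:
    """Conjunction of the turn, CA-CA proximity and H-bond count rules."""
    if not classify_turn(c, crit):
        return False
    if mean_ca_ca(c, crit) > crit.max_mean_ca_ca:
        return False
    return count_interstrand_hbonds(c, crit) >= crit.min_hbonds


def classify_xb(
    c: Conformer,
    donor: tuple[Selector, Selector],
    acceptor: Selector,
    vdw: VdwTable = VdwTable(),
    crit: XbCriteria = XbCriteria(),
) -> bool:
    """Halogen-bond classifier.

    ``donor`` is the (C, X) selector pair of the covalent C-X bond, and
    ``acceptor`` selects the Lewis base atom Y.  The distance rule is
    inclusive ("equal or shorter" than sum of vdW radii); the angle rule
    is strict (> ``min_angle``).
    """
    c_sel, x_sel = donor
    x_elem = c.atom(x_sel).element.capitalize()
    y_elem = c.atom(acceptor).element.capitalize()
    if x_elem not in crit.allowed_donors:
        if crit.strict:
            raise LabelingError(
                f"donor element {x_elem!r} carries no sigma-hole (allowed: "
                f"{crit.allowed_donors})"
            )
        return False
    if y_elem not in crit.allowed_acceptors:
        if crit.strict:
            raise LabelingError(
                f"acceptor element {y_elem!r} not allowed ({crit.allowed_acceptors})"
            )
        return False
    d = distance(c, x_sel, acceptor)
    if d > vdw.sum(x_elem, y_elem):
        return False
    theta = angle(c, c_sel, x_sel, acceptor)
    return theta > crit.min_angle


def vdw_ratio(
    d: float, x_elem: str, y_elem: str, vdw: VdwTable = VdwTable()
) -> tuple[float, int]:
    """Contact distance as a percentage of the vdW-radius sum.

    Returns ``(raw_percent, rounded_percent)``; e.g. a 3.02 A Br...O
    contact is 89.6% -> 90% of the 3.37 A radius sum.
    """
    if d <= 0:
        raise UnknownElementError("distance must be positive")
    raw = 100.0 * d / vdw.sum(x_elem, y_elem)
    return raw, int(round(raw))
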