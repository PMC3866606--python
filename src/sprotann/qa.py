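"""Model assessment: torsions, hydrogen bonds, secondary structure,
Ramachandran stereochemistry, per-model QA reports and confidence tiers.

Secondary structure follows the DSSP pattern formalism: backbone H-bonds by
the electrostatic criterion E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH -
1/r_CN) < -0.5 kcal/mol, n-turns and bridge patterns promoted to helix and
strand states with priority H > E > G > I > B > T > C. Side-chain hydrogen
bonds use a purely geometric rule (donor-acceptor <= 3.5 A, donor-antecedent
angle >= 90 deg), appropriate for coarse models whose side chains may be
synthetic stubs. Ramachandran regions come from a shipped 10x10-degree grid
built from rectangular core regions (alpha, beta, left-handed alpha) with
"additional allowed" and "generously allowed" expansion bands.

Model confidence tiers follow the expected-TM-score convention: >= 0.7 high,
>= 0.4 moderate, < 0.4 low, no estimate -> none. The estimate is an input
(produced upstream by model ranking), never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as K
from .errors import ContractError
from .geometry import bond_angle
from .structio import ProteinChain, measure_torsions

__all__ = [
    "SecondaryStructureAssignment", "HydrogenBond", "RamachandranAssignment",
    "QAReport", "ConfidenceTier", "torsion_angles", "detect_hbonds",
    "assign_secondary_structure", "ramachandran_classify", "qa_report",
    "confidence_tier",
]

SS_CLASSES = "HGIEBTC"
RAMA_REGIONS = ("most favored", "additional allowed",
                "generously allowed", "disallowed")
HBOND_CATEGORIES = ("main-main", "side-side", "main-side")
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "H"})
HBOND_ENERGY_CUTOFF = -0.5           # kcal/mol, DSSP electrostatic criterion
SIDECHAIN_HBOND_DISTANCE = 3.5       # A
SIDECHAIN_HBOND_ANGLE = 90.0         # degrees
TIER_HIGH = 0.7
TIER_MODERATE = 0.4


@dataclass
class SecondaryStructureAssignment:
    """Per-residue class string over H, G, I, E, B, T, C."""

    classes: str

    def fractions(self) -> dict[str, float]:
        n = len(self.classes)
        if n == 0:
            return {c: 0.0 for c in SS_CLASSES}
        return {c: self.classes.count(c) / n for c in SS_CLASSES}


@dataclass
class HydrogenBond:
    donor_res: int          # 0-based residue index
    donor_atom: str
    acceptor_res: int
    acceptor_atom: str
    category: str           # main-main | side-side | main-side
    energy: float | None    # kcal/mol for backbone bonds, None for geometric


@dataclass
class RamachandranAssignment:
    """Per-residue region (None where phi or psi is undefined)."""

    regions: list[str | None]
    phi: list[float | None]
    psi: list[float | None]

    def fractions(self, exclude_gly_for: ProteinChain | None = None) -> dict[str, float]:
        counted = [r for r in self.regions if r is not None]
        n = len(counted)
        if n == 0:
            return {r: 0.0 for r in RAMA_REGIONS}
        return {r: counted.count(r) / n for r in RAMA_REGIONS}


@dataclass
class QAReport:
    ss_fractions: dict[str, float]
    hbond_fractions: dict[str, float]     # bonds per residue, by category
    ramachandran_fractions: dict[str, float]


@dataclass
class ConfidenceTier:
    tier: str                  # high | moderate | low | none
    estimated_tm: float | None


def torsion_angles(chain: ProteinChain):
    """Per-residue (phi, psi, omega) in degrees, None where undefined."""
    return measure_torsions(chain)


def _amide_h(chain: ProteinChain, i: int) -> np.ndarray | None:
    """Geometric amide hydrogen on the C(i-1)-N(i)-CA(i) bisector, 1.0 A from N."""
    r = chain[i]
    if "H" in r:
        return r["H"].position
    if i == 0 or not chain.is_continuous(i - 1):
        return None
    prev = chain[i - 1]
    if "C" not in prev or "N" not in r or "CA" not in r:
        return None
    n = r["N"].position
    v1 = n - prev["C"].position
    v2 = n - r["CA"].position
    v1 = v1 / np.linalg.norm(v1)
    v2 = v2 / np.linalg.norm(v2)
    b = v1 + v2
    nb = np.linalg.norm(b)
    if nb < 1e-9:
        return None
    return n + K.BOND_N_H * b / nb


def _backbone_hbond_energy(h: np.ndarray, n: np.ndarray,
                           c: np.ndarray, o: np.ndarray) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 0.0
    return 0.084 * 332.0 * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _sidechain_polar_atoms(chain: ProteinChain, i: int):
    """Side-chain N/O/S atoms (anything beyond the backbone set)."""
    out = []
    for name, atom in chain[i].atoms.items():
        if name in BACKBONE_ATOMS:
            continue
        if atom.element in ("N", "O", "S"):
            out.append(atom)
    return out


def _antecedent(chain: ProteinChain, i: int, atom) -> np.ndarray | None:
    """Nearest other heavy atom of the same residue (covalent neighbor proxy)."""
    best, best_d = None, np.inf
    for name, other in chain[i].atoms.items():
        if other is atom:
            continue
        d = float(np.linalg.norm(other.position - atom.position))
        if d < best_d:
            best, best_d = other, d
    return None if best is None else best.position


def detect_hbonds(chain: ProteinChain) -> list[HydrogenBond]:
    """All hydrogen bonds: backbone-backbone by the DSSP electrostatic
    criterion, side-chain-involving bonds by geometry. Proline contributes
    no amide donor."""
    n_res = len(chain)
    bonds: list[HydrogenBond] = []

    h_pos = [_amide_h(chain, i) for i in range(n_res)]

    # backbone-backbone: N-H(i) -> C=O(j), |i - j| >= 2
    for i in range(n_res):
        if chain[i].aa == "P" or h_pos[i] is None or "N" not in chain[i]:
            continue
        n_i = chain[i]["N"].position
        for j in range(n_res):
            if abs(i - j) < 2:
                continue
            rj = chain[j]
            if "C" not in rj or "O" not in rj:
                continue
            e = _backbone_hbond_energy(h_pos[i], n_i,
                                       rj["C"].position, rj["O"].position)
            if e < HBOND_ENERGY_CUTOFF:
                bonds.append(HydrogenBond(i, "N", j, "O", "main-main", e))

    # bonds involving side-chain polar atoms: geometric criterion
    backbone_acceptors = [("O", chain[j]["O"].position)
                          for j in range(n_res) if "O" in chain[j]]
    for i in range(n_res):
        for atom in _sidechain_polar_atoms(chain, i):
            ante = _antecedent(chain, i, atom)
            if ante is None:
                continue
            # side-chain donor -> backbone O acceptor (main-side)
            for j in range(n_res):
                if j == i or "O" not in chain[j]:
                    continue
                acc = chain[j]["O"].position
                if np.linalg.norm(acc - atom.position) > SIDECHAIN_HBOND_DISTANCE:
                    continue
                if bond_angle(ante, atom.position, acc) < SIDECHAIN_HBOND_ANGLE:
                    continue
                bonds.append(HydrogenBond(i, atom.name, j, "O", "main-side", None))
            # side-chain <-> side-chain (side-side)
            for j in range(i + 1, n_res):
                for other in _sidechain_polar_atoms(chain, j):
                    if np.linalg.norm(other.position - atom.position) > SIDECHAIN_HBOND_DISTANCE:
                        continue
                    if bond_angle(ante, atom.position, other.position) < SIDECHAIN_HBOND_ANGLE:
                        continue
                    bonds.append(HydrogenBond(i, atom.name, j, other.name,
                                              "side-side", None))
    # backbone N-H donor -> side-chain acceptor (main-side)
    for i in range(n_res):
        if chain[i].aa == "P" or h_pos[i] is None or "N" not in chain[i]:
            continue
        n_i = chain[i]["N"].position
        for j in range(n_res):
            if j == i:
                continue
            for atom in _sidechain_polar_atoms(chain, j):
                if np.linalg.norm(atom.position - n_i) > SIDECHAIN_HBOND_DISTANCE:
                    continue
                if bond_angle(h_pos[i], n_i, atom.position) < SIDECHAIN_HBOND_ANGLE:
                    continue
                bonds.append(HydrogenBond(i, "N", j, atom.name, "main-side", None))
    return bonds


def assign_secondary_structure(chain: ProteinChain) -> SecondaryStructureAssignment:
    """DSSP-style pattern assignment from backbone hydrogen bonds."""
    n = len(chain)
    if n < 5:
        return SecondaryStructureAssignment("C" * n)

    hb = {(b.donor_res, b.acceptor_res)
          for b in detect_hbonds(chain) if b.category == "main-main"}

    def turn(i: int, k: int) -> bool:
        return (i + k, i) in hb

    assigned = [""] * n

    def mark(idx: int, cls: str) -> None:
        if 0 <= idx < n and assigned[idx] == "":
            assigned[idx] = cls

    # bridges first collected (E assignment happens after H by priority)
    parallel, antiparallel = set(), set()
    for i in range(n):
        for j in range(i + 3, n):
            if ((j, i - 1) in hb and (i + 1, j) in hb) or \
               ((i, j - 1) in hb and (j + 1, i) in hb):
                parallel.add((i, j))
            if ((j, i) in hb and (i, j) in hb) or \
               ((j + 1, i - 1) in hb and (i + 1, j - 1) in hb):
                antiparallel.add((i, j))
    bridges = parallel | antiparallel
    ladder_res, isolated_res = set(), set()
    for (i, j) in bridges:
        in_ladder = any((i + di, j + dj) in bridges
                        for di in (-1, 1) for dj in (-1, 1))
        (ladder_res if in_ladder else isolated_res).update((i, j))

    # priority H > E > G > I > B > T > C
    for i in range(n - 1):
        if turn(i, 4) and turn(i + 1, 4):
            for k in range(i + 1, i + 5):
                mark(k, "H")
    for r in sorted(ladder_res):
        mark(r, "E")
    for i in range(n - 1):
        if turn(i, 3) and turn(i + 1, 3):
            for k in range(i + 1, i + 4):
                mark(k, "G")
    for i in range(n - 1):
        if turn(i, 5) and turn(i + 1, 5):
            for k in range(i + 1, i + 6):
                mark(k, "I")
    for r in sorted(isolated_res):
        mark(r, "B")
    for k in (3, 4, 5):
        for i in range(n - k):
            if turn(i, k):
                for t in range(i + 1, i + k):
                    mark(t, "T")
    return SecondaryStructureAssignment("".join(a or "C" for a in assigned))


# --- Ramachandran regions ----------------------------------------------------

# Rectangular core regions (phi_lo, phi_hi, psi_lo, psi_hi), degrees.
_RAMA_CORES = (
    (-90.0, -35.0, -70.0, -20.0),    # right-handed alpha
    (-170.0, -50.0, 90.0, 175.0),    # beta / extended (incl. polyproline II)
    (40.0, 80.0, 20.0, 70.0),        # left-handed alpha
)
_RAMA_ADDITIONAL_BAND = 20.0
_RAMA_GENEROUS_BAND = 45.0
_RAMA_GRID_STEP = 10.0


def _circ_dist_to_interval(x: float, lo: float, hi: float) -> float:
    """Angular distance (degrees, torus metric) from x to [lo, hi]."""
    if lo <= x <= hi:
        return 0.0
    d_lo = min(abs(x - lo), 360.0 - abs(x - lo))
    d_hi = min(abs(x - hi), 360.0 - abs(x - hi))
    return min(d_lo, d_hi)


def _region_at(phi: float, psi: float) -> str:
    best = np.inf
    for (plo, phi_hi, slo, shi) in _RAMA_CORES:
        d = max(_circ_dist_to_interval(phi, plo, phi_hi),
                _circ_dist_to_interval(psi, slo, shi))
        best = min(best, d)
    if best == 0.0:
        return "most favored"
    if best <= _RAMA_ADDITIONAL_BAND:
        return "additional allowed"
    if best <= _RAMA_GENEROUS_BAND:
        return "generously allowed"
    return "disallowed"


def _build_rama_grid() -> np.ndarray:
    """36 x 36 grid of region codes over phi, psi in [-180, 180)."""
    grid = np.empty((36, 36), dtype=np.int8)
    for a in range(36):
        for b in range(36):
            phi = -180.0 + (a + 0.5) * _RAMA_GRID_STEP
            psi = -180.0 + (b + 0.5) * _RAMA_GRID_STEP
            grid[a, b] = RAMA_REGIONS.index(_region_at(phi, psi))
    return grid


_RAMA_GRID = _build_rama_grid()


def _grid_lookup(phi: float, psi: float) -> str:
    a = int((phi + 180.0) // _RAMA_GRID_STEP) % 36
    b = int((psi + 180.0) // _RAMA_GRID_STEP) % 36
    return RAMA_REGIONS[_RAMA_GRID[a, b]]


def ramachandran_classify(chain: ProteinChain) -> RamachandranAssignment:
    """Classify each residue's (phi, psi) into the shipped region grid.

    Glycine is exempt from "disallowed" and reported at best "generously
    allowed". Residues with undefined phi or psi (termini, breaks) get None.
    """
    torsions = measure_torsions(chain)
    regions: list[str | None] = []
    phis: list[float | None] = []
    psis: list[float | None] = []
    for res, (phi, psi, _) in zip(chain, torsions):
        phis.append(phi)
        psis.append(psi)
        if phi is None or psi is None:
            regions.append(None)
            continue
        region = _grid_lookup(phi, psi)
        if res.aa == "G" and region == "disallowed":
            region = "generously allowed"
        regions.append(region)
    return RamachandranAssignment(regions, phis, psis)


def qa_report(chain: ProteinChain) -> QAReport:
    """Combined QA fractions: secondary-structure class content, hydrogen
    bonds per residue by category, Ramachandran region fractions.

    Denominators: secondary-structure fractions are over all residues (every
    residue receives a class); hydrogen-bond fractions are bond counts
    divided by residue count; Ramachandran fractions are over non-glycine
    residues with both torsions defined.
    """
    n = len(chain)
    ss = assign_secondary_structure(chain).fractions()
    bonds = detect_hbonds(chain)
    hb = {cat: sum(1 for b in bonds if b.category == cat) / n
          for cat in HBOND_CATEGORIES}
    rama = ramachandran_classify(chain)
    counted = [r for res, r in zip(chain, rama.regions)
               if r is not None and res.aa != "G"]
    if counted:
        rf = {r: counted.count(r) / len(counted) for r in RAMA_REGIONS}
    else:
        rf = {r: 0.0 for r in RAMA_REGIONS}
    return QAReport(ss, hb, rf)


def confidence_tier(estimated_tm: float | None) -> ConfidenceTier:
    """Model confidence from the expected TM-score: >= 0.7 high, >= 0.4
    moderate, below low; no estimate (no templates found) -> none."""
    if estimated_tm is None:
        return ConfidenceTier("none", None)
    if not (0.0 <= estimated_tm <= 1.0):
        raise ContractError(f"estimated TM-score {estimated_tm} outside [0, 1]")
    if estimated_tm >= TIER_HIGH:
        return ConfidenceTier("high", estimated_tm)
    if estimated_tm >= TIER_MODERATE:
        return ConfidenceTier("moderate", estimated_tm)
    return ConfidenceTier("low", estimated_tm)
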