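"""Structural data model and standard-format I/O.

The in-memory model is deliberately small: a :class:`ProteinChain` is an
ordered list of residues with named atoms and 1-based sequential numbering
(author numbering is discarded on read). Coordinates are Angstrom throughout.
The module also provides :func:`chain_from_torsions`, an ideal-geometry
backbone builder that turns per-residue (phi, psi, omega) torsions into a
full backbone with CB stubs — the geometric foundation of every synthetic
structure in the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from . import constants as K
from .errors import ContractError, ParseError, ValidationError
from .geometry import dihedral, place_atom

__all__ = [
    "Atom", "Residue", "ProteinChain", "SequenceRecord", "PDBContents",
    "read_pdb", "write_pdb", "read_fasta", "write_fasta",
    "chain_from_torsions",
]


@dataclass
class Atom:
    """A named atom with element and position (Angstrom)."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise ValidationError("atom name must be non-empty")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    """One residue: 1-based chain position, one-letter code, named atoms."""

    seq_index: int
    aa: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aa not in K.EXTENDED_AA_SET:
            raise ValidationError(f"unknown amino acid code {self.aa!r}")

    def __contains__(self, atom_name: str) -> bool:
        return atom_name in self.atoms

    def __getitem__(self, atom_name: str) -> Atom:
        return self.atoms[atom_name]

    def get(self, atom_name: str) -> Atom | None:
        return self.atoms.get(atom_name)

    def add(self, atom: Atom) -> None:
        if atom.name in self.atoms:
            raise ValidationError(
                f"residue {self.seq_index}: duplicate atom {atom.name}")
        self.atoms[atom.name] = atom

    def validate(self, require_o: bool = False) -> None:
        needed = ("N", "CA", "C", "O") if require_o else ("N", "CA", "C")
        for name in needed:
            if name not in self.atoms:
                raise ValidationError(
                    f"residue {self.seq_index} lacks backbone atom {name}")


class ProteinChain:
    """An ordered protein chain with optional annotated chain breaks.

    Invariants: residue seq_index strictly increasing; for consecutive
    residues not separated by a break, the CA-CA distance lies in
    [2.5, 4.5] Angstrom.
    """

    def __init__(self, chain_id: str, residues: Sequence[Residue],
                 breaks: Iterable[int] = ()) -> None:
        self.chain_id = chain_id
        self.residues = list(residues)
        self.breaks = set(breaks)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of CA positions."""
        return np.array([r["CA"].position for r in self.residues], dtype=float)

    def cb_coords(self) -> np.ndarray:
        """(n, 3) array of CB positions, falling back to CA (Gly, coarse models)."""
        out = np.empty((len(self.residues), 3), dtype=float)
        for i, r in enumerate(self.residues):
            atom = r.get("CB") or r.get("CA")
            if atom is None:
                raise ValidationError(f"residue {r.seq_index} lacks CA and CB")
            out[i] = atom.position
        return out

    def backbone_coords(self, atom_name: str) -> np.ndarray:
        return np.array([r[atom_name].position for r in self.residues], dtype=float)

    def is_continuous(self, i: int) -> bool:
        """True when residues i and i+1 (0-based) are covalently connected."""
        return self.residues[i].seq_index not in self.breaks

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinChain":
        """Return a rigidly moved copy of the chain."""
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        residues = []
        for r in self.residues:
            atoms = {
                name: Atom(name, a.element, rot @ a.position + t)
                for name, a in r.atoms.items()
            }
            residues.append(Residue(r.seq_index, r.aa, atoms))
        return ProteinChain(self.chain_id, residues, set(self.breaks))

    def with_sequence(self, sequence: str) -> "ProteinChain":
        """Return a copy with residue identities replaced (coordinates kept)."""
        if len(sequence) != len(self.residues):
            raise ContractError("sequence length does not match chain length")
        residues = []
        for r, aa in zip(self.residues, sequence):
            atoms = {n: Atom(n, a.element, a.position.copy()) for n, a in r.atoms.items()}
            residues.append(Residue(r.seq_index, aa, atoms))
        return ProteinChain(self.chain_id, residues, set(self.breaks))

    def validate(self) -> None:
        prev_idx = 0
        for r in self.residues:
            if r.seq_index <= prev_idx:
                raise ValidationError("seq_index must be strictly increasing")
            prev_idx = r.seq_index
            r.validate()
        ca = self.ca_coords()
        for i in range(len(self.residues) - 1):
            if not self.is_continuous(i):
                continue
            d = float(np.linalg.norm(ca[i + 1] - ca[i]))
            if not (2.5 <= d <= 4.5):
                raise ValidationError(
                    f"chain {self.chain_id}: CA-CA distance {d:.2f} A between "
                    f"residues {self.residues[i].seq_index} and "
                    f"{self.residues[i + 1].seq_index} outside [2.5, 4.5]")


@dataclass
class SequenceRecord:
    """A named amino-acid sequence (20 standard letters + X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"record {self.id}: empty sequence")
        bad = set(self.sequence) - K.EXTENDED_AA_SET
        if bad:
            raise ValidationError(
                f"record {self.id}: invalid symbol(s) {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.sequence)


class PDBContents(NamedTuple):
    """Parsed PDB content: polymer chains plus ligand/metal HETATM atoms."""

    chains: dict[str, ProteinChain]
    het_atoms: list[Atom]


# --- PDB ---------------------------------------------------------------------

def _parse_float(line: str, lo: int, hi: int, lineno: int, what: str) -> float:
    text = line[lo:hi].strip()
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"line {lineno}: malformed {what} field {text!r}") from None


def read_pdb(stream) -> PDBContents:
    """Parse ATOM/HETATM records from PDB-format text.

    Accepts a file-like object or a string. Altloc conflicts resolve to the
    highest occupancy (ties: first listed); insertion codes are folded away
    and residues renumbered 1..n per chain; HETATM atoms are returned
    separately, never as chain residues. Chain breaks are detected from
    CA-CA distances above 4.5 A.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    # (chain, author resseq+icode) -> {atom name -> (occupancy, order, Atom, aa)}
    chains_raw: dict[str, dict] = {}
    het_atoms: list[Atom] = []
    order = 0

    for lineno, line in enumerate(stream, start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        x = _parse_float(line, 30, 38, lineno, "x coordinate")
        y = _parse_float(line, 38, 46, lineno, "y coordinate")
        z = _parse_float(line, 46, 54, lineno, "z coordinate")
        name = line[12:16].strip()
        element = line[76:78].strip() or name[:1]
        atom = Atom(name, element, np.array([x, y, z]))
        if rec == "HETATM":
            het_atoms.append(atom)
            continue
        occ_text = line[54:60].strip()
        occ = float(occ_text) if occ_text else 1.0
        chain_id = line[21].strip() or "A"
        res_key = line[22:27]  # author resseq + insertion code
        res3 = line[17:20].strip()
        aa = K.THREE_TO_ONE.get(res3, "X")
        residues = chains_raw.setdefault(chain_id, {})
        slot = residues.setdefault(res_key, {"aa": aa, "order": order, "atoms": {}})
        order += 1
        prev = slot["atoms"].get(name)
        if prev is None or occ > prev[0]:
            slot["atoms"][name] = (occ, order, atom)

    chains: dict[str, ProteinChain] = {}
    for chain_id, residues_raw in chains_raw.items():
        slots = sorted(residues_raw.values(), key=lambda s: s["order"])
        residues = []
        for idx, slot in enumerate(slots, start=1):
            atoms = {name: a for name, (_, _, a) in slot["atoms"].items()}
            residues.append(Residue(idx, slot["aa"], atoms))
        if not any("CA" in r for r in residues):
            raise ParseError(f"chain {chain_id}: no CA atoms")
        chain = ProteinChain(chain_id, residues)
        # annotate breaks from geometry
        for i in range(len(residues) - 1):
            a, b = residues[i].get("CA"), residues[i + 1].get("CA")
            if a is None or b is None:
                chain.breaks.add(residues[i].seq_index)
            elif float(np.linalg.norm(b.position - a.position)) > 4.5:
                chain.breaks.add(residues[i].seq_index)
        chains[chain_id] = chain
    return PDBContents(chains, het_atoms)


def write_pdb(chains: Iterable[ProteinChain] | Mapping[str, ProteinChain],
              ligand_atoms: Sequence[Atom] | None = None) -> str:
    """Serialize chains (and optional HETATM ligand/metal atoms) to PDB text."""
    if isinstance(chains, Mapping):
        chains = list(chains.values())
    else:
        chains = list(chains)
    if not chains:
        raise ContractError("write_pdb requires at least one chain")

    lines: list[str] = []
    serial = 1

    def fmt(record: str, serial: int, name: str, res3: str, chain_id: str,
            resseq: int, pos: np.ndarray, element: str) -> str:
        if np.any(np.abs(pos) >= 10000.0):
            raise ValidationError(
                f"coordinate magnitude >= 10000 A cannot be formatted: {pos}")
        aname = name if len(name) == 4 else f" {name:<3s}"
        return (f"{record:<6s}{serial:>5d} {aname:<4s}{res3:>4s} {chain_id:1s}"
                f"{resseq:>4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")

    for chain in chains:
        for res in chain:
            res3 = K.ONE_TO_THREE.get(res.aa, "UNK")
            for atom in res.atoms.values():
                lines.append(fmt("ATOM", serial, atom.name, res3,
                                 chain.chain_id, res.seq_index,
                                 atom.position, atom.element))
                serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    for atom in ligand_atoms or ():
        lines.append(fmt("HETATM", serial, atom.name, atom.element.upper().ljust(3),
                         "X", 1, atom.position, atom.element))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# --- FASTA -------------------------------------------------------------------

def read_fasta(stream) -> list[SequenceRecord]:
    """Read FASTA records; sequences are upper-cased and validated."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[SequenceRecord] = []
    header: str | None = None
    parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(parts).upper()
        records.append(SequenceRecord(header, seq))

    for line in stream:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0] if line[1:].split() else line[1:]
            parts = []
        else:
            if header is None:
                raise ParseError("sequence data before first FASTA header")
            parts.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], width: int = 60) -> str:
    out: list[str] = []
    for rec in records:
        out.append(f">{rec.id}")
        for i in range(0, len(rec.sequence), width):
            out.append(rec.sequence[i:i + width])
    return "\n".join(out) + ("\n" if out else "")


# --- ideal-geometry backbone builder ----------------------------------------

def chain_from_torsions(sequence: str,
                        torsions: Sequence[tuple[float, float, float]],
                        chain_id: str = "A") -> ProteinChain:
    """Build a backbone (N, CA, C, O, CB) chain from torsions and sequence.

    ``torsions[i]`` is (phi_i, psi_i, omega_i) in degrees. Convention: phi_i
    is C(i-1)-N(i)-CA(i)-C(i), psi_i is N(i)-CA(i)-C(i)-N(i+1), and omega_i
    is the peptide dihedral CA(i-1)-C(i-1)-N(i)-CA(i) preceding residue i.
    Accordingly phi and omega of the first residue and psi of the last are
    unused. Bond lengths/angles are the ideal values of the constants table;
    O is placed in the carbonyl plane and CB by ideal tetrahedral geometry
    (L-configuration) for non-glycine residues.
    """
    sequence = sequence.upper()
    if len(sequence) != len(torsions):
        raise ContractError(
            f"sequence length {len(sequence)} != torsion count {len(torsions)}")
    if len(sequence) == 0:
        raise ContractError("empty sequence")
    bad = set(sequence) - K.EXTENDED_AA_SET
    if bad:
        raise ValidationError(f"invalid amino acid(s) {sorted(bad)!r}")

    n_res = len(sequence)
    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))

    # first residue in a canonical frame
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (K.BOND_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - K.ANGLE_N_CA_C)
    C[0] = CA[0] + K.BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_res):
        psi_prev = torsions[i - 1][1]
        omega_i = torsions[i][2]
        phi_i = torsions[i][0]
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          K.BOND_C_N, K.ANGLE_CA_C_N, psi_prev)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           K.BOND_N_CA, K.ANGLE_C_N_CA, omega_i)
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          K.BOND_CA_C, K.ANGLE_N_CA_C, phi_i)

    residues: list[Residue] = []
    for i, aa in enumerate(sequence):
        atoms = {
            "N": Atom("N", "N", N[i]),
            "CA": Atom("CA", "C", CA[i]),
            "C": Atom("C", "C", C[i]),
        }
        # carbonyl O in the plane of CA(i), C(i) and the next amide N
        if i + 1 < n_res:
            ref = N[i + 1]
        else:
            ref = place_atom(N[i], CA[i], C[i],
                             K.BOND_C_N, K.ANGLE_CA_C_N, torsions[i][1])
        v1 = ref - C[i]
        v1 /= np.linalg.norm(v1)
        v2 = CA[i] - C[i]
        v2 /= np.linalg.norm(v2)
        o_dir = -(v1 + v2)
        o_dir /= np.linalg.norm(o_dir)
        atoms["O"] = Atom("O", "O", C[i] + K.BOND_C_O * o_dir)
        if aa != "G":
            cb = place_atom(C[i], N[i], CA[i], K.BOND_CA_CB,
                            K.ANGLE_N_CA_CB, K.DIHEDRAL_C_N_CA_CB)
            atoms["CB"] = Atom("CB", "C", cb)
        residues.append(Residue(i + 1, aa, atoms))

    return ProteinChain(chain_id, residues)


def measure_torsions(chain: ProteinChain) -> list[tuple[float | None, float | None, float | None]]:
    """Per-residue (phi, psi, omega) in degrees; None where undefined.

    Uses the same conventions as :func:`chain_from_torsions`. Angles spanning
    a chain break are reported as None.
    """
    n = len(chain)
    out: list[tuple[float | None, float | None, float | None]] = []
    for i in range(n):
        r = chain[i]
        phi = psi = omega = None
        have = all(a in r for a in ("N", "CA", "C"))
        if have and i > 0 and chain.is_continuous(i - 1):
            p = chain[i - 1]
            if "C" in p:
                phi = dihedral(p["C"].position, r["N"].position,
                               r["CA"].position, r["C"].position)
            if "CA" in p and "C" in p:
                omega = dihedral(p["CA"].position, p["C"].position,
                                 r["N"].position, r["CA"].position)
        if have and i + 1 < n and chain.is_continuous(i):
            nxt = chain[i + 1]
            if "N" in nxt:
                psi = dihedral(r["N"].position, r["CA"].position,
                               r["C"].position, nxt["N"].position)
        out.append((phi, psi, omega))
    return out
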