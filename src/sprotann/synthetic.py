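"""Seeded synthetic benchmark generators.

Every generator is a pure function of (parameters, seed) built on
``numpy.random.default_rng``: identical calls are bit-identical. The
generators emulate the external data a small-protein annotation study
consumes — small-protein sequences (50-100 aa), structure models across
quality tiers (torsion-space noise), dimer template libraries with labeled
interfaces, fold libraries with hierarchical C.A.T labels, proteomes with
planted receptor homologs, holo templates with planted ligand pockets or
metal sites, and fingerprint compound libraries with planted actives.
Ground truth is a first-class output so downstream evaluation never reaches
into generator internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import constants as K
from .binding import HoloTemplate
from .errors import ContractError, GenerationError
from .ppi import DimerTemplate, template_interface
from .structio import (ProteinChain, SequenceRecord, chain_from_torsions,
                       measure_torsions, write_fasta, write_pdb)

__all__ = [
    "FoldSpec", "LabeledFoldLibrary", "LibraryEntry", "CompoundLibrary",
    "HoloTemplateSet", "SyntheticBenchmark", "BenchmarkParams",
    "make_sprotein_sequences", "make_fold", "perturb_model",
    "make_dimer_template", "make_labeled_library", "make_proteome",
    "make_compound_library", "make_holo_templates", "make_benchmark",
    "random_sequence", "standard_fold_specs", "SproteinModel",
]

_AA = np.array(list(K.AMINO_ACIDS))
_BG = np.array([K.BACKGROUND_FREQUENCIES[a] for a in K.AMINO_ACIDS])
_BG = _BG / _BG.sum()

FOLD_MAX_RETRIES = 300
DOCK_MAX_RETRIES = 120
MIN_NONBONDED_CA = 3.5          # A, steric clash threshold, |i-j| >= 3
MIN_INTERCHAIN_CA = 3.8         # A
MIN_INTERFACE_RESIDUES = 8
FINGERPRINT_DENSITY = 0.2


@dataclass(frozen=True)
class FoldSpec:
    """Topology recipe: ordered (kind, length) elements plus a packing rule."""

    elements: tuple[tuple[str, int], ...]
    packing: str = "bundle"     # bundle | sheet | extended

    def __post_init__(self) -> None:
        if self.packing not in ("bundle", "sheet", "extended"):
            raise ContractError(f"unknown packing {self.packing!r}")
        for kind, length in self.elements:
            if kind not in ("helix", "strand", "loop"):
                raise ContractError(f"unknown element kind {kind!r}")
            if length < 3:
                raise ContractError("element lengths must be >= 3")
        if self.total_length < 10:
            raise ContractError("fold total length must be >= 10")

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.elements)


@dataclass
class LibraryEntry:
    entry_id: str
    chain: ProteinChain
    label: str                   # dotted C.A.T


@dataclass
class LabeledFoldLibrary:
    entries: list[LibraryEntry]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


@dataclass
class CompoundLibrary:
    ids: list[str]
    fingerprints: np.ndarray        # (n, n_bits) 0/1
    probe: np.ndarray
    active_ids: list[str]


@dataclass
class HoloTemplateSet:
    templates: list[HoloTemplate]
    true_site: np.ndarray                  # in query frame
    query: ProteinChain                    # site-consistent copy of the input
    coordinating_residues: frozenset[int]  # query indices (metal sets)
    probe_fingerprint: np.ndarray | None   # ligand sets
    metal_type: str | None


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


_POLAR = np.array([K.SURFACE_POLAR_FREQUENCIES[a] for a in K.AMINO_ACIDS])
_POLAR = _POLAR / _POLAR.sum()


def random_sequence(length: int, rng: np.random.Generator,
                    composition: str = "background") -> str:
    p = _POLAR if composition == "polar" else _BG
    return "".join(rng.choice(_AA, size=length, p=p))


def make_sprotein_sequences(n: int, length_range=(50, 100), seed: int = 0,
                            prefix: str = "sp") -> list[SequenceRecord]:
    """n random small-protein sequences, lengths uniform on the closed range,
    composition from the fixed background table."""
    if n <= 0:
        raise ContractError("n must be positive")
    lo, hi = length_range
    if not (10 <= lo <= hi <= 600):
        raise ContractError("length_range must lie within [10, 600]")
    rng = _rng(seed)
    out = []
    for k in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append(SequenceRecord(f"{prefix}{k:04d}", random_sequence(length, rng)))
    return out


def _loop_torsion(rng: np.random.Generator) -> tuple[float, float, float]:
    """One loop residue's torsions, drawn from broad allowed-region bands."""
    if rng.random() < 0.8:
        phi = rng.uniform(-160.0, -50.0)
        psi = rng.uniform(-70.0, 170.0)
    else:
        phi = rng.uniform(40.0, 90.0)
        psi = rng.uniform(-10.0, 80.0)
    return (phi, psi, 180.0)


def _fold_torsions(spec: FoldSpec, rng: np.random.Generator):
    torsions: list[tuple[float, float, float]] = []
    kinds = [k for k, _ in spec.elements]
    for e_idx, (kind, length) in enumerate(spec.elements):
        if kind == "helix":
            torsions.extend([(K.HELIX_PHI_PSI[0], K.HELIX_PHI_PSI[1], 180.0)] * length)
        elif kind == "strand":
            torsions.extend([(K.STRAND_PHI_PSI[0], K.STRAND_PHI_PSI[1], 180.0)] * length)
        else:
            between_strands = (spec.packing == "sheet"
                               and 0 < e_idx < len(kinds) - 1
                               and kinds[e_idx - 1] == "strand"
                               and kinds[e_idx + 1] == "strand")
            if between_strands:
                # calibrated hairpin turn at the loop center, random flanks
                (p1, s1), (p2, s2) = K.BETA_TURN_TORSIONS
                mid = (length - 2) // 2
                for i in range(length):
                    if i == mid:
                        torsions.append((p1 + rng.normal(0, 2.0),
                                         s1 + rng.normal(0, 2.0), 180.0))
                    elif i == mid + 1:
                        torsions.append((p2 + rng.normal(0, 2.0),
                                         s2 + rng.normal(0, 2.0), 180.0))
                    else:
                        torsions.append(
                            (K.STRAND_PHI_PSI[0] + rng.normal(0, 3.0),
                             K.STRAND_PHI_PSI[1] + rng.normal(0, 3.0), 180.0))
            else:
                torsions.extend(_loop_torsion(rng) for _ in range(length))
    return torsions


def _min_nonbonded_ca(chain: ProteinChain) -> float:
    ca = chain.ca_coords()
    n = len(ca)
    if n < 4:
        return np.inf
    d2 = ((ca[:, None, :] - ca[None, :, :]) ** 2).sum(axis=2)
    iu = np.triu_indices(n, k=3)
    return float(np.sqrt(d2[iu].min()))


def make_fold(spec: FoldSpec, sequence: str, seed: int = 0,
              chain_id: str = "A") -> ProteinChain:
    """Fold a sequence onto the spec's topology with ideal-geometry elements.

    Helices at (-57, -47), strands at (-120, 120), loops randomized (with a
    calibrated hairpin turn between consecutive strands under sheet packing).
    Loop torsions are re-drawn until the chain is clash-free (no CA pair of
    residues |i-j| >= 3 closer than 3.5 A); exhaustion raises
    GenerationError.
    """
    if len(sequence) != spec.total_length:
        raise ContractError(
            f"sequence length {len(sequence)} != spec length {spec.total_length}")
    rng = _rng(seed)
    for _ in range(FOLD_MAX_RETRIES):
        torsions = _fold_torsions(spec, rng)
        chain = chain_from_torsions(sequence, torsions, chain_id)
        if _min_nonbonded_ca(chain) >= MIN_NONBONDED_CA:
            return chain
    raise GenerationError(
        f"make_fold: no clash-free conformation in {FOLD_MAX_RETRIES} tries")


def perturb_model(chain: ProteinChain, torsion_noise_deg: float,
                  seed: int = 0) -> ProteinChain:
    """Gaussian torsion-space noise: phi/psi jittered, chain rebuilt with
    ideal geometry. Zero noise reproduces the input geometry exactly (for
    chains built by this package's ideal-geometry builder)."""
    if torsion_noise_deg < 0:
        raise ContractError("torsion_noise_deg must be >= 0")
    rng = _rng(seed)
    measured = measure_torsions(chain)
    torsions = []
    for i, (phi, psi, omega) in enumerate(measured):
        phi = phi if phi is not None else -120.0
        psi = psi if psi is not None else 120.0
        omega = omega if omega is not None else 180.0
        torsions.append((phi + rng.normal(0.0, torsion_noise_deg),
                         psi + rng.normal(0.0, torsion_noise_deg),
                         omega))
    return chain_from_torsions(chain.sequence, torsions, chain.chain_id)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation mapping unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        return _rotation_about(axis / np.linalg.norm(axis), np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _biased_interface_aa(rng: np.random.Generator, bias: dict[str, float] | None) -> str:
    if bias is None:
        letters = list(K.INTERFACE_ENRICHED_AA)
        return letters[int(rng.integers(len(letters)))]
    letters = sorted(bias)
    p = np.array([bias[a] for a in letters], dtype=float)
    p /= p.sum()
    return str(rng.choice(letters, p=p))


def make_dimer_template(ligand_spec: FoldSpec, receptor_spec: FoldSpec,
                        seed: int = 0, template_id: str = "dimer",
                        interface_bias: dict[str, float] | None = None,
                        receptor_interface_bias: dict[str, float] | None = None,
                        interface_composition: str = "enriched") -> DimerTemplate:
    """A contacting two-chain complex with labeled interfaces.

    The two monomers are folded independently (polar surface composition),
    then the ligand is rigidly docked with an exposed face toward the
    receptor along a random approach direction, accepting the farthest pose
    where both interfaces carry at least 8 residues without CA overlap
    (< 3.8 A rejected). With interface_composition="enriched" (default),
    interface residues are re-typed from an interface-enriched hydrophobic
    composition (or the supplied bias tables), giving the complex a
    favorable contact signature by construction; "background" leaves the
    polar surface sequence in place, yielding a weak interface. Coordinates
    are untouched by re-typing.
    """
    if ligand_spec.total_length >= receptor_spec.total_length:
        raise ContractError("ligand must be shorter than the receptor")
    if not (50 <= ligand_spec.total_length <= 600
            and 50 <= receptor_spec.total_length <= 600):
        raise ContractError("monomer lengths must lie in [50, 600]")
    rng = _rng(seed)
    lig_seq = random_sequence(ligand_spec.total_length, rng, "polar")
    rec_seq = random_sequence(receptor_spec.total_length, rng, "polar")
    ligand = make_fold(ligand_spec, lig_seq, int(rng.integers(2 ** 31)), "A")
    receptor = make_fold(receptor_spec, rec_seq, int(rng.integers(2 ** 31)), "B")

    rec_ca = receptor.ca_coords()
    rec_center = rec_ca.mean(axis=0)

    # candidate contact faces: outward directions of exposed ligand residues
    from .ppi import _exposure
    expo = _exposure(ligand)
    lig_ca0 = ligand.ca_coords()
    lig_c0 = lig_ca0.mean(axis=0)
    exposed = [i for i in range(len(ligand)) if expo[i] >= 0.5]
    if not exposed:
        exposed = list(range(len(ligand)))

    for _ in range(DOCK_MAX_RETRIES):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        # rotate the ligand so a randomly chosen exposed face points at the
        # receptor (interfaces form on exposed surface, not buried grooves)
        face = exposed[int(rng.integers(len(exposed)))]
        u = lig_ca0[face] - lig_c0
        u /= max(np.linalg.norm(u), 1e-9)
        spin = _rotation_about(v, rng.uniform(0.0, 2 * np.pi))
        R = spin @ _rotation_between(u, -v)
        lig_ca = lig_ca0 @ R.T
        lig_cb = ligand.cb_coords() @ R.T
        lig_center = lig_ca.mean(axis=0)
        rec_cb = receptor.cb_coords()
        r_start = 1.2 * (np.linalg.norm(rec_ca - rec_center, axis=1).max()
                         + np.linalg.norm(lig_ca - lig_center, axis=1).max()) + 10.0
        # slide inward; accept the farthest (minimal-contact) pose whose
        # interfaces already meet the minimum size on both sides
        candidate = None
        for r in np.arange(r_start, 0.0, -0.5):
            t = rec_center + r * v - lig_center
            d2_ca = (((lig_ca + t)[:, None, :] - rec_ca[None, :, :]) ** 2).sum(axis=2)
            if d2_ca.min() < MIN_INTERCHAIN_CA ** 2:
                break
            d2_cb = (((lig_cb + t)[:, None, :] - rec_cb[None, :, :]) ** 2).sum(axis=2)
            in_contact = d2_cb <= 64.0   # 8 A CB-CB contact rule
            if (in_contact.any(axis=1).sum() >= MIN_INTERFACE_RESIDUES
                    and in_contact.any(axis=0).sum() >= MIN_INTERFACE_RESIDUES):
                candidate = ligand.transformed(R, t)
                break
        if candidate is not None:
            iface_l, iface_r = template_interface((candidate, receptor))
            if interface_composition == "background":
                return DimerTemplate(template_id, candidate, receptor,
                                     iface_l, iface_r)
            lig_final = list(candidate.sequence)
            for i in iface_l:
                lig_final[i] = _biased_interface_aa(rng, interface_bias)
            rec_final = list(receptor.sequence)
            for j in iface_r:
                rec_final[j] = _biased_interface_aa(
                    rng, receptor_interface_bias or interface_bias)
            lig_chain = candidate.with_sequence("".join(lig_final))
            rec_chain = receptor.with_sequence("".join(rec_final))
            return DimerTemplate(template_id, lig_chain, rec_chain,
                                 iface_l, iface_r)
    raise GenerationError(
        f"make_dimer_template: docking failed after {DOCK_MAX_RETRIES} tries")


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    out = list(sequence)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in K.AMINO_ACIDS if a != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def make_labeled_library(n_per_topology: int, topologies, seed: int = 0,
                         member_noise_deg: float = 8.0,
                         member_mutation_rate: float = 0.1) -> LabeledFoldLibrary:
    """A fold library whose members cluster by topology.

    ``topologies`` is a list of (label, FoldSpec) with dotted C.A.T labels.
    Members of one topology are torsion-perturbed, sequence-mutated variants
    of a common parent fold, so within-topology structural similarity
    exceeds cross-topology similarity and pairwise identity stays below the
    95% redundancy threshold.
    """
    topologies = list(topologies)
    if len(topologies) < 2:
        raise ContractError("need >= 2 topologies")
    rng = _rng(seed)
    entries: list[LibraryEntry] = []
    for label, spec in topologies:
        parts = label.split(".")
        if len(parts) != 3 or not all(p.isdigit() and int(p) > 0 for p in parts):
            raise ContractError(f"label {label!r} is not a dotted C.A.T string")
        parent_seq = random_sequence(spec.total_length, rng)
        parent = make_fold(spec, parent_seq, int(rng.integers(2 ** 31)))
        for k in range(n_per_topology):
            member = perturb_model(parent, member_noise_deg,
                                   int(rng.integers(2 ** 31)))
            member = member.with_sequence(
                _mutate(parent_seq, member_mutation_rate, rng))
            entries.append(LibraryEntry(f"{label}_{k:02d}", member, label))
    return LabeledFoldLibrary(entries)


def make_proteome(n_background: int, receptors_to_plant, mutation_rate: float,
                  seed: int = 0, background_length_range=(60, 150)):
    """Proteome stand-in: random background sequences plus planted receptor
    homologs derived by point mutation. Returns (records, truth) with truth
    mapping planted sequence ids to their source template ids."""
    if not (0.0 <= mutation_rate <= 0.6):
        raise ContractError("mutation_rate must be in [0, 0.6]")
    rng = _rng(seed)
    records: list[SequenceRecord] = []
    lo, hi = background_length_range
    for k in range(n_background):
        length = int(rng.integers(lo, hi + 1))
        records.append(SequenceRecord(f"bg{k:04d}", random_sequence(length, rng)))
    truth: dict[str, str] = {}
    for item in receptors_to_plant:
        if isinstance(item, DimerTemplate):
            src_id, seq = item.template_id, item.receptor_chain.sequence
        else:
            src_id, seq = item.id, item.sequence
        hid = f"hom_{src_id}"
        records.append(SequenceRecord(hid, _mutate(seq, mutation_rate, rng)))
        truth[hid] = src_id
    return records, truth


def make_compound_library(n: int, n_bits: int = 256, n_actives: int = 5,
                          similarity_to_probe: float = 0.9, seed: int = 0,
                          probe: np.ndarray | None = None,
                          density: float = FINGERPRINT_DENSITY) -> CompoundLibrary:
    """Bit-fingerprint library with planted actives.

    Background fingerprints have independent bits at the given density.
    Actives are derived from the probe by swapping k set bits for k unset
    bits with k = round(n1 (1-t)/(1+t)), which realizes an expected Tanimoto
    of t to the probe.
    """
    if n_bits < 64:
        raise ContractError("n_bits must be >= 64")
    if not (0 <= n_actives < n):
        raise ContractError("need 0 <= n_actives < n")
    rng = _rng(seed)
    if probe is None:
        probe = (rng.random(n_bits) < density).astype(np.int8)
        if probe.sum() < 4:
            probe[:4] = 1
    probe = np.asarray(probe).astype(np.int8)
    fps = np.zeros((n, n_bits), dtype=np.int8)
    ids = [f"cmpd{k:05d}" for k in range(n)]
    active_idx = list(range(n_actives))
    on = np.where(probe == 1)[0]
    off = np.where(probe == 0)[0]
    t = similarity_to_probe
    k_flip = int(round(len(on) * (1.0 - t) / (1.0 + t)))
    for i in range(n):
        if i in active_idx:
            fp = probe.copy()
            if k_flip > 0:
                drop = rng.choice(on, size=min(k_flip, len(on)), replace=False)
                gain = rng.choice(off, size=min(k_flip, len(off)), replace=False)
                fp[drop] = 0
                fp[gain] = 1
            fps[i] = fp
        else:
            fps[i] = (rng.random(n_bits) < density).astype(np.int8)
    return CompoundLibrary(ids, fps, probe,
                           [ids[i] for i in active_idx])


def make_holo_templates(query_fold: ProteinChain, n_templates: int,
                        site_kind: str = "ligand", metal_type: str | None = None,
                        seed: int = 0, template_noise_deg: float = 5.0,
                        site_jitter: float = 1.0) -> HoloTemplateSet:
    """Holo templates sharing a planted binding site on the query fold.

    A surface-adjacent true site is chosen in the query frame; each template
    is a torsion-perturbed copy of the query carrying the site (with <= 1 A
    jitter) expressed in its own frame after a random rigid motion, so that
    alignment-based transfer must recover it. For metal sites, residues
    whose CA lies within 6 A of the site are mutated to chemically apt types
    in the templates AND in the returned query copy, and recorded as the
    coordinating set.
    """
    if n_templates < 1:
        raise ContractError("n_templates must be >= 1")
    if site_kind not in ("ligand", "metal"):
        raise ContractError("site_kind must be 'ligand' or 'metal'")
    if site_kind == "metal":
        if metal_type not in K.METAL_TYPES:
            raise ContractError(f"metal_type must be one of {K.METAL_TYPES}")
    rng = _rng(seed)
    ca = query_fold.ca_coords()
    centroid = ca.mean(axis=0)
    anchor = int(rng.integers(5, len(ca) - 5))
    local = ca[anchor - 1:anchor + 2].mean(axis=0)
    outward = local - centroid
    norm = np.linalg.norm(outward)
    outward = outward / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    # sits just off the local backbone so several CAs fall within the
    # 6 A coordination shell
    true_site = local + 3.0 * outward

    coord_res = frozenset(
        int(i) for i in np.where(
            np.linalg.norm(ca - true_site[None, :], axis=1) <= 6.0)[0])

    query_out = query_fold
    if site_kind == "metal":
        apt = K.METAL_SITE_RESIDUES[metal_type]
        seq = list(query_fold.sequence)
        for i in sorted(coord_res):
            seq[i] = apt[int(rng.integers(len(apt)))]
        query_out = query_fold.with_sequence("".join(seq))

    probe = None
    if site_kind == "ligand":
        probe = (rng.random(256) < FINGERPRINT_DENSITY).astype(np.int8)
        if probe.sum() < 4:
            probe[:4] = 1

    templates: list[HoloTemplate] = []
    for k in range(n_templates):
        tpl_chain = perturb_model(query_out, template_noise_deg,
                                  int(rng.integers(2 ** 31)))
        # express the query-frame site in the rebuilt template's frame
        from .align import kabsch
        sup = kabsch(ca, tpl_chain.ca_coords())
        site_t = sup.rotation @ true_site + sup.translation
        site_t = site_t + rng.normal(0.0, site_jitter / np.sqrt(3.0), size=3)
        if site_kind == "metal":
            # chemistry must hold in each template's own geometry too
            apt = K.METAL_SITE_RESIDUES[metal_type]
            d_tpl = np.linalg.norm(tpl_chain.ca_coords() - site_t[None, :],
                                   axis=1)
            seq_t = list(tpl_chain.sequence)
            for i in np.where(d_tpl <= 6.0)[0]:
                seq_t[i] = apt[int(rng.integers(len(apt)))]
            tpl_chain = tpl_chain.with_sequence("".join(seq_t))
        # random rigid motion of the whole template
        R = _random_rotation(rng)
        t = rng.normal(0.0, 20.0, size=3)
        tpl_chain = tpl_chain.transformed(R, t)
        site_t = R @ site_t + t
        fingerprint = None
        if site_kind == "ligand":
            fp = probe.copy()
            flips = rng.choice(len(fp), size=3, replace=False)
            fp[flips] = 1 - fp[flips]
            fingerprint = fp
        templates.append(HoloTemplate(
            f"holo{k:02d}", tpl_chain, site_t, site_kind,
            metal_type if site_kind == "metal" else None,
            fingerprint, coord_res if site_kind == "metal" else frozenset()))
    return HoloTemplateSet(templates, true_site, query_out, coord_res,
                           probe, metal_type if site_kind == "metal" else None)


# --- whole-benchmark assembly ------------------------------------------------

def standard_fold_specs() -> dict[str, tuple[str, FoldSpec]]:
    """A small panel of distinct topologies with C.A.T labels: mainly-alpha
    bundles, a mainly-beta hairpin-sheet, and alpha-beta mixtures."""
    return {
        "two_helix_bundle": ("1.10.1", FoldSpec(
            (("helix", 22), ("loop", 6), ("helix", 22)), "bundle")),
        "three_helix_bundle": ("1.20.2", FoldSpec(
            (("helix", 16), ("loop", 5), ("helix", 16), ("loop", 5),
             ("helix", 16)), "bundle")),
        "beta_hairpin_sheet": ("2.40.3", FoldSpec(
            (("strand", 8), ("loop", 4), ("strand", 8), ("loop", 6),
             ("helix", 14), ("loop", 4), ("strand", 8)), "sheet")),
        "alpha_beta_plait": ("3.30.4", FoldSpec(
            (("strand", 7), ("loop", 4), ("helix", 18), ("loop", 4),
             ("strand", 7), ("loop", 5), ("helix", 12)), "sheet")),
        "long_hairpin": ("2.30.5", FoldSpec(
            (("strand", 10), ("loop", 4), ("strand", 10), ("loop", 5),
             ("helix", 21)), "sheet")),
        "helix_hairpin": ("1.10.6", FoldSpec(
            (("helix", 26), ("loop", 5), ("helix", 20)), "bundle")),
    }


@dataclass
class BenchmarkParams:
    """Study conditions of the synthetic benchmark (defaults are the
    conditions the pipeline is evaluated under)."""

    n_dimers: int = 6
    n_weak_dimers: int = 24
    n_sproteins_per_dimer: int = 1
    n_background_sproteins: int = 2
    sprotein_noise_deg: float = 3.0
    n_background_proteome: int = 20
    homolog_mutation_rate: float = 0.08
    n_compounds: int = 300
    n_actives: int = 5
    active_similarity: float = 0.9
    n_holo_templates: int = 5
    n_metal_queries: int = 4


@dataclass
class SproteinModel:
    sprotein_id: str
    chain: ProteinChain
    source_template: str | None      # dimer template id or None for background
    noise_deg: float
    estimated_tm: float | None


@dataclass
class SyntheticBenchmark:
    params: BenchmarkParams
    seed: int
    sproteins: list[SproteinModel]
    dimer_library: list[DimerTemplate]
    proteome: list[SequenceRecord]
    fold_library: LabeledFoldLibrary
    compound_library: CompoundLibrary
    holo_sets: dict[str, HoloTemplateSet]       # sprotein id -> ligand set
    metal_sets: dict[str, HoloTemplateSet]      # sprotein id -> metal set
    truth: dict = field(default_factory=dict)

    def save(self, directory) -> None:
        """Serialize to a directory of PDB/FASTA/TSV files + JSON manifest."""
        root = Path(directory)
        root.mkdir(parents=True, exist_ok=True)
        (root / "models").mkdir(exist_ok=True)
        for sp in self.sproteins:
            (root / "models" / f"{sp.sprotein_id}.pdb").write_text(
                write_pdb([sp.chain]))
        (root / "dimers").mkdir(exist_ok=True)
        for dimer in self.dimer_library:
            (root / "dimers" / f"{dimer.template_id}.pdb").write_text(
                write_pdb([dimer.ligand_chain, dimer.receptor_chain]))
        (root / "proteome.fasta").write_text(write_fasta(self.proteome))
        with open(root / "fold_labels.tsv", "w") as fh:
            fh.write("entry_id\tlabel\n")
            for e in self.fold_library.entries:
                fh.write(f"{e.entry_id}\t{e.label}\n")
        manifest = {
            "seed": self.seed,
            "params": self.params.__dict__,
            "models": [
                {"id": sp.sprotein_id, "source_template": sp.source_template,
                 "noise_deg": sp.noise_deg, "estimated_tm": sp.estimated_tm}
                for sp in self.sproteins],
            "truth": {k: v for k, v in self.truth.items()
                      if isinstance(v, (str, int, float, list, dict))},
        }
        (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def make_benchmark(params: BenchmarkParams | None = None,
                   seed: int = 0) -> SyntheticBenchmark:
    """Assemble the full synthetic study: dimer library, small-protein models
    derived from the dimers' ligand chains (plus unrelated background
    models), a proteome with planted receptor homologs, a labeled fold
    library over the same topologies, holo-template sets with planted
    ligand/metal sites, and a compound library with planted actives."""
    params = params or BenchmarkParams()
    rng = _rng(seed)
    specs = standard_fold_specs()
    names = list(specs)

    dimers: list[DimerTemplate] = []
    receptor_spec = FoldSpec((("helix", 18), ("loop", 5), ("helix", 18),
                              ("loop", 5), ("helix", 18), ("loop", 5),
                              ("helix", 18)), "bundle")
    for d in range(params.n_dimers):
        label, lig_spec = specs[names[d % len(names)]]
        dimers.append(make_dimer_template(
            lig_spec, receptor_spec, seed=int(rng.integers(2 ** 31)),
            template_id=f"tpl{d:02d}"))
    # weak complexes: background (polar) interfaces; they broaden the
    # reference energy distribution toward unfavorable scores but are never
    # sources of planted truth
    weak_dimers: list[DimerTemplate] = []
    for d in range(params.n_weak_dimers):
        label, lig_spec = specs[names[d % len(names)]]
        weak_dimers.append(make_dimer_template(
            lig_spec, receptor_spec, seed=int(rng.integers(2 ** 31)),
            template_id=f"weak{d:02d}", interface_composition="background"))

    truth: dict = {"interactions": [], "planted_homologs": {}}
    sproteins: list[SproteinModel] = []
    k = 0
    for dimer in dimers:
        for _ in range(params.n_sproteins_per_dimer):
            model = perturb_model(dimer.ligand_chain, params.sprotein_noise_deg,
                                  int(rng.integers(2 ** 31)))
            sid = f"sprot{k:03d}"
            sproteins.append(SproteinModel(sid, model, dimer.template_id,
                                           params.sprotein_noise_deg, 0.7))
            truth["interactions"].append([sid, f"hom_{dimer.template_id}"])
            k += 1
    bg_spec = FoldSpec((("helix", 12), ("loop", 4), ("strand", 6), ("loop", 4),
                        ("strand", 6), ("loop", 4), ("helix", 14)), "sheet")
    for _ in range(params.n_background_sproteins):
        seq = random_sequence(bg_spec.total_length, rng)
        chain = make_fold(bg_spec, seq, int(rng.integers(2 ** 31)))
        sproteins.append(SproteinModel(f"sprot{k:03d}", chain, None,
                                       0.0, 0.3))
        k += 1

    proteome, planted = make_proteome(
        params.n_background_proteome, dimers, params.homolog_mutation_rate,
        seed=int(rng.integers(2 ** 31)))
    truth["planted_homologs"] = planted

    topo = [(specs[n][0], specs[n][1]) for n in names[:4]]
    fold_library = make_labeled_library(3, topo, seed=int(rng.integers(2 ** 31)))

    holo_sets: dict[str, HoloTemplateSet] = {}
    metal_sets: dict[str, HoloTemplateSet] = {}
    metal_names = list(K.METAL_TYPE_MIXTURE)
    metal_p = np.array(list(K.METAL_TYPE_MIXTURE.values()))
    metal_p = metal_p / metal_p.sum()
    probe = None
    for sp in sproteins[:2]:
        hs = make_holo_templates(sp.chain, params.n_holo_templates, "ligand",
                                 seed=int(rng.integers(2 ** 31)))
        holo_sets[sp.sprotein_id] = hs
        if probe is None:
            probe = hs.probe_fingerprint
    for sp in sproteins[:params.n_metal_queries]:
        mt = str(rng.choice(metal_names, p=metal_p))
        metal_sets[sp.sprotein_id] = make_holo_templates(
            sp.chain, params.n_holo_templates, "metal", metal_type=mt,
            seed=int(rng.integers(2 ** 31)))

    compounds = make_compound_library(
        params.n_compounds, n_actives=params.n_actives,
        similarity_to_probe=params.active_similarity,
        seed=int(rng.integers(2 ** 31)), probe=probe)

    return SyntheticBenchmark(params, seed, sproteins, dimers + weak_dimers,
                              proteome, fold_library, compounds, holo_sets,
                              metal_sets, truth)
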