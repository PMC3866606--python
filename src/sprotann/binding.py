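"""Template-transfer binding-site annotation.

Ligand pockets: bound-ligand centroids of holo templates are mapped through
structure alignments (TM >= 0.4) into the query frame, clustered by
average-linkage at 8 A, and each cluster becomes a pocket with a
support-and-similarity logistic confidence; a pocket's consensus fingerprint
drives ligand-based virtual screening, with the Z-score of the top-ranked
compound (>= 2 confident) summarizing the screen.

Metal sites: the same transfer-and-cluster machinery plus a TM-weighted
majority vote over template metal types and a coordination-chemistry filter
on binding residues, reported with three independent confidence channels
(site, residues, type) that may add up to 300%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import expit

from . import constants as K
from .align import align_structures, TM_SIGNIFICANCE
from .errors import ContractError
from .structio import ProteinChain

__all__ = [
    "HoloTemplate", "PocketPrediction", "ScreeningResult", "MetalPrediction",
    "transfer_site_centers", "cluster_sites", "screen_library",
    "dedupe_library", "predict_metal_sites", "tanimoto",
]

CLUSTER_CUTOFF = 8.0              # A, average-linkage cut for site centers
POCKET_RESIDUE_CA_RADIUS = 6.0    # A
SITE_CONFIDENCE_A = 4.0           # weight on support fraction
SITE_CONFIDENCE_B = 5.0           # weight on mean template TM
SITE_CONFIDENCE_C = -5.0          # intercept
Z_CONFIDENT = 2.0
DEDUPE_TANIMOTO = 0.8
METAL_SIDECHAIN_RADIUS = 3.0      # A, any side-chain atom
METAL_CA_RADIUS = 6.0             # A, CA fallback for backbone-only models


@dataclass
class HoloTemplate:
    """A holo structure carrying a bound-ligand centroid or metal position."""

    template_id: str
    chain: ProteinChain
    site_position: np.ndarray          # centroid (ligand) or metal position
    kind: str                          # "ligand" | "metal"
    metal_type: str | None = None
    fingerprint: np.ndarray | None = None
    coordinating_residues: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.site_position = np.asarray(self.site_position, dtype=float)
        if self.kind == "ligand" and self.fingerprint is None:
            raise ContractError(f"{self.template_id}: ligand template needs a fingerprint")
        if self.kind == "metal" and self.metal_type not in K.METAL_TYPES:
            raise ContractError(f"{self.template_id}: invalid metal type {self.metal_type}")


@dataclass
class PocketPrediction:
    center: np.ndarray
    supporting_templates: list[tuple[str, float]]   # (template id, tm)
    binding_residues: frozenset[int]
    site_confidence: float
    rank_weight: float                              # sum of member TM-scores
    member_centers: np.ndarray = field(repr=False, default=None)
    member_templates: list[HoloTemplate] = field(repr=False, default_factory=list)
    member_tms: list[float] = field(repr=False, default_factory=list)
    # per member: template residue index -> query residue index
    member_mappings: list[dict[int, int]] = field(repr=False, default_factory=list)


@dataclass
class ScreeningResult:
    ranking: list[tuple[str, float]]    # (compound id, similarity) descending
    z_top: float

    @property
    def confident(self) -> bool:
        return self.z_top >= Z_CONFIDENT


@dataclass
class MetalPrediction:
    position: np.ndarray
    metal_type: str
    binding_residues: frozenset[int]
    conf_site: float
    conf_residues: float
    conf_type: float


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Generalized Tanimoto sum(min)/sum(max); works on bit and real vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = np.maximum(a, b).sum()
    if denom == 0:
        return 0.0
    return float(np.minimum(a, b).sum() / denom)


def transfer_site_centers(query: ProteinChain, holo_templates,
                          tm_min: float = TM_SIGNIFICANCE):
    """Map template site positions into the query frame.

    Each template is aligned to the query (normalization: query length);
    templates below the TM gate are discarded. The alignment transform maps
    query coordinates onto the template; its inverse carries the template's
    site position into the query frame. Returns [(center, template, tm, template->query residue map)].
    """
    out = []
    for tpl in holo_templates:
        aln = align_structures(query, tpl.chain)
        if aln.tm_score < tm_min or aln.superposition is None:
            continue
        R = aln.superposition.rotation
        t = aln.superposition.translation
        center = R.T @ (tpl.site_position - t)
        mapping = {j: i for i, j in aln.pairs}
        out.append((center, tpl, aln.tm_score, mapping))
    return out


def cluster_sites(centers, cutoff: float = CLUSTER_CUTOFF,
                  query: ProteinChain | None = None) -> list[PocketPrediction]:
    """Average-linkage clustering of transferred centers into pockets.

    ``centers`` is the output of :func:`transfer_site_centers`. Pocket center
    is the TM-weighted mean of cluster members; pockets are ranked by summed
    member TM; confidence is a fixed logistic in the support fraction and the
    mean member TM. Binding residues are query residues with CA within 6 A
    of the center (empty when no query is supplied).
    """
    centers = list(centers)
    if not centers:
        raise ContractError("cluster_sites: no centers")
    centers = [(c[0], c[1], c[2], c[3] if len(c) > 3 else {}) for c in centers]
    pts = np.array([np.asarray(c, float) for c, _, _, _ in centers])
    if len(pts) == 1:
        labels = np.array([1])
    else:
        Z = linkage(pts, method="average")
        labels = fcluster(Z, t=cutoff, criterion="distance")
    n_total = len(centers)
    pockets = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        tms = np.array([centers[i][2] for i in idx])
        weights = tms / tms.sum()
        center = (pts[idx] * weights[:, None]).sum(axis=0)
        support = [(centers[i][1].template_id, float(centers[i][2])) for i in idx]
        support.sort(key=lambda s: (-s[1], s[0]))
        conf = float(expit(SITE_CONFIDENCE_A * (len(idx) / n_total)
                           + SITE_CONFIDENCE_B * tms.mean()
                           + SITE_CONFIDENCE_C))
        if query is not None:
            ca = query.ca_coords()
            d = np.linalg.norm(ca - center[None, :], axis=1)
            residues = frozenset(np.where(d <= POCKET_RESIDUE_CA_RADIUS)[0].tolist())
        else:
            residues = frozenset()
        pockets.append(PocketPrediction(
            center, support, residues, conf, float(tms.sum()),
            member_centers=pts[idx],
            member_templates=[centers[i][1] for i in idx],
            member_tms=[float(centers[i][2]) for i in idx],
            member_mappings=[centers[i][3] for i in idx]))
    pockets.sort(key=lambda p: -p.rank_weight)
    return pockets


def screen_library(pocket: PocketPrediction, compound_ids, fingerprints) -> ScreeningResult:
    """Rank a compound library against the pocket's consensus fingerprint.

    The consensus is the per-bit mean over supporting-template fingerprints;
    similarity is generalized Tanimoto; z_top standardizes the top score
    against the whole score distribution. Ties break by compound id.
    """
    fps = [t.fingerprint for t in pocket.member_templates if t.fingerprint is not None]
    if not fps:
        raise ContractError("screen_library: pocket templates carry no fingerprints")
    ids = list(compound_ids)
    X = np.asarray(fingerprints, dtype=float)
    if len(ids) < 10:
        raise ContractError("screen_library: library must have >= 10 compounds")
    consensus = np.mean(np.asarray(fps, dtype=float), axis=0)
    scores = np.array([tanimoto(consensus, x) for x in X])
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    sd = scores.std(ddof=0)
    if sd < 1e-12:
        raise ContractError("screen_library: degenerate score distribution (sd = 0)")
    z_top = float((scores[order[0]] - scores.mean()) / sd)
    ranking = [(ids[i], float(scores[i])) for i in order]
    return ScreeningResult(ranking, z_top)


def dedupe_library(compound_ids, fingerprints, t_max: float = DEDUPE_TANIMOTO):
    """Greedy non-redundancy filter: keep a compound iff its Tanimoto to every
    already-kept compound is < t_max; input order defines priority."""
    if not (0.0 < t_max <= 1.0):
        raise ContractError("t_max must be in (0, 1]")
    ids = list(compound_ids)
    X = np.asarray(fingerprints, dtype=float)
    kept: list[int] = []
    for i in range(len(ids)):
        if all(tanimoto(X[i], X[j]) < t_max for j in kept):
            kept.append(i)
    return [ids[i] for i in kept], X[kept]


def _metal_binding_residues(query: ProteinChain, position: np.ndarray,
                            metal_type: str) -> frozenset[int]:
    """Residues coordinating the metal: any side-chain atom within 3 A, or CA
    within 6 A for backbone-only/stub models, filtered by the chemistry table
    (backbone O within 3.5 A also qualifies for Ca/Mg)."""
    apt = K.METAL_CHEMISTRY[metal_type]
    hits = set()
    for i, res in enumerate(query.residues):
        side = [a for name, a in res.atoms.items()
                if name not in ("N", "CA", "C", "O", "H")]
        near = any(np.linalg.norm(a.position - position) <= METAL_SIDECHAIN_RADIUS
                   for a in side)
        if not near and "CA" in res:
            near = np.linalg.norm(res["CA"].position - position) <= METAL_CA_RADIUS
        if not near:
            continue
        if res.aa in apt:
            hits.add(i)
        elif metal_type in ("Ca", "Mg") and "O" in res and \
                np.linalg.norm(res["O"].position - position) <= 3.5:
            hits.add(i)
    return frozenset(hits)


def predict_metal_sites(query: ProteinChain, metal_templates,
                        tm_min: float = TM_SIGNIFICANCE,
                        cutoff: float = CLUSTER_CUTOFF) -> list[MetalPrediction]:
    """Metal-site prediction with three independent confidence channels.

    Transferred metal positions are clustered like ligand centers; the metal
    type is a TM-weighted majority vote among cluster members (conf_type =
    winning vote share); binding residues follow the coordination-chemistry
    filter; conf_residues is the fraction of members whose own coordinating
    residues map onto the reported query residues.
    """
    centers = transfer_site_centers(query, metal_templates, tm_min)
    if not centers:
        return []
    pockets = cluster_sites(centers, cutoff, query)
    out = []
    for pocket in pockets:
        votes: dict[str, float] = {}
        for tpl, tm in zip(pocket.member_templates, pocket.member_tms):
            votes[tpl.metal_type] = votes.get(tpl.metal_type, 0.0) + tm
        total = sum(votes.values())
        metal_type = max(sorted(votes), key=lambda m: votes[m])
        conf_type = votes[metal_type] / total if total > 0 else 0.0
        residues = _metal_binding_residues(query, pocket.center, metal_type)
        n_match = 0
        for tpl, mapping in zip(pocket.member_templates, pocket.member_mappings):
            mapped = {mapping[r] for r in tpl.coordinating_residues if r in mapping}
            if mapped and mapped & residues:
                n_match += 1
        conf_res = n_match / len(pocket.member_templates) if pocket.member_templates else 0.0
        out.append(MetalPrediction(pocket.center, metal_type, residues,
                                   pocket.site_confidence, conf_res, conf_type))
    return out
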